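"""Euclidean-disc/ball binary morphology via distance transforms.

Dilation, erosion, closing and opening with a radius-r Euclidean structuring
element (pixels whose center distance to the origin is <= r) are computed by
thresholding exact Euclidean distance transforms rather than by iterating a
structuring element.  The result is identical to structure-element morphology
with the discrete Euclidean disc/ball and background border value (scipy's
default): the outside of the volume counts as background, so dilation is
clipped at the border and erosion shrinks objects touching it.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def disc(radius: int) -> np.ndarray:
    """Discrete Euclidean disc: pixels with center distance <= radius."""
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def ball(radius: int) -> np.ndarray:
    r = int(radius)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (zz * zz + yy * yy + xx * xx) <= r * r


def dilate(mask: np.ndarray, radius: float, sampling=None) -> np.ndarray:
    """Dilate by a Euclidean disc/ball of the given radius (same units as sampling)."""
    mask = np.asarray(mask, dtype=bool)
    if radius <= 0 or not mask.any():
        return mask.copy()
    d = ndimage.distance_transform_edt(~mask, sampling=sampling)
    return d <= radius


def erode(mask: np.ndarray, radius: float, sampling=None) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if radius <= 0 or not mask.any():
        return mask.copy()
    # pad with one background layer so the outside of the volume erodes the border
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    d = ndimage.distance_transform_edt(padded, sampling=sampling)
    sl = tuple(slice(1, -1) for _ in range(mask.ndim))
    return d[sl] > radius


def close(mask: np.ndarray, radius: float, sampling=None) -> np.ndarray:
    """Closing on an effectively infinite canvas.

    The volume is padded by the disc radius before dilating so that the
    erosion step sees the full dilated support; otherwise a large disc whose
    dilation is clipped at the canvas edge under-fills, and dent volume would
    not grow monotonically with the radius.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius <= 0 or not mask.any():
        return mask.copy()
    if sampling is None:
        pad = int(np.ceil(radius)) + 1
    else:
        pad = int(np.ceil(radius / min(sampling))) + 1
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    out = erode(dilate(padded, radius, sampling), radius, sampling)
    sl = tuple(slice(pad, -pad) for _ in range(mask.ndim))
    return out[sl]


def open_(mask: np.ndarray, radius: float, sampling=None) -> np.ndarray:
    return dilate(erode(mask, radius, sampling), radius, sampling)
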