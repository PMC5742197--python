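"""Brain-contour binarization and pial-vessel dent extraction.

In modified-Nissl contrast the tissue is stained dark while vessel lumina and
the embedding resin outside the brain are unstained (bright).  The brain
contour is therefore recovered per coronal slice by median filtering, a single
global Otsu threshold (dark side = tissue), hole filling, small-scale
morphological cleanup, and connected-component pruning.

Pial surface vessels run on the brain surface and indent it: closing each
slice with a radius-30 disc fills those concave dents, and subtracting the
original mask from the closed mask isolates them.  Stacked across slices the
dents form continuous 3D tubes that can be traced like any other vessel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _morph
from .stack import BinaryVolume, ImageStack


class DegenerateImageError(ValueError):
    """Raised when a threshold is requested on a constant image."""


@dataclass
class ContourParams:
    """Parameters of the brain-contour pipeline.

    ``closing_disc_radius_px`` is the disc radius used to fill pial dents
    (default 30 px, i.e. 150 um at 5 um voxels).  ``open_radius_px`` /
    ``close_radius_px`` are the small cleanup radii applied after hole
    filling; ``min_component_voxels`` prunes large-scale off-brain noise.
    """

    median_window: int = 3
    closing_disc_radius_px: int = 30
    min_component_voxels: int = 1000
    fill_holes: bool = True
    open_radius_px: int = 2
    close_radius_px: int = 2
    object_is_dark: bool = True
    per_slice_threshold: bool = False

    def __post_init__(self) -> None:
        if self.median_window != 3:
            raise ValueError("median window is fixed at 3")
        for name in ("closing_disc_radius_px", "open_radius_px", "close_radius_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_component_voxels < 0:
            raise ValueError("min_component_voxels must be >= 0")


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu threshold of an 8-bit image.

    Returns the level ``t`` in [0, 254] maximizing the between-class variance
    of the split ``{<= t, > t}``; ties are broken by the lowest maximizing t.
    Raises :class:`DegenerateImageError` on a constant image.
    """
    arr = np.asarray(image)
    hist = np.bincount(arr.astype(np.uint8).ravel(), minlength=256).astype(float)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("Otsu threshold undefined on a constant image")
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)[:-1]  # weight of class {<= t}, t = 0..254
    w1 = total - w0
    m0 = np.cumsum(hist * levels)[:-1]
    mu_total = (hist * levels).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (mu_total - m0) / w1
        var_between = w0 * w1 * (mean0 - mean1) ** 2
    var_between[np.isnan(var_between)] = -1.0
    return int(np.argmax(var_between))  # argmax returns the first (lowest) maximizer


def binarize_brain(stack: ImageStack, params: ContourParams | None = None) -> BinaryVolume:
    """Segment the brain contour from a Nissl-contrast stack.

    Per slice: 3x3 median filter, binarize at a single global Otsu threshold
    (dark side by default), fill holes, close, open; then prune 3D connected
    components smaller than ``min_component_voxels``.
    """
    from .stack import median_filter_slice

    params = params or ContourParams()
    filtered = median_filter_slice(stack)
    vol = filtered.voxels
    if params.per_slice_threshold:
        mask = np.zeros(vol.shape, dtype=bool)
        for z in range(vol.shape[0]):
            t = otsu_threshold(vol[z])
            mask[z] = (vol[z] <= t) if params.object_is_dark else (vol[z] > t)
    else:
        t = otsu_threshold(vol)
        mask = (vol <= t) if params.object_is_dark else (vol > t)

    for z in range(mask.shape[0]):
        sl = mask[z]
        if params.fill_holes:
            sl = ndimage.binary_fill_holes(sl)
        if params.close_radius_px:
            sl = _morph.close(sl, params.close_radius_px)
        if params.open_radius_px:
            sl = _morph.open_(sl, params.open_radius_px)
        mask[z] = sl

    if params.min_component_voxels > 0 and mask.any():
        lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        sizes = np.bincount(lab.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes[1:] >= params.min_component_voxels
        mask = keep[lab]

    if not mask.any():
        warnings.warn("brain mask empty after cleanup", stacklevel=2)
    return BinaryVolume(mask, stack.voxel_size_um, provenance="brain_mask")


def extract_dents(mask: BinaryVolume, closing_disc_radius_px: int = 30) -> BinaryVolume:
    """Extract pial-vessel dents: per-slice ``close(mask, disc(r)) & ~mask``.

    The closing fills surface concavities narrower than the disc; subtracting
    the original mask leaves exactly the filled-in dents.  Components touching
    the image border are kept (dents sit on the surface by construction).
    Dent volume grows monotonically with the disc radius.
    """
    src = mask.voxels
    dents = np.zeros(src.shape, dtype=bool)
    for z in range(src.shape[0]):
        closed = _morph.close(src[z], closing_disc_radius_px)
        dents[z] = closed & ~src[z]
    return BinaryVolume(dents, mask.voxel_size_um, provenance="dent_mask")
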