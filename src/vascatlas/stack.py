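"""Raster data model, TIFF I/O, slice-wise median filtering, affine reorientation.

The carrier type for every raster stage is :class:`ImageStack`: an 8-bit 3D
voxel grid indexed ``(z, y, x)`` (z = coronal section index) with an
anisotropic voxel size in micrometres.  Whole-brain artery/vein work uses
5x5x5 um voxels; microvessel cubes use 0.35x0.35x1 um.

Spatial reorientation follows the row-vector homogeneous convention
``A * T = B``: a coordinate row vector ``(z, y, x, 1)`` of the source stack A
left-multiplies the 4x4 matrix T to give the target coordinate in B.  Output
voxels are resampled by inverse mapping: each voxel of B looks up its value in
A at the ``T``-inverse-mapped position.  Translations are expressed in voxel
units by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage


class StackIOError(RuntimeError):
    """Raised for unreadable, inconsistent, or gappy stack inputs."""


@dataclass
class ImageStack:
    """8-bit intensity volume with voxel size in micrometres, indexed (z, y, x)."""

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_convention: str = "zyx"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if self.voxels.dtype != np.uint8:
            if self.voxels.min() < 0 or self.voxels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.voxels = self.voxels.astype(np.uint8)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be three positive floats (dz, dy, dx)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BinaryVolume:
    """{0,1} volume on the same grid as its source stack."""

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: str = "brain_mask"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(np.count_nonzero(self.voxels))


@dataclass
class LabelVolume:
    """Integer-labeled volume (brain regions, or one label per named vessel)."""

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("label volume must be integer typed")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def labels(self) -> np.ndarray:
        lab = np.unique(self.voxels)
        return lab[lab != 0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"(\d+)")


def _series_index(path: Path) -> int | None:
    m = _NUM_RE.findall(path.stem)
    return int(m[-1]) if m else None


def read_stack(path, voxel_size_um=(1.0, 1.0, 1.0)) -> ImageStack:
    """Read a multi-page TIFF, or a directory of numbered per-slice images.

    A slice series must be contiguously numbered; a gap raises
    :class:`StackIOError` naming the missing indices.  Mixed dtypes across
    slices are rejected.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            [p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")],
            key=lambda p: (_series_index(p) is None, _series_index(p), p.name),
        )
        if not files:
            raise StackIOError(f"no TIFF/PNG slices found in {path}")
        indices = [_series_index(p) for p in files]
        if all(i is not None for i in indices):
            missing = sorted(set(range(min(indices), max(indices) + 1)) - set(indices))
            if missing:
                names = ", ".join(f"{i:04d}" for i in missing)
                raise StackIOError(f"slice series has gaps; missing indices: {names}")
        slices = []
        for p in files:
            if p.suffix.lower() == ".png":
                import imageio.v3 as iio

                arr = iio.imread(p)
            else:
                arr = tifffile.imread(p)
            if arr.ndim != 2:
                raise StackIOError(f"slice {p.name} is not 2D (shape {arr.shape})")
            slices.append(arr)
        dtypes = {s.dtype for s in slices}
        if len(dtypes) > 1:
            raise StackIOError(f"mixed dtypes across slices: {sorted(map(str, dtypes))}")
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise StackIOError(f"mixed slice shapes: {sorted(shapes)}")
        vol = np.stack(slices, axis=0)
    else:
        vol = tifffile.imread(path)
        if vol.ndim == 2:
            vol = vol[None]
    return ImageStack(vol, voxel_size_um)


def write_stack(stack: ImageStack, path) -> Path:
    """Write as an uncompressed multi-page TIFF; lossless round trip."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.voxels, photometric="minisblack")
    return path


def write_volume(voxels: np.ndarray, path) -> Path:
    """Write an arbitrary (binary/label) volume as multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(voxels)
    if arr.dtype == bool:
        arr = (arr * np.uint8(255)).astype(np.uint8)
    tifffile.imwrite(path, arr, photometric="minisblack")
    return path


def read_volume(path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def median_filter_slice(stack: ImageStack) -> ImageStack:
    """3x3 median filter applied to every z-slice independently (reflect edges).

    This is the denoising step that precedes brain-contour binarization; a 3x3
    window rejects isolated salt/pepper voxels while leaving flat regions and
    straight edges unchanged.
    """
    out = ndimage.median_filter(stack.voxels, size=(1, 3, 3), mode="reflect")
    return ImageStack(out, stack.voxel_size_um)


# ---------------------------------------------------------------------------
# Affine reorientation
# ---------------------------------------------------------------------------


@dataclass
class AffineTransform:
    """4x4 homogeneous transform under the row-vector convention ``A * T = B``.

    The upper-left 3x3 block S holds rotation/scale, the fourth *row* holds the
    translation (t1, t2, t3) in voxel units; the last column is (0, 0, 0, 1)^T.
    """

    matrix: np.ndarray
    interpolation: str = "nearest"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[:, 3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("last column must be (0, 0, 0, 1)^T (row-vector convention)")
        if abs(np.linalg.det(self.matrix[:3, :3])) <= 1e-12:
            raise ValueError("rotation/scale block S is singular")
        if self.interpolation not in ("nearest", "trilinear"):
            raise ValueError("interpolation must be 'nearest' or 'trilinear'")

    @classmethod
    def identity(cls, interpolation: str = "nearest") -> "AffineTransform":
        return cls(np.eye(4), interpolation)

    @classmethod
    def from_rotation_translation(
        cls, S: np.ndarray, t=(0.0, 0.0, 0.0), interpolation: str = "nearest"
    ) -> "AffineTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(S, dtype=float)
        m[3, :3] = np.asarray(t, dtype=float)
        return cls(m, interpolation)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.interpolation)


def apply_affine(stack: ImageStack, transform: AffineTransform, out_shape=None) -> ImageStack:
    """Resample ``stack`` through ``transform`` by inverse mapping.

    Every output voxel coordinate ``(z, y, x, 1)`` is mapped through T^-1 to a
    source coordinate; the output value is sampled there (nearest-neighbour by
    default, trilinear optionally).  Coordinates that fall outside the source
    volume yield 0.
    """
    shape = tuple(out_shape) if out_shape is not None else stack.shape
    inv = np.linalg.inv(transform.matrix)
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    coords_out = np.stack(
        [zz.ravel(), yy.ravel(), xx.ravel(), np.ones(zz.size)], axis=1
    ).astype(float)
    coords_in = coords_out @ inv
    sample = coords_in[:, :3].T  # (3, N) in (z, y, x) order
    order = 0 if transform.interpolation == "nearest" else 1
    vals = ndimage.map_coordinates(
        stack.voxels.astype(float), sample, order=order, mode="constant", cval=0.0, prefilter=False
    )
    out = np.clip(np.rint(vals), 0, 255).astype(np.uint8).reshape(shape)
    return ImageStack(out, stack.voxel_size_um)
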