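"""Image containers, left-right geometry, masks and ROI utilities.

All volumes in this package live on a common :class:`ImageGrid`. By
convention the *first* voxel axis is the left-right axis; the mid-sagittal
plane lies between columns ``(nx - 1) // 2`` and ``nx // 2``, so mirror
flipping is a pure index reversal along axis 0. No affine handling or
resampling is performed: images that are to be combined must share a grid,
and mismatches are hard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageGrid",
    "ScalarVolume",
    "BoldImage",
    "BinaryMask",
    "GridMismatchError",
    "EmptyMaskError",
    "flip_lr",
    "mirror_mask",
    "threshold_to_mask",
    "mean_in_mask",
    "mean_timecourse",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_bold",
    "save_bold",
]


class GridMismatchError(ValueError):
    """Raised when two images on different grids are combined."""


class EmptyMaskError(ValueError):
    """Raised when an operation requires a nonempty mask."""


@dataclass(frozen=True)
class ImageGrid:
    """A 3-D voxel lattice with isotropic-or-not voxel sizes in mm.

    Axis 0 is left-right, axis 1 anterior-posterior, axis 2
    inferior-superior (the slice axis used for slice-wise laterality).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three dims >= 1, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")

    @property
    def nx(self) -> int:
        return self.shape[0]

    def affine(self) -> np.ndarray:
        """Diagonal voxel-to-mm affine used when writing NIfTI."""
        return np.diag([*self.voxel_size, 1.0])


def _check_grid(a, b) -> None:
    if a.grid != b.grid:
        raise GridMismatchError(f"grid mismatch: {a.grid} vs {b.grid}")


@dataclass(frozen=True)
class ScalarVolume:
    """A 3-D real-valued map (FA, Fisher-z connectivity, t, p, ...)."""

    grid: ImageGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.shape != self.grid.shape:
            raise ValueError(f"data shape {data.shape} != grid shape {self.grid.shape}")
        object.__setattr__(self, "data", data)


@dataclass(frozen=True)
class BoldImage:
    """A 4-D BOLD series (x, y, z, t) with repetition time in seconds."""

    grid: ImageGrid
    data: np.ndarray = field(repr=False)
    tr: float = 2.41

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 4 or data.shape[:3] != self.grid.shape:
            raise ValueError(
                f"BOLD data must be 4-D on grid {self.grid.shape}, got {data.shape}"
            )
        if data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 frames")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[3])


@dataclass(frozen=True)
class BinaryMask:
    """A boolean 3-D mask (tract skeleton, cortical ROI, brain mask)."""

    grid: ImageGrid
    data: np.ndarray = field(repr=False)
    side: str | None = None  # "left" | "right" | "bilateral" | None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=bool)
        if data.shape != self.grid.shape:
            raise ValueError(f"mask shape {data.shape} != grid shape {self.grid.shape}")
        if self.side not in (None, "left", "right", "bilateral"):
            raise ValueError(f"invalid side label {self.side!r}")
        object.__setattr__(self, "data", data)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def flip_lr(img):
    """Mirror an image across the mid-sagittal plane.

    Voxel ``x`` maps to ``nx - 1 - x`` along axis 0; all other axes are
    untouched. Applying the flip twice is the identity, bit for bit.
    """
    return replace(img, data=img.data[::-1].copy())


def mirror_mask(m: BinaryMask) -> BinaryMask:
    """Mirror a mask left<->right, swapping its side label.

    This is how the hand ROI of the missing hand is derived from the
    intact-hand ROI: flip the coordinates on the x axis.
    """
    if m.n_voxels == 0:
        raise EmptyMaskError("cannot mirror an empty mask (invalid ROI)")
    swap = {"left": "right", "right": "left"}
    return BinaryMask(m.grid, m.data[::-1].copy(), side=swap.get(m.side, m.side))


def threshold_to_mask(v: ScalarVolume, thresh: float) -> BinaryMask:
    """Mask of voxels with value strictly greater than ``thresh``."""
    return BinaryMask(v.grid, v.data > thresh)


def mean_in_mask(v: ScalarVolume, m: BinaryMask) -> float:
    """Arithmetic mean of a volume over the true voxels of a mask."""
    _check_grid(v, m)
    if m.n_voxels == 0:
        raise EmptyMaskError("mean over an empty mask is undefined")
    vals = v.data[m.data]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values inside the mask")
    return float(vals.mean())


def mean_timecourse(b: BoldImage, m: BinaryMask) -> np.ndarray:
    """Per-frame mean of a BOLD image over a mask (length-T vector)."""
    _check_grid(b, m)
    if m.n_voxels == 0:
        raise EmptyMaskError("mean time-course over an empty mask is undefined")
    return b.data[m.data].mean(axis=0)


# ---------------------------------------------------------------------------
# NIfTI I/O. TR is stored in / read from the 4th pixdim of the header.


def _grid_from_nifti(img) -> ImageGrid:
    zooms = img.header.get_zooms()
    return ImageGrid(tuple(img.shape[:3]), tuple(float(z) for z in zooms[:3]))


def save_volume(v: ScalarVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(v.data.astype(np.float32), v.grid.affine()), str(path))


def load_volume(path: str | Path) -> ScalarVolume:
    img = nib.load(str(path))
    return ScalarVolume(_grid_from_nifti(img), np.asanyarray(img.dataobj))


def save_mask(m: BinaryMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(m.data.astype(np.uint8), m.grid.affine()), str(path))


def load_mask(path: str | Path, side: str | None = None) -> BinaryMask:
    img = nib.load(str(path))
    return BinaryMask(_grid_from_nifti(img), np.asanyarray(img.dataobj) > 0, side=side)


def save_bold(b: BoldImage, path: str | Path) -> None:
    img = nib.Nifti1Image(b.data.astype(np.float32), b.grid.affine())
    img.header.set_zooms((*b.grid.voxel_size, b.tr))
    nib.save(img, str(path))


def load_bold(path: str | Path, tr: float | None = None) -> BoldImage:
    """Load a 4-D NIfTI; TR comes from the header unless overridden."""
    img = nib.load(str(path))
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 0.0
        if tr <= 0:
            raise ValueError(f"{path}: no usable TR in header; pass tr explicitly")
    return BoldImage(_grid_from_nifti(img), np.asanyarray(img.dataobj), tr=tr)
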