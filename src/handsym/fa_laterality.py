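"""Fractional anisotropy and left-right laterality indices.

The laterality index LI = (A - B) / (A + B) is the bounded asymmetry
measure used throughout: A is the mean FA of the tract in the hemisphere
contralateral to the intact (or dominant) hand, B the homologous tract on
the other side. LI > 0 means higher microstructural anisotropy on the
intact/dominant side.

Tract means follow the white-matter skeleton convention: only skeleton
voxels with FA above a floor (default 0.2) enter the average, so partial
volume voxels at tract edges do not dilute the estimate. The same floor is
applied in the slice-wise profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .imggeom import BinaryMask, EmptyMaskError, ScalarVolume, _check_grid

__all__ = [
    "TractFA",
    "SliceLateralityProfile",
    "fa_from_eigenvalues",
    "laterality_index",
    "tract_mean_fa",
    "slice_laterality_profile",
]


class TractFA(NamedTuple):
    mean_fa: float
    n_voxels: int


def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy from the three diffusion-tensor eigenvalues.

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, in [0, 1].
    Accepts scalars or broadcastable arrays; eigenvalues must be
    nonnegative and not all zero.
    """
    lam = np.stack(np.broadcast_arrays(
        np.asarray(l1, float), np.asarray(l2, float), np.asarray(l3, float)))
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be nonnegative")
    norm = np.sqrt((lam ** 2).sum(axis=0))
    if np.any(norm == 0):
        raise ValueError("FA undefined for all-zero eigenvalues")
    dev = lam - lam.mean(axis=0)
    fa = np.sqrt(1.5) * np.sqrt((dev ** 2).sum(axis=0)) / norm
    return float(fa) if fa.ndim == 0 else fa


def laterality_index(a_intact: float, b_residual: float) -> float:
    """(A - B) / (A + B); antisymmetric in its arguments, 0 at symmetry."""
    s = a_intact + b_residual
    if s == 0:
        raise ValueError("laterality index undefined: A + B = 0")
    return (a_intact - b_residual) / s


def tract_mean_fa(fa: ScalarVolume, skeleton: BinaryMask, fa_floor: float = 0.2) -> TractFA:
    """Mean FA over skeleton voxels whose FA exceeds ``fa_floor``.

    Returns the mean and the number of voxels that survived the floor.
    """
    _check_grid(fa, skeleton)
    if skeleton.n_voxels == 0:
        raise EmptyMaskError("empty tract skeleton")
    vals = fa.data[skeleton.data]
    vals = vals[vals > fa_floor]
    if vals.size == 0:
        raise ValueError(f"no skeleton voxel has FA > {fa_floor}")
    return TractFA(float(vals.mean()), int(vals.size))


@dataclass(frozen=True)
class SliceLateralityProfile:
    """Per-axial-slice laterality of FA along a tract pair.

    Only slices where both tracts contribute at least one voxel above the
    FA floor carry a value; others are excluded (LI is undefined there).
    """

    z_indices: np.ndarray  # int, ascending
    li: np.ndarray         # float, same length
    n_intact: np.ndarray   # voxels used on the intact/dominant side
    n_other: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.z_indices)
        if not (len(self.li) == len(self.n_intact) == len(self.n_other) == n):
            raise ValueError("profile arrays must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_index": np.asarray(self.z_indices, int),
                "li": np.asarray(self.li, float),
                "n_intact": np.asarray(self.n_intact, int),
                "n_other": np.asarray(self.n_other, int),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def slice_laterality_profile(
    fa: ScalarVolume,
    left_tract: BinaryMask,
    right_tract: BinaryMask,
    intact_side: str,
    fa_floor: float = 0.2,
) -> SliceLateralityProfile:
    """Slice-wise laterality along the superior-inferior (z) axis.

    For every z slice where both tract skeletons have at least one voxel
    above the FA floor, computes LI of the slice-wise mean FA with the
    intact-side tract as numerator term A.
    """
    _check_grid(fa, left_tract)
    _check_grid(fa, right_tract)
    if left_tract.n_voxels == 0 or right_tract.n_voxels == 0:
        raise EmptyMaskError("empty tract skeleton")
    if intact_side not in ("left", "right"):
        raise ValueError("intact_side must be 'left' or 'right'")
    a_mask = left_tract if intact_side == "left" else right_tract
    b_mask = right_tract if intact_side == "left" else left_tract

    zs, lis, n_a, n_b = [], [], [], []
    for z in range(fa.grid.shape[2]):
        va = fa.data[:, :, z][a_mask.data[:, :, z]]
        vb = fa.data[:, :, z][b_mask.data[:, :, z]]
        va = va[va > fa_floor]
        vb = vb[vb > fa_floor]
        if va.size == 0 or vb.size == 0:
            continue
        zs.append(z)
        lis.append(laterality_index(float(va.mean()), float(vb.mean())))
        n_a.append(va.size)
        n_b.append(vb.size)
    if not zs:
        raise ValueError("no slice has skeleton voxels on both sides")
    return SliceLateralityProfile(
        np.array(zs, int), np.array(lis, float), np.array(n_a, int), np.array(n_b, int)
    )
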