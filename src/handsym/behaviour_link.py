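"""Brain-behaviour coupling: connectivity versus compensatory limb use.

The behaviour score is a bimanual-usage index: how often a one-hander
incorporates the residual arm into typically two-handed daily tasks.
Only one-handers carry a score; controls have none. Two analyses relate
the score to inter-hemispheric connectivity:

* a voxel-wise correlation map across subjects (with parametric
  one-tailed p-values, FDR-corrected downstream), and
* a single ROI-level correlation with a one-tailed randomisation p.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .imggeom import BinaryMask, ScalarVolume, _check_grid
from .perm_stats import PermResult, perm_test_correlation

__all__ = [
    "load_behaviour_table",
    "save_behaviour_table",
    "voxelwise_behaviour_corr",
    "roi_behaviour_corr",
]

_GROUPS = ("one_hander", "control")


def load_behaviour_table(path: str | Path) -> pd.DataFrame:
    """Read a behaviour TSV (subject_id, group, usage_index, flip).

    Validates unique subject ids, known group labels, and that every
    one-hander carries a usage score.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "group", "usage_index", "flip"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"behaviour table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    bad = set(df["group"]) - set(_GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    oh = df[df["group"] == "one_hander"]
    if oh["usage_index"].isna().any():
        raise ValueError("every one-hander needs a usage_index")
    df["flip"] = df["flip"].astype(bool)
    return df


def save_behaviour_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def voxelwise_behaviour_corr(maps, scores, brain: BinaryMask):
    """Correlate connectivity maps with behaviour scores voxel by voxel.

    ``maps`` is a list of per-subject Fisher-z connectivity volumes,
    ``scores`` the matching usage indices (n >= 4, non-constant). Returns
    (r map, one-tailed p map): per voxel the Pearson r across subjects
    and the p of the positive tail via t = r*sqrt(n-2)/sqrt(1-r^2) with
    n-2 degrees of freedom. Voxels with non-finite or constant
    connectivity values are NaN.
    """
    scores = np.asarray(scores, float)
    n = scores.size
    if len(maps) != n:
        raise ValueError("one map per score required")
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(scores) == 0:
        raise ValueError("behaviour scores are constant")
    for m in maps:
        _check_grid(m, brain)
    mat = np.stack([m.data[brain.data] for m in maps])  # (n, n_vox)
    finite = np.isfinite(mat).all(axis=0)
    s0 = scores - scores.mean()
    m0 = mat - mat.mean(axis=0)
    nm = np.sqrt((m0 ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (s0 @ m0) / (nm * np.sqrt((s0 ** 2).sum()))
        t = r * np.sqrt(n - 2) / np.sqrt(np.maximum(1.0 - r ** 2, 0.0))
    bad = ~finite | (nm == 0)
    r[bad] = np.nan
    t[bad] = np.nan
    p = stats.t.sf(t, n - 2)  # one-tailed, positive
    r_map = np.full(brain.grid.shape, np.nan)
    p_map = np.full(brain.grid.shape, np.nan)
    r_map[brain.data] = r
    p_map[brain.data] = p
    return ScalarVolume(brain.grid, r_map), ScalarVolume(brain.grid, p_map)


def roi_behaviour_corr(
    conn_values,
    scores,
    n_iter: int = 10000,
    seed: int = 0,
) -> tuple[float, PermResult]:
    """ROI-level brain-behaviour randomisation test.

    Pearson r between per-subject inter-hemispheric connectivity values
    and usage scores, with a one-tailed (positive) permutation p obtained
    by shuffling the connectivity values against the unshuffled scores.
    """
    res = perm_test_correlation(conn_values, scores, n_iter=n_iter, seed=seed, tail="greater")
    return res.observed, res
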