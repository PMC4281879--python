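"""Randomisation tests, 1-D TFCE cluster statistics and FDR correction.

Conventions shared by every test here:

* Monte-Carlo p-values use the add-one rule p = (1 + b) / (n_iter + 1),
  where b counts null draws at least as extreme as the observed statistic
  (ties count as extreme). p can therefore never be 0 and the test is
  exact-level under exchangeability.
* ``tail`` is one of ``"two_sided"`` (extremity of |stat|), ``"greater"``
  or ``"less"``.
* When group sizes are unequal, the null distribution can optionally be
  built after randomly subsampling the larger group to ``subsample_to``
  members, redrawn independently on every iteration; the observed
  statistic is always computed on the full groups. This equates group
  sizes inside the null without discarding observed data.
* Every result records its seed and iteration count; the same seed gives
  a bit-identical result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermResult",
    "TfceParams",
    "TfceResult",
    "perm_test_mean_diff",
    "exhaustive_perm_pvalue",
    "perm_test_correlation",
    "tfce_enhance",
    "tfce_permutation_test",
    "bh_fdr",
]

_TAILS = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class PermResult:
    """Outcome of a randomisation test."""

    observed: float
    n_iter: int
    p_value: float
    seed: int
    tail: str
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "stat": self.observed,
            "p": self.p_value,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "tail": self.tail,
            "degenerate": self.degenerate,
        }


def _count_extreme(null: np.ndarray, observed: float, tail: str) -> int:
    # ties count as extreme (conservative); the tolerance keeps float
    # round-off from dropping relabellings that are ties in exact
    # arithmetic (e.g. the identity labelling itself)
    tol = 1e-12 * max(1.0, abs(observed))
    if tail == "two_sided":
        return int(np.count_nonzero(np.abs(null) >= abs(observed) - tol))
    if tail == "greater":
        return int(np.count_nonzero(null >= observed - tol))
    if tail == "less":
        return int(np.count_nonzero(null <= observed + tol))
    raise ValueError(f"tail must be one of {_TAILS}, got {tail!r}")


def _null_pool_indices(
    rng: np.random.Generator,
    n_iter: int,
    n1: int,
    n2: int,
    subsample_to: int | None,
):
    """Build (n_iter, pool) index matrices into the concatenated data.

    Returns (idx, m1): per-iteration pooled subject indices (after any
    subsampling of the larger group) in shuffled order, and the size m1 of
    the pseudo first group (the first m1 columns).
    """
    n = n1 + n2
    if subsample_to is None:
        idx = np.argsort(rng.random((n_iter, n)), axis=1)
        return idx, n1
    if subsample_to > max(n1, n2):
        raise ValueError("subsample_to exceeds the larger group size")
    # Subsample the larger group (ties: the second group) to subsample_to.
    if n1 > n2:
        keep1, keep2 = subsample_to, n2
        big_idx = np.argsort(rng.random((n_iter, n1)), axis=1)[:, :subsample_to]
        pool = np.concatenate([big_idx, np.broadcast_to(np.arange(n1, n), (n_iter, n2))], axis=1)
    else:
        keep1, keep2 = n1, subsample_to
        big_idx = n1 + np.argsort(rng.random((n_iter, n2)), axis=1)[:, :subsample_to]
        pool = np.concatenate([np.broadcast_to(np.arange(n1), (n_iter, n1)), big_idx], axis=1)
    m = keep1 + keep2
    shuf = np.argsort(rng.random((n_iter, m)), axis=1)
    idx = np.take_along_axis(pool, shuf, axis=1)
    return idx, keep1


def perm_test_mean_diff(
    g1,
    g2,
    n_iter: int = 10000,
    subsample_to: int | None = None,
    seed: int = 0,
    tail: str = "two_sided",
) -> PermResult:
    """Randomisation test for a difference in group means.

    Observed statistic: mean(g1) - mean(g2) on the full groups. The null
    is built by shuffling pooled group labels, optionally after equating
    group sizes by subsampling the larger group each iteration.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 members")
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}, got {tail!r}")
    observed = float(g1.mean() - g2.mean())
    pooled = np.concatenate([g1, g2])
    if np.ptp(pooled) == 0:
        return PermResult(observed, n_iter, 1.0, seed, tail, degenerate=True)
    rng = np.random.default_rng(seed)
    idx, m1 = _null_pool_indices(rng, n_iter, g1.size, g2.size, subsample_to)
    vals = pooled[idx]
    null = vals[:, :m1].mean(axis=1) - vals[:, m1:].mean(axis=1)
    b = _count_extreme(null, observed, tail)
    return PermResult(observed, n_iter, (1 + b) / (n_iter + 1), seed, tail)


def exhaustive_perm_pvalue(g1, g2, tail: str = "two_sided") -> float:
    """Exact permutation p for the mean difference, over every labelling.

    Enumerates all C(n1+n2, n1) assignments of the pooled values to the
    first group (no subsampling, no add-one correction); the Monte-Carlo
    test converges to this as n_iter grows. Limited to 1e5 assignments.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    n1, n = g1.size, g1.size + g2.size
    total = math.comb(n, n1)
    if total > 100_000:
        raise ValueError(f"{total} label assignments exceed the enumeration limit")
    pooled = np.concatenate([g1, g2])
    observed = g1.mean() - g2.mean()
    grand = pooled.sum()
    count = 0
    for combo in combinations(range(n), n1):
        s1 = pooled[list(combo)].sum()
        stat = s1 / n1 - (grand - s1) / (n - n1)
        if tail == "two_sided":
            count += abs(stat) >= abs(observed) - 1e-12
        elif tail == "greater":
            count += stat >= observed - 1e-12
        elif tail == "less":
            count += stat <= observed + 1e-12
        else:
            raise ValueError(f"tail must be one of {_TAILS}, got {tail!r}")
    return count / total


def perm_test_correlation(
    x,
    y,
    n_iter: int = 10000,
    seed: int = 0,
    tail: str = "greater",
) -> PermResult:
    """Randomisation test for a Pearson correlation.

    The null is built by shuffling ``x`` against the unshuffled ``y``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}, got {tail!r}")
    x0 = x - x.mean()
    y0 = y - y.mean()
    denom = np.sqrt((x0 ** 2).sum() * (y0 ** 2).sum())
    if denom == 0:
        raise ValueError("zero variance in x or y")
    observed = float((x0 * y0).sum() / denom)
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_iter, x.size)), axis=1)
    null = (x0[perms] @ y0) / denom  # permutation preserves ||x0||
    b = _count_extreme(null, observed, tail)
    return PermResult(observed, n_iter, (1 + b) / (n_iter + 1), seed, tail)


# ---------------------------------------------------------------------------
# Threshold-free cluster enhancement on 1-D profiles.


@dataclass(frozen=True)
class TfceParams:
    """TFCE settings: extent exponent E, height exponent H, height step dh.

    E=1, H=2 with a small dh is the usual convention for skeletonised
    (effectively one-dimensional) statistics.
    """

    E: float = 1.0
    H: float = 2.0
    dh: float = 0.1
    n_perm: int = 10000

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0 or self.dh <= 0:
            raise ValueError("E, H and dh must be positive")


def _tfce_batch(stats: np.ndarray, E: float, H: float, dh: float) -> np.ndarray:
    """TFCE-enhance each row of a (n_profiles, L) statistic matrix.

    TFCE(p) = sum over thresholds h = dh, 2dh, ..., <= stat(p) of
    extent(p, h)^E * h^H * dh, where extent(p, h) is the length of the
    contiguous run of positions with stat >= h that contains p. Negative
    values contribute nothing (positive tail).
    """
    stats = np.asarray(stats, float)
    if not np.all(np.isfinite(stats)):
        raise ValueError("non-finite values in TFCE input")
    P, L = stats.shape
    out = np.zeros_like(stats)
    hmax = stats.max(initial=0.0)
    if hmax < dh:
        return out
    idx = np.arange(L)
    n_steps = int(np.floor(hmax / dh + 1e-9))
    for k in range(1, n_steps + 1):
        h = k * dh
        m = stats >= h - 1e-12
        if not m.any():
            break
        prev = np.zeros_like(m)
        prev[:, 1:] = m[:, :-1]
        starts = np.where(m & ~prev, idx, -1)
        start_fill = np.maximum.accumulate(starts, axis=1)
        nxt = np.zeros_like(m)
        nxt[:, :-1] = m[:, 1:]
        ends = np.where(m & ~nxt, idx, L)
        end_fill = np.minimum.accumulate(ends[:, ::-1], axis=1)[:, ::-1]
        extent = (end_fill - start_fill + 1).astype(float)
        out += np.where(m, extent ** E * h ** H * dh, 0.0)
    return out


def tfce_enhance(stat_profile, params: TfceParams = TfceParams()) -> np.ndarray:
    """TFCE enhancement of a single 1-D statistic profile."""
    profile = np.atleast_2d(np.asarray(stat_profile, float))
    return _tfce_batch(profile, params.E, params.H, params.dh)[0]


def _group_t_rows(vals: np.ndarray, m1: int) -> np.ndarray:
    """Pooled-variance two-sample t per column block.

    ``vals`` has shape (n_iter, n_subj, L); the first m1 subjects of every
    row form group 1. Zero-pooled-variance positions give t = 0.
    """
    n1 = m1
    n2 = vals.shape[1] - m1
    a = vals[:, :m1, :]
    b = vals[:, m1:, :]
    ma = a.mean(axis=1)
    mb = b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


@dataclass(frozen=True)
class TfceResult:
    """Familywise-corrected slice-wise TFCE permutation test outcome."""

    z_indices: np.ndarray
    observed_t: np.ndarray
    enhanced: np.ndarray
    corrected_p: np.ndarray
    n_perm: int
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "z_index": np.asarray(self.z_indices, int),
                "t": self.observed_t,
                "tfce": self.enhanced,
                "p_corrected": self.corrected_p,
            }
        )


def tfce_permutation_test(
    profiles,
    labels,
    params: TfceParams = TfceParams(),
    seed: int = 0,
    subsample_to: int | None = None,
    z_indices=None,
    batch: int = 256,
) -> TfceResult:
    """Slice-wise group comparison with TFCE and max-statistic correction.

    ``profiles`` is either an (n_subjects, L) array of laterality values
    on a common slice set, or a list of SliceLateralityProfile objects
    (which must share identical slice indices). ``labels`` is a boolean
    array marking group-1 membership (e.g. the one-handers). The observed
    per-slice statistic is the pooled two-sample t (group 1 minus group
    2), TFCE-enhanced on its positive tail; the null is the maximum
    enhanced value across slices under label shuffles (with the same
    optional subsampling of the larger group as the mean-difference
    test). Corrected p per slice = (1 + #{max_null >= enhanced}) /
    (n_perm + 1), controlling the familywise error across slices.
    """
    if hasattr(profiles[0], "li"):
        z0 = np.asarray(profiles[0].z_indices)
        for p in profiles[1:]:
            if not np.array_equal(np.asarray(p.z_indices), z0):
                raise ValueError("subjects have mismatched slice index sets")
        data = np.stack([np.asarray(p.li, float) for p in profiles])
        z_indices = z0
    else:
        data = np.asarray(profiles, float)
        if z_indices is None:
            z_indices = np.arange(data.shape[1])
    labels = np.asarray(labels, bool)
    if labels.size != data.shape[0]:
        raise ValueError("labels length does not match number of subjects")
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")

    # Observed statistic on the full groups, in group1-first order.
    ordered = np.concatenate([data[labels], data[~labels]])
    obs_t = _group_t_rows(ordered[None, :, :], n1)[0]
    obs_enh = _tfce_batch(obs_t[None, :], params.E, params.H, params.dh)[0]

    rng = np.random.default_rng(seed)
    n_perm = params.n_perm
    max_null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        nb = min(batch, n_perm - done)
        idx, m1 = _null_pool_indices(rng, nb, n1, n2, subsample_to)
        vals = ordered[idx]  # (nb, pool, L)
        t_null = _group_t_rows(vals, m1)
        enh = _tfce_batch(t_null, params.E, params.H, params.dh)
        max_null[done : done + nb] = enh.max(axis=1)
        done += nb
    b = (max_null[:, None] >= obs_enh[None, :] - 1e-12).sum(axis=0)
    corrected_p = (1 + b) / (n_perm + 1)
    return TfceResult(np.asarray(z_indices), obs_t, obs_enh, corrected_p, n_perm, seed)


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR correction.

    Returns (reject flags, adjusted p-values) for the given p-values at
    FDR level ``q``.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
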