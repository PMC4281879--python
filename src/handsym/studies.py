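"""Calibration, power and parameter-recovery studies.

These functions run many replicates of the generative model through the
statistical pipeline to measure operating characteristics: type-I error
of the randomisation tests, detection power at configured effect sizes,
and recovery of the generator's target brain-behaviour correlation.

For the functional replicates the per-subject statistic only involves
the two smoothed ROI mean time-courses. Because nuisance regression and
high-pass filtering apply one common temporal projection to every voxel,
and Gaussian smoothing is linear and symmetric, the smoothed ROI mean
equals a fixed voxel weighting w = smooth(ROI indicator)/|ROI| applied
to the unsmoothed data, and the temporal projections commute with that
weighting. Replicates therefore simulate the voxel field only on the
(finite) support of w and reduce it immediately - an exact shortcut for
the reported statistics, not an approximation (verified against the full
image pipeline in the test suite).
"""

from __future__ import annotations

import numpy as np

from .fa_laterality import laterality_index
from .perm_stats import (
    TfceParams,
    exhaustive_perm_pvalue,
    perm_test_correlation,
    perm_test_mean_diff,
    tfce_permutation_test,
)
from .rsfc import fisher_z, preprocess_series
from .synthdata import (
    CohortConfig,
    _fa_tract_values,
    _simulate_bold_field,
    coupling_slope_for_target,
    make_masks,
    roi_smoothing_weights,
)

__all__ = [
    "simulate_roi_connectivity_cohort",
    "simulate_tract_li_cohort",
    "perm_oracle_check",
    "type1_mean_diff",
    "type1_correlation",
    "type1_tfce",
    "power_roi_connectivity",
    "power_tract_laterality",
    "behaviour_recovery",
]


def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


class _RoiModel:
    """Cached mask geometry and smoothing weights for one configuration."""

    def __init__(self, config: CohortConfig):
        self.config = config
        self.masks = make_masks(config.grid)
        w = roi_smoothing_weights(self.masks, config)
        self.support = (w["left"] > 0) | (w["right"] > 0)
        self.w_left = w["left"][self.support]
        self.w_right = w["right"][self.support]


def simulate_roi_connectivity_cohort(
    config: CohortConfig, seed: int, model: _RoiModel | None = None
) -> dict:
    """One cohort's per-subject preprocessed ROI-ROI connectivity.

    Returns arrays: ``z`` (Fisher-z inter-ROI connectivity per subject),
    ``is_patient``, ``usage`` (NaN for controls) and the true ``rho``.
    """
    model = model or _RoiModel(config)
    cfg = config
    ss = np.random.SeedSequence(seed)
    n_total = cfg.n_patients + cfg.n_controls
    cohort_ss, *subj_ss = ss.spawn(1 + n_total)
    crng = np.random.default_rng(cohort_ss)
    usage_p = crng.uniform(*cfg.usage_range, size=cfg.n_patients)
    b = cfg.slope if cfg.slope is not None else coupling_slope_for_target(cfg, model.masks)
    rho_p = np.clip(cfg.rho0 + b * usage_p, 0.0, 0.95)

    z = np.empty(n_total)
    usage = np.full(n_total, np.nan)
    rho = np.empty(n_total)
    is_patient = np.zeros(n_total, bool)
    for i in range(n_total):
        patient = i < cfg.n_patients
        r_i = float(rho_p[i]) if patient else cfg.rho_control
        rng = np.random.default_rng(subj_ss[i])
        X, conf = _simulate_bold_field(cfg, r_i, model.masks, rng, model.support)
        y = np.vstack([model.w_left @ X, model.w_right @ X])
        y = preprocess_series(y, conf.to_numpy().T, cfg.tr, cfg.highpass_s)
        z[i] = fisher_z(np.corrcoef(y[0], y[1])[0, 1])
        rho[i] = r_i
        is_patient[i] = patient
        if patient:
            usage[i] = usage_p[i]
    return {"z": z, "usage": usage, "rho": rho, "is_patient": is_patient}


def simulate_tract_li_cohort(config: CohortConfig, seed: int, masks=None, fa_floor: float = 0.2) -> dict:
    """One cohort's per-subject tract-level FA laterality indices."""
    masks = masks or make_masks(config.grid)
    cfg = config
    n_total = cfg.n_patients + cfg.n_controls
    ss = np.random.SeedSequence(seed)
    _, *subj_ss = ss.spawn(1 + n_total)
    li = np.empty(n_total)
    is_patient = np.zeros(n_total, bool)
    for i in range(n_total):
        group = "one_hander" if i < cfg.n_patients else "control"
        rng = np.random.default_rng(subj_ss[i])
        lv, rv = _fa_tract_values(cfg, group, masks, rng)
        lv, rv = lv[lv > fa_floor], rv[rv > fa_floor]
        li[i] = laterality_index(float(lv.mean()), float(rv.mean()))
        is_patient[i] = group == "one_hander"
    return {"li": li, "is_patient": is_patient}


# ---------------------------------------------------------------------------
# Operating-characteristic studies


def perm_oracle_check(seed: int, n_iter: int = 10000) -> list[dict]:
    """Monte-Carlo vs exhaustive permutation p on small instances.

    Returns per instance the two p-values and the binomial standard
    error of the Monte-Carlo estimate.
    """
    rng = np.random.default_rng(seed)
    results = []
    for n1, n2 in ((3, 3), (4, 4), (5, 5), (4, 6)):
        g1 = rng.standard_normal(n1) + 0.8
        g2 = rng.standard_normal(n2)
        p_ex = exhaustive_perm_pvalue(g1, g2, tail="two_sided")
        p_mc = perm_test_mean_diff(
            g1, g2, n_iter=n_iter, seed=int(rng.integers(2**31)), tail="two_sided"
        ).p_value
        se = float(np.sqrt(p_ex * (1 - p_ex) / n_iter))
        results.append({"n1": n1, "n2": n2, "p_exhaustive": p_ex, "p_mc": p_mc, "se": se})
    return results


def type1_mean_diff(
    n_sims: int = 1000,
    n1: int = 14,
    n2: int = 23,
    subsample_to: int | None = 14,
    n_iter: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the (subsampled) group-mean randomisation test
    under a standard-normal global null."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_sims):
        g1 = rng.standard_normal(n1)
        g2 = rng.standard_normal(n2)
        res = perm_test_mean_diff(
            g1, g2, n_iter=n_iter, subsample_to=subsample_to,
            seed=int(rng.integers(2**31)),
        )
        rej += res.p_value <= alpha
    return rej / n_sims


def type1_correlation(
    n_sims: int = 1000, n: int = 14, n_iter: int = 999, alpha: float = 0.05, seed: int = 0
) -> float:
    """Type-I error of the correlation randomisation test under
    independence."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_sims):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        res = perm_test_correlation(
            x, y, n_iter=n_iter, seed=int(rng.integers(2**31)), tail="greater"
        )
        rej += res.p_value <= alpha
    return rej / n_sims


def type1_tfce(
    n_sims: int = 1000,
    n1: int = 14,
    n2: int = 23,
    n_slices: int = 16,
    subsample_to: int | None = 14,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Familywise error of the slice-wise TFCE permutation test: the
    fraction of null cohorts in which any slice reaches corrected
    p <= alpha."""
    params = TfceParams(n_perm=n_perm)
    rng = np.random.default_rng(seed)
    labels = np.array([True] * n1 + [False] * n2)
    rej = 0
    for _ in range(n_sims):
        data = rng.standard_normal((n1 + n2, n_slices))
        res = tfce_permutation_test(
            data, labels, params, seed=int(rng.integers(2**31)), subsample_to=subsample_to
        )
        rej += bool((res.corrected_p <= alpha).any())
    return rej / n_sims


def power_roi_connectivity(
    config: CohortConfig,
    n_reps: int = 100,
    n_iter: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicate cohorts in which the ROI-ROI group
    randomisation test detects the configured coupling difference."""
    model = _RoiModel(config)
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        cohort = simulate_roi_connectivity_cohort(config, int(rng.integers(2**31)), model)
        res = perm_test_mean_diff(
            cohort["z"][cohort["is_patient"]],
            cohort["z"][~cohort["is_patient"]],
            n_iter=n_iter,
            subsample_to=config.n_patients,
            seed=int(rng.integers(2**31)),
        )
        rej += res.p_value <= alpha
    return rej / n_reps


def power_tract_laterality(
    config: CohortConfig,
    n_reps: int = 100,
    n_iter: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicate cohorts in which the tract-LI group
    randomisation test detects the configured FA asymmetry."""
    masks = make_masks(config.grid)
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        cohort = simulate_tract_li_cohort(config, int(rng.integers(2**31)), masks)
        res = perm_test_mean_diff(
            cohort["li"][cohort["is_patient"]],
            cohort["li"][~cohort["is_patient"]],
            n_iter=n_iter,
            subsample_to=config.n_patients,
            seed=int(rng.integers(2**31)),
        )
        rej += res.p_value <= alpha
    return rej / n_reps


def behaviour_recovery(config: CohortConfig, n_reps: int = 200, seed: int = 0) -> dict:
    """Mean recovered usage-connectivity correlation across replicates.

    Each replicate generates a cohort from the coupling law and
    correlates the patients' measured Fisher-z connectivity with their
    usage scores; the mean sample r estimates how faithfully the
    generator realises its target brain-behaviour correlation.
    """
    model = _RoiModel(config)
    rng = np.random.default_rng(seed)
    rs = np.empty(n_reps)
    for k in range(n_reps):
        cohort = simulate_roi_connectivity_cohort(config, int(rng.integers(2**31)), model)
        pat = cohort["is_patient"]
        rs[k] = np.corrcoef(cohort["z"][pat], cohort["usage"][pat])[0, 1]
    return {"mean_r": float(rs.mean()), "sd_r": float(rs.std(ddof=1)), "n_reps": n_reps}
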