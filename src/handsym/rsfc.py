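"""Resting-state preprocessing and seed-based connectivity statistics.

The preprocessing chain applied to each subject's BOLD image is:

1. temporal high-pass filtering (:func:`highpass`) with a 150 s cutoff,
   implemented as regression on a discrete-cosine drift basis,
2. nuisance regression (:func:`regress_out`) of motion parameters and
   ventricle / white-matter mean time-courses - themselves high-passed
   with the same basis, so the regression cannot reintroduce drift -
   on the unsmoothed data,
3. spatial Gaussian smoothing (:func:`gaussian_smooth`, 8 mm FWHM).

:func:`preprocess_series` / :func:`preprocess_bold` bundle steps 1-2 and
1-3 respectively. Connectivity is then the Pearson correlation of a seed
ROI's mean time-course with every brain voxel (or with a second ROI),
reported on the Fisher-z scale. All steps are deterministic linear
operations: identical inputs give identical maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, stats

from .imggeom import BinaryMask, BoldImage, EmptyMaskError, ScalarVolume, _check_grid, mean_timecourse

__all__ = [
    "ConnectivityValue",
    "regress_out",
    "preprocess_series",
    "preprocess_bold",
    "highpass",
    "dct_drift_basis",
    "gaussian_smooth",
    "fisher_z",
    "seed_map",
    "group_diff_map",
    "roi_connectivity",
    "variance_controls",
    "FWHM_TO_SIGMA",
]

# FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ConnectivityValue:
    """A Pearson correlation and its Fisher-z transform."""

    r: float
    z: float


def regress_out(data: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each series on [intercept, confounds].

    ``data`` is (n_series, T), ``confounds`` is (n_confounds, T). The
    intercept removes each series' mean together with the confound fit.
    Rank-deficient confound matrices are rejected with the offending
    columns named.
    """
    data = np.atleast_2d(np.asarray(data, float))
    confounds = np.atleast_2d(np.asarray(confounds, float))
    if data.shape[1] != confounds.shape[1]:
        raise ValueError("data and confounds must share the time dimension")
    T = data.shape[1]
    X = np.column_stack([np.ones(T), confounds.T])  # (T, k+1)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name collinear columns: those whose removal does not drop the rank
        bad = [
            j - 1
            for j in range(1, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"confound matrix is rank deficient; collinear rows: {bad}")
    beta, *_ = np.linalg.lstsq(X, data.T, rcond=None)
    return data - (X @ beta).T


def dct_drift_basis(T: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift regressors with frequencies below 1/cutoff_s.

    Returns a (n_basis, T) matrix of DCT-II functions
    cos(pi*k*(2t+1)/(2T)) for k = 1 .. K, K the largest k with
    k / (2*T*tr) < 1/cutoff_s. May be empty when the scan is short
    relative to the cutoff.
    """
    t = np.arange(T)
    K = int(np.ceil(2.0 * T * tr / cutoff_s)) - 1
    return np.array([np.cos(np.pi * k * (2 * t + 1) / (2 * T)) for k in range(1, K + 1)])


def highpass(data: np.ndarray, tr: float, cutoff_s: float = 150.0) -> np.ndarray:
    """Remove fluctuations slower than ``cutoff_s`` from each series.

    Regresses out the discrete-cosine drift basis and re-adds each
    series' mean, so constants pass through unchanged. Warns when the
    total scan duration is shorter than twice the cutoff (the drift basis
    is then very small and the filter weak).
    """
    data = np.atleast_2d(np.asarray(data, float))
    T = data.shape[1]
    if T * tr < 2.0 * cutoff_s:
        warnings.warn(
            f"scan duration {T * tr:.0f}s is below twice the {cutoff_s:.0f}s cutoff; "
            "the high-pass filter has little effect",
            stacklevel=2,
        )
    basis = dct_drift_basis(T, tr, cutoff_s)
    mean = data.mean(axis=1, keepdims=True)
    if basis.size == 0:
        return data.copy()
    return regress_out(data - mean, basis) + mean


def preprocess_series(
    data: np.ndarray, confounds: np.ndarray, tr: float, cutoff_s: float = 150.0
) -> np.ndarray:
    """Temporal cleaning shared by every series-level analysis.

    High-passes the data and the confound courses with the same
    discrete-cosine basis, then regresses the filtered confounds (plus
    an intercept) out of the filtered data. Filtering the confounds with
    the identical basis is what makes the two projections consistent: a
    confound regression with unfiltered regressors would reintroduce the
    drift components that the filter just removed (and vice versa).
    """
    data_f = highpass(data, tr, cutoff_s)
    conf_f = highpass(np.atleast_2d(np.asarray(confounds, float)), tr, cutoff_s)
    return regress_out(data_f, conf_f)


def preprocess_bold(
    bold: BoldImage,
    confounds: np.ndarray,
    cutoff_s: float = 150.0,
    fwhm_mm: float = 8.0,
) -> BoldImage:
    """Full per-subject BOLD preprocessing.

    Temporal cleaning (:func:`preprocess_series`) voxel-wise on the
    unsmoothed data, followed by spatial Gaussian smoothing.
    """
    X = bold.data.reshape(-1, bold.n_frames)
    X = preprocess_series(X, confounds, bold.tr, cutoff_s)
    cleaned = BoldImage(bold.grid, X.reshape(bold.data.shape), tr=bold.tr)
    return gaussian_smooth(cleaned, fwhm_mm)


def _smooth_sigmas(grid, fwhm_mm: float) -> tuple[float, float, float]:
    return tuple(fwhm_mm * FWHM_TO_SIGMA / v for v in grid.voxel_size)


def gaussian_smooth(img, fwhm_mm: float = 8.0):
    """Spatial Gaussian smoothing of a 3-D or 4-D image.

    The kernel width is given as full-width-at-half-maximum in mm and
    converted to voxel-wise sigmas via the grid's voxel sizes; 4-D input
    is smoothed frame-wise (no temporal blurring). Symmetric (reflect)
    boundary handling preserves constants. ``fwhm_mm = 0`` is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be nonnegative")
    if fwhm_mm == 0:
        return replace(img, data=img.data.copy())
    sig = _smooth_sigmas(img.grid, fwhm_mm)
    if isinstance(img, BoldImage):
        out = ndimage.gaussian_filter(img.data, sigma=(*sig, 0.0), mode="reflect")
    else:
        out = ndimage.gaussian_filter(img.data, sigma=sig, mode="reflect")
    return replace(img, data=out)


def fisher_z(r, clamp: float = 0.999999):
    """Fisher's r-to-z transform atanh(r), with |r| clamped below 1."""
    r = np.clip(np.asarray(r, float), -clamp, clamp)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def _corr_with_series(series: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Pearson r of a reference series against each row of ``mat``.

    Rows with zero variance yield NaN.
    """
    s0 = series - series.mean()
    ns = np.sqrt((s0 ** 2).sum())
    m0 = mat - mat.mean(axis=1, keepdims=True)
    nm = np.sqrt((m0 ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (m0 @ s0) / (nm * ns)
    r[nm == 0] = np.nan
    return r


def seed_map(
    bold: BoldImage,
    seed: BinaryMask,
    brain: BinaryMask,
    clamp: float = 0.999999,
) -> ScalarVolume:
    """Fisher-z map of correlation between the seed mean series and every
    brain voxel.

    Voxels outside the brain mask, and brain voxels with a constant
    series, are flagged NaN. Raises if the seed's mean time-course is
    constant.
    """
    _check_grid(bold, seed)
    _check_grid(bold, brain)
    if seed.n_voxels == 0 or brain.n_voxels == 0:
        raise EmptyMaskError("seed and brain masks must be nonempty")
    if bold.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation map")
    seed_ts = mean_timecourse(bold, seed)
    if np.ptp(seed_ts) == 0:
        raise ValueError("seed mean time-course is constant")
    r = _corr_with_series(seed_ts, bold.data[brain.data])
    out = np.full(bold.grid.shape, np.nan)
    valid = ~np.isnan(r)
    vox = np.where(brain.data)
    out[vox[0][valid], vox[1][valid], vox[2][valid]] = fisher_z(r[valid], clamp)
    return ScalarVolume(bold.grid, out)


def group_diff_map(maps_g1, maps_g2, brain: BinaryMask):
    """Voxel-wise pooled-variance two-sample t test between two groups of
    maps.

    The t statistic is mean(g2) - mean(g1) over the pooled standard
    error, i.e. positive where group 2 exceeds group 1 (call with
    (one-handers, controls) for the controls > one-handers contrast).
    Returns (t map, two-sided p map) with n1+n2-2 degrees of freedom;
    voxels with zero pooled variance, any non-finite input, or outside
    the brain mask are NaN.
    """
    if len(maps_g1) < 2 or len(maps_g2) < 2:
        raise ValueError("need at least 2 maps per group")
    for m in (*maps_g1, *maps_g2):
        _check_grid(m, brain)
    a = np.stack([m.data[brain.data] for m in maps_g1])
    b = np.stack([m.data[brain.data] for m in maps_g2])
    n1, n2 = a.shape[0], b.shape[0]
    df = n1 + n2 - 2
    finite = np.isfinite(a).all(axis=0) & np.isfinite(b).all(axis=0)
    sp2 = ((n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (b.mean(axis=0) - a.mean(axis=0)) / se
    t[~finite | (se == 0)] = np.nan
    p = 2.0 * stats.t.sf(np.abs(t), df)
    t_map = np.full(brain.grid.shape, np.nan)
    p_map = np.full(brain.grid.shape, np.nan)
    t_map[brain.data] = t
    p_map[brain.data] = p
    return ScalarVolume(brain.grid, t_map), ScalarVolume(brain.grid, p_map)


def roi_connectivity(
    bold: BoldImage,
    roi_a: BinaryMask,
    roi_b: BinaryMask,
    clamp: float = 0.999999,
) -> ConnectivityValue:
    """Pearson correlation (and Fisher z) between two ROI mean
    time-courses. Symmetric in its ROI arguments."""
    ts_a = mean_timecourse(bold, roi_a)
    ts_b = mean_timecourse(bold, roi_b)
    if np.ptp(ts_a) == 0 or np.ptp(ts_b) == 0:
        raise ValueError("constant ROI mean time-course")
    r = float(np.corrcoef(ts_a, ts_b)[0, 1])
    return ConnectivityValue(r, fisher_z(r, clamp))


def variance_controls(bold: BoldImage, mask: BinaryMask) -> tuple[float, float]:
    """Signal-amplitude controls for an ROI.

    Returns (temporal variance of the ROI mean series, mean over voxels
    of each voxel's temporal variance) - the two quantities compared
    between groups to rule out SNR differences as the source of a
    connectivity effect. Sample variances (ddof=1).
    """
    ts = mean_timecourse(bold, mask)
    var_of_mean = float(ts.var(ddof=1))
    mean_voxel_var = float(bold.data[mask.data].var(axis=1, ddof=1).mean())
    return var_of_mean, mean_voxel_var
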