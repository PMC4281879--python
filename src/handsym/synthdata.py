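"""Synthetic cohort generator.

Produces complete one-hander / control cohorts - 4-D BOLD images, FA
volumes, mirror-paired masks, confound tables and behaviour scores -
with the second-order statistical structure the analysis pipeline
assumes, so that every stage can be exercised and calibrated without any
real data.

Generative model
----------------
Every subject is generated in a canonical orientation in which the
*left* hemisphere is the one contralateral to the intact (or dominant)
hand; the right-hemisphere hand region is therefore the missing-hand
(or nondominant) territory used as the connectivity seed. A configurable
subset of subjects is then stored mirror-flipped, emulating scanners'
mixed handedness; the pipeline must un-flip them.

BOLD: two latent Gaussian sources with correlation rho drive the left
and right hand ROIs; every voxel additionally carries white Gaussian
noise, slow drift, and motion / ventricle / white-matter nuisance
courses with voxel-specific gains. The recorded confound table contains
the true nuisance courses (6 motion + ventricle + white matter), so
nuisance regression can remove them exactly; drift is left to the
high-pass filter. For controls rho = rho_c; for one-handers rho follows
the coupling law rho_i = rho0 + b * usage_i (clipped to [0, 0.95]),
which ties inter-hemispheric coupling to the bimanual-usage score.

FA: tract-skeleton voxels are drawn around side- and group-specific
means (with a per-subject, per-side random offset), giving one-handers a
lower mean on the residual side and hence a positive expected laterality
index; non-tract voxels get low background FA. An optional z-localised
"bump" deepens the asymmetry on a chosen slice range for cluster-level
testing.

One master seed drives everything through numpy SeedSequence spawning:
stream 0 generates cohort-level draws (usage scores, flip flags), then
one child stream per subject generates that subject's images.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .imggeom import (
    BinaryMask,
    BoldImage,
    ImageGrid,
    ScalarVolume,
    flip_lr,
    mirror_mask,
    save_bold,
    save_mask,
    save_volume,
)
from .rsfc import FWHM_TO_SIGMA, dct_drift_basis

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "SyntheticCohort",
    "make_masks",
    "simulate_subject_bold",
    "simulate_subject_fa",
    "generate_cohort",
    "coupling_slope_for_target",
]

_CONFOUND_COLS = [
    "trans_x",
    "trans_y",
    "trans_z",
    "rot_x",
    "rot_y",
    "rot_z",
    "ventricle",
    "white_matter",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the analysed samples of the study the pipeline
    emulates: 14 one-handers vs 23 controls, 128 BOLD volumes at TR
    2.41 s, 4 of 14 and 8 of 23 subjects stored mirror-flipped. Control
    inter-ROI coupling is rho_c; one-hander coupling follows
    rho0 + slope * usage with usage uniform on ``usage_range``. When
    ``slope`` is None it is solved so that the population correlation
    between usage and measured Fisher-z connectivity equals
    ``target_behaviour_r`` (see :func:`coupling_slope_for_target`).
    """

    n_patients: int = 14
    n_controls: int = 23
    shape: tuple[int, int, int] = (32, 32, 24)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    T: int = 128
    tr: float = 2.41
    # functional effect structure
    rho_control: float = 0.6
    rho0: float = 0.1
    slope: float | None = None
    target_behaviour_r: float = 0.66
    usage_range: tuple[float, float] = (0.0, 1.0)
    source_sd: float = 1.0
    noise_sd: float = 1.0
    motion_amp: float = 0.3
    nuisance_amp: float = 0.5
    drift_amp: float = 2.0
    baseline: float = 100.0
    # structural effect structure: (intact/dominant side, other side)
    fa_patient: tuple[float, float] = (0.50, 0.44)
    fa_control: tuple[float, float] = (0.50, 0.48)
    fa_voxel_sd: float = 0.08
    fa_subject_sd: float = 0.02
    fa_background: float = 0.12
    fa_background_sd: float = 0.02
    fa_bump_slices: tuple[int, int] | None = None
    fa_bump_delta: float = 0.0
    # flip handling
    n_flip_patients: int = 4
    n_flip_controls: int = 8
    # preprocessing parameters assumed when calibrating the coupling law
    fwhm_mm: float = 8.0
    highpass_s: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not 0 <= self.rho_control <= 0.95 or not 0 <= self.rho0 <= 0.95:
            raise ValueError("couplings must lie in [0, 0.95]")
        if not (0 <= self.n_flip_patients <= self.n_patients):
            raise ValueError("invalid n_flip_patients")
        if not (0 <= self.n_flip_controls <= self.n_controls):
            raise ValueError("invalid n_flip_controls")
        if self.T < 2 or self.tr <= 0:
            raise ValueError("invalid BOLD dimensions")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(self.shape, self.voxel_size)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        d["voxel_size"] = list(self.voxel_size)
        d["usage_range"] = list(self.usage_range)
        d["fa_patient"] = list(self.fa_patient)
        d["fa_control"] = list(self.fa_control)
        if self.fa_bump_slices is not None:
            d["fa_bump_slices"] = list(self.fa_bump_slices)
        return d


@dataclass
class SubjectRecord:
    """One synthetic subject: labels, ground truth and image handles."""

    subject_id: str
    group: str  # "one_hander" | "control"
    flipped: bool
    usage: float | None
    rho: float
    bold: BoldImage | None = None
    fa: ScalarVolume | None = None
    confounds: pd.DataFrame | None = None
    paths: dict = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    subjects: list[SubjectRecord]
    masks: dict[str, BinaryMask]
    manifest: dict

    @property
    def patients(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "one_hander"]

    @property
    def controls(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "control"]


# ---------------------------------------------------------------------------
# Masks


def _sphere(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


def make_masks(grid: ImageGrid) -> dict[str, BinaryMask]:
    """Construct the shared mask set on a grid.

    Returns left/right hand ROIs (spheres in the upper part of the
    volume), left/right tract skeletons (columns of voxels descending
    along z), and a brain mask (an ellipsoid containing all of them).
    Right-sided masks are exact mirrors of the left ones; ROIs and
    tracts are disjoint. Raises when the grid is too small to hold the
    geometry.
    """
    nx, ny, nz = grid.shape
    if nx < 16 or ny < 12 or nz < 14:
        raise ValueError(f"grid {grid.shape} too small for disjoint bilateral masks")
    xl = round(0.25 * (nx - 1))
    yc = ny // 2
    z_roi = round(0.78 * (nz - 1))
    roi_left = np.zeros(grid.shape, bool)
    roi_left |= _sphere(grid.shape, (xl, yc, z_roi), 2.0)

    tract_left = np.zeros(grid.shape, bool)
    z_top = round(0.55 * (nz - 1))
    tract_left[xl - 1 : xl + 2, yc - 1 : yc + 2, 2 : z_top + 1] = True

    brain = np.zeros(grid.shape, bool)
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ax_, ay, az = 0.47 * nx, 0.47 * ny, 0.54 * nz
    gx, gy, gz = np.ogrid[0:nx, 0:ny, 0:nz]
    brain = ((gx - cx) / ax_) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2 <= 1.0

    masks = {
        "roi_left": BinaryMask(grid, roi_left, side="left"),
        "tract_left": BinaryMask(grid, tract_left, side="left"),
    }
    masks["roi_right"] = mirror_mask(masks["roi_left"])
    masks["tract_right"] = mirror_mask(masks["tract_left"])
    masks["brain"] = BinaryMask(grid, brain, side="bilateral")

    if (roi_left & tract_left).any():
        raise ValueError("grid too small: ROI and tract overlap")
    if (roi_left & masks["roi_right"].data).any():
        raise ValueError("grid too small: bilateral ROIs overlap")
    for name in ("roi_left", "roi_right", "tract_left", "tract_right"):
        if not masks[name].data[brain].sum() == masks[name].n_voxels:
            raise ValueError(f"grid too small: {name} not contained in brain mask")
    return masks


# ---------------------------------------------------------------------------
# BOLD simulation


def _ar1(rng: np.random.Generator, T: int, n: int, phi: float = 0.95) -> np.ndarray:
    """n unit-variance AR(1) series of length T."""
    innov = rng.standard_normal((n, T)) * np.sqrt(1 - phi ** 2)
    out = np.empty((n, T))
    out[:, 0] = rng.standard_normal(n)
    for t in range(1, T):
        out[:, t] = phi * out[:, t - 1] + innov[:, t]
    return out


def _confound_courses(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    motion = config.motion_amp * _ar1(rng, config.T, 6)
    nuis = config.nuisance_amp * _ar1(rng, config.T, 2, phi=0.9)
    return pd.DataFrame(np.vstack([motion, nuis]).T, columns=_CONFOUND_COLS)


def _drift_courses(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Scanner drift: a linear ramp plus a random mix of the two slowest
    cosine harmonics of the scan (periods 2*T*tr and T*tr seconds, both
    well below the high-pass cutoff frequency for the default scan)."""
    t = np.arange(config.T)
    linear = t / (config.T - 1) - 0.5
    c = rng.uniform(-1.0, 1.0, size=2)
    slow = c[0] * np.cos(np.pi * (2 * t + 1) / (2 * config.T)) + c[1] * np.cos(
        2 * np.pi * (2 * t + 1) / (2 * config.T)
    )
    return config.drift_amp * np.vstack([linear, slow])


def _simulate_bold_field(
    config: CohortConfig,
    rho: float,
    masks: dict[str, BinaryMask],
    rng: np.random.Generator,
    where: np.ndarray,
):
    """Simulate the BOLD field at the voxels selected by ``where``.

    Returns (X, confounds): X is (n_selected, T) in C-order of the
    selected voxels. The same generative model regardless of the
    selection, so restricting ``where`` to a neighbourhood of the ROIs
    yields a draw from the identical distribution at those voxels.
    """
    if not 0 <= rho <= 0.95:
        raise ValueError(f"coupling must lie in [0, 0.95], got {rho}")
    T = config.T
    a1 = rng.standard_normal(T)
    a2 = rng.standard_normal(T)
    s_left = config.source_sd * a1
    s_right = config.source_sd * (rho * a1 + np.sqrt(1.0 - rho ** 2) * a2)

    conf = _confound_courses(config, rng)
    drift = _drift_courses(config, rng)
    nuisance = np.vstack([conf.to_numpy().T, drift])  # (10, T)

    n_vox = int(where.sum())
    gains = 1.0 + 0.3 * rng.standard_normal((n_vox, nuisance.shape[0]))
    X = config.baseline + gains @ nuisance
    X += config.noise_sd * rng.standard_normal((n_vox, T))
    X[masks["roi_left"].data[where]] += s_left
    X[masks["roi_right"].data[where]] += s_right
    return X, conf


def simulate_subject_bold(
    config: CohortConfig,
    rho: float,
    masks: dict[str, BinaryMask],
    rng: np.random.Generator,
) -> tuple[BoldImage, pd.DataFrame]:
    """Simulate one subject's full 4-D BOLD image plus confound table.

    The two hand ROIs carry latent sources with correlation ``rho``; all
    voxels carry noise, drift, and the recorded nuisance courses.
    """
    grid = config.grid
    where = np.ones(grid.shape, bool)
    X, conf = _simulate_bold_field(config, rho, masks, rng, where)
    return BoldImage(grid, X.reshape(*grid.shape, config.T), tr=config.tr), conf


# ---------------------------------------------------------------------------
# FA simulation


def _fa_tract_values(
    config: CohortConfig, group: str, masks: dict[str, BinaryMask], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw FA values for the (left, right) tract-skeleton voxels.

    Left is the intact/dominant side in canonical orientation. Values
    are clipped to [0, 1]. The optional bump lowers the residual-side
    mean further on a z-slice range, for one-handers only.
    """
    mu_a, mu_b = config.fa_patient if group == "one_hander" else config.fa_control
    offs = config.fa_subject_sd * rng.standard_normal(2)
    out = []
    for side, mu, off in (("left", mu_a, offs[0]), ("right", mu_b, offs[1])):
        m = masks[f"tract_{side}"]
        vals = mu + off + config.fa_voxel_sd * rng.standard_normal(m.n_voxels)
        if (
            side == "right"
            and group == "one_hander"
            and config.fa_bump_slices is not None
            and config.fa_bump_delta != 0.0
        ):
            zlo, zhi = config.fa_bump_slices
            zs = np.where(m.data)[2]
            vals = vals - config.fa_bump_delta * ((zs >= zlo) & (zs <= zhi))
        out.append(np.clip(vals, 0.0, 1.0))
    return out[0], out[1]


def simulate_subject_fa(
    config: CohortConfig,
    group: str,
    masks: dict[str, BinaryMask],
    rng: np.random.Generator,
) -> ScalarVolume:
    """Simulate one subject's FA volume in canonical orientation."""
    grid = config.grid
    data = np.clip(
        config.fa_background + config.fa_background_sd * rng.standard_normal(grid.shape),
        0.0,
        1.0,
    )
    left_vals, right_vals = _fa_tract_values(config, group, masks, rng)
    data[masks["tract_left"].data] = left_vals
    data[masks["tract_right"].data] = right_vals
    return ScalarVolume(grid, data)


# ---------------------------------------------------------------------------
# Coupling-law calibration


def roi_smoothing_weights(
    masks: dict[str, BinaryMask], config: CohortConfig
) -> dict[str, np.ndarray]:
    """Adjoint weights of "smooth, then average over the ROI".

    Because Gaussian smoothing is linear and symmetric, the ROI mean of
    a smoothed image equals the w-weighted sum of the unsmoothed image
    with w = smooth(ROI indicator) / ROI size. Returned per side as full
    3-D weight arrays.
    """
    sig = tuple(config.fwhm_mm * FWHM_TO_SIGMA / v for v in config.voxel_size)
    out = {}
    for side in ("left", "right"):
        ind = masks[f"roi_{side}"].data.astype(float)
        w = ndimage.gaussian_filter(ind, sigma=sig, mode="reflect")
        out[side] = w / ind.sum()
    return out


def _measured_r_for_slope(b: float, config: CohortConfig, atten: float, eps_var: float) -> float:
    """Population correlation between usage and measured Fisher z."""
    u0, u1 = config.usage_range
    u = np.linspace(u0, u1, 2001)
    rho = np.clip(config.rho0 + b * u, 0.0, 0.95)
    z = np.arctanh(atten * rho)
    cov = np.mean((z - z.mean()) * (u - u.mean()))
    var_z = z.var() + eps_var
    return cov / np.sqrt(var_z * u.var())


def coupling_slope_for_target(
    config: CohortConfig, masks: dict[str, BinaryMask] | None = None
) -> float:
    """Solve the usage-coupling slope for a target brain-behaviour r.

    Model: the measured per-subject Fisher z is atanh(a * rho_i) plus
    measurement noise of variance 1/(T_eff - 3), where the attenuation a
    accounts for voxel noise entering the smoothed ROI means and T_eff
    is the number of frames left after nuisance and drift regression.
    The slope b is found by root-finding on the population correlation
    between usage and measured z.
    """
    if masks is None:
        masks = make_masks(config.grid)
    w = roi_smoothing_weights(masks, config)
    # signal retention and noise passthrough of the smoothed ROI mean
    w_l = w["left"]
    w_in = w_l[masks["roi_left"].data].sum()
    sum_w2 = (w_l ** 2).sum()
    atten = 1.0 / (1.0 + config.noise_sd ** 2 * sum_w2 / (config.source_sd ** 2 * w_in ** 2))
    n_drift = len(dct_drift_basis(config.T, config.tr, config.highpass_s))
    t_eff = config.T - 1 - len(_CONFOUND_COLS) - n_drift
    eps_var = 1.0 / max(t_eff - 3, 1)

    target = config.target_behaviour_r
    u1 = config.usage_range[1]
    b_hi = (0.95 - config.rho0) / max(u1, 1e-9)
    f = lambda b: _measured_r_for_slope(b, config, atten, eps_var) - target
    if f(b_hi) < 0:
        raise ValueError(
            f"target behaviour r={target} unreachable with rho0={config.rho0}"
        )
    return float(optimize.brentq(f, 1e-6, b_hi, xtol=1e-6))


# ---------------------------------------------------------------------------
# Cohort assembly


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def generate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> SyntheticCohort:
    """Generate a full cohort; optionally write it to disk.

    Patients' usage scores are drawn first, couplings derived from the
    coupling law, then each subject's images are generated from an
    independent child seed stream; flip-flagged subjects are stored with
    their images actually mirror flipped (the analysis must un-flip
    them). When ``out_dir`` is given, NIfTI volumes, confound TSVs, the
    behaviour table and a manifest JSON (with array checksums) are
    written there; arrays stay available in memory either way.
    """
    grid = config.grid
    masks = make_masks(grid)
    n_total = config.n_patients + config.n_controls
    ss = np.random.SeedSequence(config.seed)
    cohort_ss, *subj_ss = ss.spawn(1 + n_total)
    crng = np.random.default_rng(cohort_ss)

    usage = crng.uniform(*config.usage_range, size=config.n_patients)
    b = config.slope if config.slope is not None else coupling_slope_for_target(config, masks)
    rho_patients = np.clip(config.rho0 + b * usage, 0.0, 0.95)
    flip_p = np.zeros(config.n_patients, bool)
    flip_p[crng.choice(config.n_patients, config.n_flip_patients, replace=False)] = True
    flip_c = np.zeros(config.n_controls, bool)
    flip_c[crng.choice(config.n_controls, config.n_flip_controls, replace=False)] = True

    subjects: list[SubjectRecord] = []
    for i in range(n_total):
        patient = i < config.n_patients
        group = "one_hander" if patient else "control"
        rho = float(rho_patients[i]) if patient else config.rho_control
        rec = SubjectRecord(
            subject_id=f"sub-{i + 1:02d}",
            group=group,
            flipped=bool(flip_p[i] if patient else flip_c[i - config.n_patients]),
            usage=float(usage[i]) if patient else None,
            rho=rho,
        )
        rng = np.random.default_rng(subj_ss[i])
        bold, conf = simulate_subject_bold(config, rho, masks, rng)
        fa = simulate_subject_fa(config, group, masks, rng)
        if rec.flipped:
            bold = flip_lr(bold)
            fa = flip_lr(fa)
        rec.bold, rec.fa, rec.confounds = bold, fa, conf
        subjects.append(rec)

    manifest = {
        "config": config.to_dict(),
        "coupling_slope": float(b),
        "n_subjects": n_total,
        "subjects": [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "flipped": s.flipped,
                "usage": s.usage,
                "rho": s.rho,
                "bold_sha": _checksum(s.bold.data),
                "fa_sha": _checksum(s.fa.data),
            }
            for s in subjects
        ],
    }

    if out_dir is not None:
        out = Path(out_dir)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for name, m in masks.items():
            save_mask(m, out / "masks" / f"{name}.nii.gz")
        for s in subjects:
            s.paths = {
                "bold": f"{s.subject_id}_bold.nii.gz",
                "fa": f"{s.subject_id}_fa.nii.gz",
                "confounds": f"{s.subject_id}_confounds.tsv",
            }
            save_bold(s.bold, out / s.paths["bold"])
            save_volume(s.fa, out / s.paths["fa"])
            s.confounds.to_csv(out / s.paths["confounds"], sep="\t", index=False)
        behaviour = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in subjects],
                "group": [s.group for s in subjects],
                "usage_index": [s.usage for s in subjects],
                "flip": [s.flipped for s in subjects],
            }
        )
        behaviour.to_csv(out / "behaviour.tsv", sep="\t", index=False)
        for entry, s in zip(manifest["subjects"], subjects):
            entry["paths"] = s.paths
        manifest["mask_paths"] = {n: f"masks/{n}.nii.gz" for n in masks}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return SyntheticCohort(config, subjects, masks, manifest)
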