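"""Orchestration of the three analyses on a cohort.

``run_structural`` compares corticospinal FA laterality between
one-handers and controls (tract-level randomisation test plus the
slice-wise TFCE cluster test); ``run_connectivity`` runs the seed-based
resting-state comparison (voxel-wise group t map with FDR, ROI-ROI
randomisation test, variance controls); ``run_behaviour`` relates
inter-hemispheric connectivity to the bimanual-usage index (voxel-wise
correlation map with FDR, ROI-level randomisation test).

Subjects flagged as flipped are mirror-unflipped before any analysis,
restoring the canonical orientation in which the left hemisphere is the
one contralateral to the intact / dominant hand; the shared masks are
defined in that orientation, with the right-hemisphere hand ROI (the
missing-hand territory, the mirror of the intact-hand ROI) as the
connectivity seed.

Every p-value written to the report is accompanied by its seed and
iteration count. Reports contain no timestamps or absolute paths, so a
fixed configuration and master seed reproduce them byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .behaviour_link import roi_behaviour_corr, voxelwise_behaviour_corr
from .fa_laterality import laterality_index, slice_laterality_profile, tract_mean_fa
from .imggeom import (
    BinaryMask,
    flip_lr,
    load_bold,
    load_mask,
    load_volume,
    mean_in_mask,
)
from .perm_stats import (
    TfceParams,
    bh_fdr,
    perm_test_correlation,
    perm_test_mean_diff,
    tfce_permutation_test,
)
from .rsfc import (
    group_diff_map,
    preprocess_bold,
    roi_connectivity,
    seed_map,
    variance_controls,
)
from .synthdata import CohortConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger("handsym")

__all__ = ["AnalysisConfig", "load_cohort", "run_structural", "run_connectivity",
           "run_behaviour", "run_all", "write_report"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Statistical parameters and seeds for one pipeline run.

    Defaults are the study's printed parameters: 10,000 randomisation
    iterations, FDR q = 0.05, 150 s high-pass, 8 mm FWHM smoothing.
    """

    n_iter: int = 10000
    q_fdr: float = 0.05
    tfce: TfceParams = TfceParams()
    highpass_s: float = 150.0
    fwhm_mm: float = 8.0
    clamp: float = 0.999999
    fa_floor: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1 or not 0 < self.q_fdr < 1:
            raise ValueError("invalid statistical parameters")
        if self.highpass_s <= 0 or self.fwhm_mm < 0 or not 0 < self.clamp < 1:
            raise ValueError("invalid preprocessing parameters")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tfce = TfceParams(**raw.pop("tfce", {}))
        return cls(tfce=tfce, **raw)

    def seeds(self) -> dict[str, int]:
        """Named child seeds for each randomisation test, derived from
        the master seed (all below 2**31)."""
        names = [
            "tract_li",
            "tfce",
            "li_usage",
            "roi_conn",
            "var_mean",
            "var_voxel",
            "behaviour_roi",
        ]
        ss = np.random.SeedSequence(self.seed)
        vals = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(names))]
        return dict(zip(names, vals))


def load_cohort(manifest_path: str | Path) -> SyntheticCohort:
    """Load a cohort previously written by the generator from its
    manifest JSON (images are loaded lazily into memory here)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cfg_d = dict(manifest["config"])
    for key in ("shape", "voxel_size", "usage_range", "fa_patient", "fa_control"):
        cfg_d[key] = tuple(cfg_d[key])
    if cfg_d.get("fa_bump_slices") is not None:
        cfg_d["fa_bump_slices"] = tuple(cfg_d["fa_bump_slices"])
    config = CohortConfig(**cfg_d)
    masks = {
        name: load_mask(root / rel, side="left" if "left" in name else
                        "right" if "right" in name else "bilateral")
        for name, rel in manifest["mask_paths"].items()
    }
    from .synthdata import SubjectRecord  # local import to avoid cycle noise
    import pandas as pd

    subjects = []
    missing = []
    for entry in manifest["subjects"]:
        paths = entry["paths"]
        try:
            bold = load_bold(root / paths["bold"], tr=config.tr)
            fa = load_volume(root / paths["fa"])
            conf = pd.read_csv(root / paths["confounds"], sep="\t")
        except FileNotFoundError:
            missing.append(entry["subject_id"])
            continue
        subjects.append(
            SubjectRecord(
                subject_id=entry["subject_id"],
                group=entry["group"],
                flipped=entry["flipped"],
                usage=entry["usage"],
                rho=entry["rho"],
                bold=bold,
                fa=fa,
                confounds=conf,
                paths=paths,
            )
        )
    if missing:
        raise FileNotFoundError(f"cohort files missing for subjects: {missing}")
    return SyntheticCohort(config, subjects, masks, manifest)


def _unflip(img, flagged: bool):
    return flip_lr(img) if flagged else img


def run_structural(cohort: SyntheticCohort, config: AnalysisConfig) -> dict:
    """Tract-level and slice-wise FA laterality group comparison."""
    t0 = time.time()
    seeds = config.seeds()
    masks = cohort.masks
    lis, profiles, groups, usages = [], [], [], []
    for s in cohort.subjects:
        fa = _unflip(s.fa, s.flipped)
        a = tract_mean_fa(fa, masks["tract_left"], config.fa_floor)
        b = tract_mean_fa(fa, masks["tract_right"], config.fa_floor)
        lis.append(laterality_index(a.mean_fa, b.mean_fa))
        profiles.append(
            slice_laterality_profile(
                fa, masks["tract_left"], masks["tract_right"], "left", config.fa_floor
            )
        )
        groups.append(s.group)
        usages.append(s.usage)
    lis = np.array(lis)
    is_patient = np.array([g == "one_hander" for g in groups])
    n_pat = int(is_patient.sum())

    group_test = perm_test_mean_diff(
        lis[is_patient],
        lis[~is_patient],
        n_iter=config.n_iter,
        subsample_to=n_pat,
        seed=seeds["tract_li"],
    )
    tfce_res = tfce_permutation_test(
        [p for p, pat in zip(profiles, is_patient) if pat]
        + [p for p, pat in zip(profiles, is_patient) if not pat],
        np.array([True] * n_pat + [False] * int((~is_patient).sum())),
        dataclasses.replace(config.tfce, n_perm=config.n_iter),
        seed=seeds["tfce"],
        subsample_to=n_pat,
    )
    # FA laterality vs usage in the patient group (both tails reported;
    # the directional hypothesis is negative: more residual-arm use,
    # less asymmetry).
    pat_usage = np.array([u for u, pat in zip(usages, is_patient) if pat], float)
    li_usage_less = perm_test_correlation(
        lis[is_patient], pat_usage, n_iter=config.n_iter, seed=seeds["li_usage"], tail="less"
    )
    li_usage_greater = perm_test_correlation(
        lis[is_patient], pat_usage, n_iter=config.n_iter, seed=seeds["li_usage"], tail="greater"
    )
    block = {
        "n_patients": n_pat,
        "n_controls": int((~is_patient).sum()),
        "mean_li_patients": float(lis[is_patient].mean()),
        "mean_li_controls": float(lis[~is_patient].mean()),
        "group_test": group_test.to_dict(),
        "tfce": {
            "z_indices": [int(z) for z in tfce_res.z_indices],
            "t": [float(v) for v in tfce_res.observed_t],
            "p_corrected": [float(v) for v in tfce_res.corrected_p],
            "n_significant_slices": int((tfce_res.corrected_p <= 0.05).sum()),
            "n_perm": tfce_res.n_perm,
            "seed": tfce_res.seed,
        },
        "li_usage": {
            "r": li_usage_less.observed,
            "p_less": li_usage_less.p_value,
            "p_greater": li_usage_greater.p_value,
            "n_iter": config.n_iter,
            "seed": seeds["li_usage"],
        },
    }
    logger.info("structural analysis: %d subjects in %.1fs", len(lis), time.time() - t0)
    return block


def _preprocessed_subjects(cohort: SyntheticCohort, config: AnalysisConfig):
    """Un-flip, clean and smooth every subject's BOLD image."""
    out = []
    for s in cohort.subjects:
        bold = _unflip(s.bold, s.flipped)
        conf = s.confounds.to_numpy().T
        out.append(preprocess_bold(bold, conf, config.highpass_s, config.fwhm_mm))
    return out


def run_connectivity(
    cohort: SyntheticCohort, config: AnalysisConfig, preprocessed=None
) -> tuple[dict, list]:
    """Seed-based connectivity group comparison plus SNR controls.

    Returns the report block and the per-subject Fisher-z seed maps
    (patients first in cohort order), for reuse by the behaviour
    analysis.
    """
    t0 = time.time()
    seeds = config.seeds()
    masks = cohort.masks
    seed_roi = masks["roi_right"]  # missing/nondominant hand territory
    brain = masks["brain"]
    if preprocessed is None:
        preprocessed = _preprocessed_subjects(cohort, config)
    is_patient = np.array([s.group == "one_hander" for s in cohort.subjects])
    n_pat = int(is_patient.sum())

    maps, conn_z, var_mean, var_vox = [], [], [], []
    for bold in preprocessed:
        maps.append(seed_map(bold, seed_roi, brain, config.clamp))
        conn_z.append(roi_connectivity(bold, masks["roi_left"], seed_roi, config.clamp).z)
        vm, vv = variance_controls(bold, seed_roi)
        var_mean.append(vm)
        var_vox.append(vv)
    conn_z = np.array(conn_z)
    var_mean = np.array(var_mean)
    var_vox = np.array(var_vox)

    pat_maps = [m for m, p in zip(maps, is_patient) if p]
    ctl_maps = [m for m, p in zip(maps, is_patient) if not p]
    t_map, p_map = group_diff_map(pat_maps, ctl_maps, brain)
    pvals = p_map.data[brain.data]
    finite = np.isfinite(pvals)
    reject, _ = bh_fdr(pvals[finite], config.q_fdr)
    n_missing = int((~finite).sum())
    if n_missing:
        logger.warning("%d brain voxels flagged missing in the group map", n_missing)

    roi_test = perm_test_mean_diff(
        conn_z[is_patient], conn_z[~is_patient],
        n_iter=config.n_iter, subsample_to=n_pat, seed=seeds["roi_conn"],
    )
    var_mean_test = perm_test_mean_diff(
        var_mean[is_patient], var_mean[~is_patient],
        n_iter=config.n_iter, subsample_to=n_pat, seed=seeds["var_mean"],
    )
    var_vox_test = perm_test_mean_diff(
        var_vox[is_patient], var_vox[~is_patient],
        n_iter=config.n_iter, subsample_to=n_pat, seed=seeds["var_voxel"],
    )
    block = {
        "n_patients": n_pat,
        "n_controls": int((~is_patient).sum()),
        "mean_z_patients": float(conn_z[is_patient].mean()),
        "mean_z_controls": float(conn_z[~is_patient].mean()),
        "roi_test": roi_test.to_dict(),
        "group_map": {
            "n_brain_voxels": int(brain.n_voxels),
            "n_tested_voxels": int(finite.sum()),
            "n_missing_voxels": n_missing,
            "n_fdr_significant": int(reject.sum()),
            "q": config.q_fdr,
            "max_t": float(np.nanmax(t_map.data)),
        },
        "variance_controls": {
            "roi_mean_series": var_mean_test.to_dict(),
            "voxelwise": var_vox_test.to_dict(),
        },
    }
    logger.info("connectivity analysis: %d subjects in %.1fs", len(maps), time.time() - t0)
    return block, maps


def run_behaviour(
    cohort: SyntheticCohort, config: AnalysisConfig, subject_maps=None, preprocessed=None
) -> dict:
    """Brain-behaviour analysis in the one-hander group."""
    t0 = time.time()
    seeds = config.seeds()
    masks = cohort.masks
    brain = masks["brain"]
    is_patient = np.array([s.group == "one_hander" for s in cohort.subjects])
    scores = np.array(
        [s.usage for s, p in zip(cohort.subjects, is_patient) if p], float
    )
    if np.any(np.isnan(scores)):
        raise ValueError("missing usage scores for one or more one-handers")
    if subject_maps is None:
        _, subject_maps = run_connectivity(cohort, config, preprocessed)
    pat_maps = [m for m, p in zip(subject_maps, is_patient) if p]

    r_map, p_map = voxelwise_behaviour_corr(pat_maps, scores, brain)
    pvals = p_map.data[brain.data]
    finite = np.isfinite(pvals)
    reject, _ = bh_fdr(pvals[finite], config.q_fdr)

    # ROI-level test on mean connectivity under the intact-hand ROI
    conn = np.array([mean_in_mask(m, masks["roi_left"]) for m in pat_maps])
    r, perm = roi_behaviour_corr(conn, scores, n_iter=config.n_iter, seed=seeds["behaviour_roi"])
    block = {
        "n": int(scores.size),
        "voxelwise": {
            "n_tested_voxels": int(finite.sum()),
            "n_fdr_significant": int(reject.sum()),
            "q": config.q_fdr,
            "max_r": float(np.nanmax(r_map.data)),
        },
        "roi": perm.to_dict() | {"r": r},
    }
    logger.info("behaviour analysis: %d one-handers in %.1fs", scores.size, time.time() - t0)
    return block


def run_all(cohort: SyntheticCohort, config: AnalysisConfig) -> dict:
    """All three analyses, sharing one preprocessing pass."""
    preprocessed = _preprocessed_subjects(cohort, config)
    structural = run_structural(cohort, config)
    connectivity, maps = run_connectivity(cohort, config, preprocessed)
    behaviour = run_behaviour(cohort, config, subject_maps=maps)
    return {
        "software": {"name": "handsym", "version": __version__},
        "parameters": {
            "n_iter": config.n_iter,
            "q_fdr": config.q_fdr,
            "tfce": dataclasses.asdict(config.tfce),
            "highpass_s": config.highpass_s,
            "fwhm_mm": config.fwhm_mm,
            "clamp": config.clamp,
            "fa_floor": config.fa_floor,
            "seed": config.seed,
        },
        "structural": structural,
        "connectivity": connectivity,
        "behaviour": behaviour,
    }


def write_report(report: dict, path: str | Path) -> None:
    """Serialise a report deterministically (sorted keys, full float
    repr)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def simulate_cohort(config: CohortConfig, out_dir: str | Path) -> SyntheticCohort:
    """Convenience wrapper: generate and persist a cohort."""
    return generate_cohort(config, out_dir)
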