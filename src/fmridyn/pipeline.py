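"""Orchestration: per-subject analysis, group analysis, run manifests.

`run_subject` chains volume discard, motion QC, nuisance regression,
optional band-pass, sliding windows, the five dynamic indices, SD
variability maps (normalize then smooth) and the two concordance
summaries. `run_group` stacks the per-subject maps and runs the
voxel-wise permutation-corrected contrasts, the volume-wise ANCOVA and
the clinical partial correlations. Every run is deterministic given
(inputs, config, seed) and records SHA-256 hashes of its outputs in a
manifest.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .concordance import volumewise_concordance, voxelwise_concordance
from .groupstats import (
    StatMap,
    ancova_scalar,
    glm_tmap,
    partial_correlation,
    permutation_cluster_correct,
)
from .indices import INDEX_NAMES, compute_dynamic_stack
from .preprocess import (
    build_nuisance_design,
    discard_initial_volumes,
    framewise_displacement,
    mean_mask_signal,
    nuisance_regress,
    qc_exclude,
)
from .variability import gaussian_smooth, variability_maps
from .volio import AnalysisConfig, BoldSeries, MotionTrace
from .windows import plan_windows

logger = logging.getLogger("fmridyn")


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class SubjectResult:
    subject_id: str
    excluded: bool
    mean_fd: float
    n_windows: int | None = None
    variability: dict = field(default_factory=dict)  # index -> 3D map
    voxel_w: np.ndarray | None = None
    volume_w: float | None = None
    manifest: dict = field(default_factory=dict)


def run_subject(
    bold: BoldSeries,
    motion: MotionTrace,
    cfg: AnalysisConfig,
    subject_id: str = "sub-001",
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
) -> SubjectResult:
    """Full per-subject analysis; QC-excluded subjects yield no maps."""
    if motion.n_frames != bold.n_frames:
        raise ValueError("motion trace and BOLD series disagree on frame count")
    fd, mean_fd = framewise_displacement(motion, cfg.fd_sphere_radius_mm)
    retained, _ = qc_exclude(
        {subject_id: motion}, cfg.max_translation_mm, cfg.max_rotation_deg
    )
    manifest = {
        "subject_id": subject_id,
        "version": __version__,
        "config": cfg.to_dict(),
        "mean_fd": mean_fd,
    }
    if not retained:
        logger.warning("subject %s excluded by motion QC", subject_id)
        return SubjectResult(subject_id, True, mean_fd, manifest=manifest)

    series = discard_initial_volumes(bold, cfg.n_discard)
    trace = MotionTrace(motion.params[cfg.n_discard :])
    wm = mean_mask_signal(series, wm_mask) if wm_mask is not None else None
    csf = mean_mask_signal(series, csf_mask) if csf_mask is not None else None
    design = build_nuisance_design(trace, wm, csf)
    series = nuisance_regress(series, design)

    plan = plan_windows(series.n_frames, cfg.window_length, cfg.window_step, cfg.taper)
    stack = compute_dynamic_stack(series, plan, cfg)
    var = variability_maps(stack, series.voxel_size, cfg.smooth_fwhm, cfg.normalization)
    voxel_w_raw = voxelwise_concordance(stack)
    voxel_w = gaussian_smooth(
        voxel_w_raw, cfg.smooth_fwhm, series.voxel_size, series.mask
    )
    volume_w = volumewise_concordance(stack)
    manifest.update(
        {
            "n_windows": plan.n_windows,
            "n_mask_voxels": series.n_mask_voxels,
            "hashes": {
                **{f"var_{k}": _hash_array(v) for k, v in var.items()},
                "voxel_w": _hash_array(voxel_w),
            },
            "volume_w": volume_w,
        }
    )
    return SubjectResult(
        subject_id=subject_id,
        excluded=False,
        mean_fd=mean_fd,
        n_windows=plan.n_windows,
        variability=var,
        voxel_w=voxel_w,
        volume_w=volume_w,
        manifest=manifest,
    )


@dataclass
class GroupResult:
    stat_maps: dict  # map name -> StatMap with cluster p-values
    volume_w_ancova: dict
    correlations: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _covariate_matrix(
    cohort: pd.DataFrame, names: list[str]
) -> np.ndarray | None:
    if not names:
        return None
    cols = []
    for name in names:
        col = cohort[name]
        if col.dtype == object:  # e.g. gender -> 0/1 by order of appearance
            col = pd.factorize(col)[0]
        cols.append(np.asarray(col, dtype=float))
    return np.column_stack(cols)


def run_group(
    results: list[SubjectResult],
    cohort: pd.DataFrame,
    mask: np.ndarray,
    cfg: AnalysisConfig,
    covariates: list[str] | None = None,
    score_columns: list[str] | None = None,
    correlation_covariates: list[str] | None = None,
) -> GroupResult:
    """Group contrasts on variability and concordance maps, volume-wise
    ANCOVA, and covariate-adjusted clinical correlations.

    `covariates` enter the voxel-wise GLM (default none); correlations
    control for `correlation_covariates` (default: age, gender, iq,
    mean_fd when present).
    """
    usable = [r for r in results if not r.excluded]
    cohort = cohort.set_index("subject_id", drop=False)
    cohort = cohort.loc[[r.subject_id for r in usable]].reset_index(drop=True)
    groups = (cohort["group"] == "patient").astype(int).to_numpy()
    if min(np.bincount(groups, minlength=2)) < 2:
        raise ValueError("each group needs at least 2 QC-passing subjects")
    if "mean_fd" not in cohort.columns:
        cohort = cohort.assign(mean_fd=[r.mean_fd for r in usable])
    Z = _covariate_matrix(cohort, covariates or [])

    rng = np.random.default_rng(cfg.seed)
    stat_maps: dict[str, StatMap] = {}
    map_sets = {f"d{name}_sd": [r.variability[name] for r in usable]
                for name in INDEX_NAMES}
    map_sets["voxel_w"] = [r.voxel_w for r in usable]
    for name, maps in map_sets.items():
        stacked = np.stack(maps)
        sm = glm_tmap(stacked, groups, mask, Z)
        sm = permutation_cluster_correct(
            sm,
            stacked,
            groups,
            Z,
            cluster_forming_p=cfg.cluster_forming_p,
            n_perm=cfg.n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        stat_maps[name] = sm

    volume_w = np.array([r.volume_w for r in usable])
    corr_cov_names = correlation_covariates
    if corr_cov_names is None:
        corr_cov_names = [
            c for c in ("age", "gender", "iq", "mean_fd") if c in cohort.columns
        ]
    Zc = _covariate_matrix(cohort, corr_cov_names)
    ancova = ancova_scalar(volume_w, groups, Zc)

    corr_rows = []
    for col in score_columns or []:
        for grp_name in ("patient", "control"):
            sel = (cohort["group"] == grp_name).to_numpy()
            if sel.sum() > (0 if Zc is None else Zc.shape[1]) + 3:
                r, p = partial_correlation(
                    volume_w[sel],
                    cohort.loc[sel, col].to_numpy(dtype=float),
                    None if Zc is None else Zc[sel],
                )
                corr_rows.append(
                    {"score": col, "group": grp_name, "r": r, "p": p,
                     "n": int(sel.sum())}
                )
    correlations = pd.DataFrame(corr_rows)
    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "n_subjects": len(usable),
        "groups": dict(cohort["group"].value_counts()),
        "clusters": {
            name: [c for c in sm.clusters] for name, sm in stat_maps.items()
        },
    }
    return GroupResult(stat_maps, ancova, correlations, manifest)
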