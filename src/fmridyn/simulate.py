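"""Synthetic resting-state BOLD cohorts with planted, known ground truth.

Each voxel's signal is AR(1)+white noise plus structured components that
give every downstream index something real to detect:

- a band-limited (0.01-0.08 Hz) global component with a slowly varying
  amplitude envelope and a smooth, spatially varying loading field (GSC,
  and co-fluctuation of all indices over windows);
- a "dALFF" region sharing a band-limited carrier whose envelope depth
  differs by group (dynamic-amplitude variability effect);
- a "ReHo" region whose voxels mix a common local carrier with private
  carriers (local coherence);
- homotopic voxel pairs sharing per-pair carriers (VMHC);
- a hub voxel sharing a latent with scattered satellite voxels (DC);
- clinical scores generated as a linear function of a planted per-subject
  concordance scalar plus covariate loadings and Gaussian noise.

Everything is reproducible bit-exactly from (spec, seed). The default
geometry (24 x 24 x 16 voxels of 3 mm, 240 frames at TR = 2 s, two groups
of 20) keeps a full cohort analysis at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import lfilter

from .volio import BoldSeries, MotionTrace


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Brain-like ellipsoid mask, symmetric about the first-axis midplane."""
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    x, y, z = np.ogrid[:nx, :ny, :nz]
    rx, ry, rz = 0.46 * nx, 0.46 * ny, 0.44 * nz
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def _box(x0, x1, y0, y1, z0, z1, shape) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[x0:x1, y0:y1, z0:z1] = True
    return m


@dataclass
class SimulationSpec:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    shape: tuple = (24, 24, 16)
    voxel_size_mm: float = 3.0
    n_per_group: int = 20
    t: int = 240
    tr: float = 2.0
    ar1: float = 0.4
    noise_sd: float = 1.0
    band: tuple = (0.01, 0.08)
    # global + network components (independent envelopes; several sources
    # of co-fluctuation so concordance topography is not hostage to one
    # envelope realization)
    gsc_amp: float = 1.2
    network_amp: float = 1.0
    n_networks: int = 3
    global_env_depth: float = 1.2
    # dALFF region: carrier amplitude and group-specific envelope depths
    dalff_amp: float = 1.0
    dalff_depth_control: float = 0.4
    dalff_depth_patient: float = 0.8
    # ReHo region
    reho_amp: float = 1.0
    reho_coherence: float = 0.6
    # VMHC region
    vmhc_amp: float = 1.8
    vmhc_coupling: float = 0.9
    # DC hub
    hub_amp: float = 1.5
    hub_fanout: int = 150
    env_smooth_frames: float = 40.0  # envelope timescale >> window length
    seed: int = 0
    regions: dict = field(default_factory=dict)  # name -> 3D bool mask

    def __post_init__(self) -> None:
        if self.shape[0] % 2:
            raise ValueError("first dimension must be even (homotopic mirror)")
        for d in (
            self.dalff_depth_control,
            self.dalff_depth_patient,
            self.global_env_depth,
        ):
            if d < 0:
                raise ValueError("modulation depth must be >= 0")
        if not self.regions:
            s = self.shape
            self.regions = {
                "dalff": _box(14, 17, 10, 13, 6, 9, s),
                "reho": _box(8, 11, 14, 17, 6, 9, s),
                "vmhc_left": _box(3, 6, 10, 13, 6, 9, s),
            }

    @property
    def mask(self) -> np.ndarray:
        return _ellipsoid_mask(self.shape)


@dataclass
class SimulatedSubject:
    subject_id: str
    group: str
    series: BoldSeries


@dataclass
class SimulatedCohort:
    subjects: list
    table: pd.DataFrame
    truth: dict
    spec: SimulationSpec


def _band_limited(rng, t, tr, band, n=1) -> np.ndarray:
    """n unit-variance signals with spectrum restricted to the band."""
    x = rng.standard_normal((n, t))
    freqs = np.fft.rfftfreq(t, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(x, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=t, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _smooth_envelope(rng, t, depth, smooth_frames) -> np.ndarray:
    """Non-negative slowly varying envelope 1 + depth * e(t), e smooth, unit SD."""
    e = ndimage.gaussian_filter1d(rng.standard_normal(t), smooth_frames, mode="wrap")
    sd = e.std()
    if sd > 0:
        e = (e - e.mean()) / sd
    return np.maximum(1.0 + depth * e, 0.0)


def _ar1_noise(rng, n_vox, t, phi, sd) -> np.ndarray:
    eps = rng.standard_normal((n_vox, t)) * sd * np.sqrt(1.0 - phi**2)
    eps[:, 0] = rng.standard_normal(n_vox) * sd
    return lfilter([1.0], [1.0, -phi], eps, axis=1)


def simulate_bold_cohort(spec: SimulationSpec) -> SimulatedCohort:
    """Generate the full cohort of 4D BOLD series plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    mask = spec.mask
    for name, region in spec.regions.items():
        if not (region <= mask).all() or (region & ~mask).any():
            raise ValueError(f"region {name!r} extends outside the mask")
    V = int(mask.sum())
    lin = np.full(spec.shape, -1, dtype=np.int64)
    lin[mask] = np.arange(V)
    # region voxel indices in mask-linear space
    idx = {name: lin[region & mask] for name, region in spec.regions.items()}
    # homotopic partner region of vmhc_left
    vmhc_left = spec.regions["vmhc_left"]
    vmhc_right = vmhc_left[::-1, :, :].copy()
    if (vmhc_right & ~mask).any():
        raise ValueError("mirror of vmhc_left extends outside the mask")
    left_idx = lin[vmhc_left]
    # pair in matching order: mirror each left coordinate
    coords_left = np.argwhere(vmhc_left)
    coords_right = coords_left.copy()
    coords_right[:, 0] = spec.shape[0] - 1 - coords_left[:, 0]
    right_idx = lin[tuple(coords_right.T)]
    # hub + satellites: fixed across subjects, drawn once from the cohort rng
    planted = np.zeros(V, dtype=bool)
    for v in idx.values():
        planted[v] = True
    planted[right_idx] = True
    hub_pool = np.flatnonzero(~planted)
    hub_sat = rng.choice(hub_pool, size=spec.hub_fanout + 1, replace=False)
    hub, satellites = hub_sat[0], hub_sat[1:]
    # smooth spatially varying loading fields, shared by the cohort: the
    # first is the global component, further ones are network components
    def _loading_field():
        f = ndimage.gaussian_filter(rng.standard_normal(spec.shape), 2.0)
        f = 0.5 * (f + f[::-1])  # bilaterally symmetric, like real topographies
        return (f - f[mask].min()) / np.ptp(f[mask])

    lam3d = _loading_field()
    lam = lam3d[mask] * spec.gsc_amp
    net_loadings = [
        _loading_field()[mask] * spec.network_amp
        for _ in range(max(spec.n_networks - 1, 0))
    ]

    n = spec.n_per_group
    groups = ["patient"] * n + ["control"] * n
    subjects, rows = [], []
    depth_by_group = {
        "patient": spec.dalff_depth_patient,
        "control": spec.dalff_depth_control,
    }
    truth_regions = {
        "dalff": spec.regions["dalff"],
        "reho": spec.regions["reho"],
        "vmhc": vmhc_left | vmhc_right,
        "hub": np.isin(lin, hub_sat) & mask,
    }
    voxel_size = np.full(3, spec.voxel_size_mm)
    subject_depths = []
    for s, group in enumerate(groups):
        sid = f"sub-{s + 1:03d}"
        sig = _ar1_noise(rng, V, spec.t, spec.ar1, spec.noise_sd)
        # global component
        g = _band_limited(rng, spec.t, spec.tr, spec.band)[0]
        g *= _smooth_envelope(rng, spec.t, spec.global_env_depth, spec.env_smooth_frames)
        sig += lam[:, None] * g[None, :]
        for net_lam in net_loadings:
            h = _band_limited(rng, spec.t, spec.tr, spec.band)[0]
            h *= _smooth_envelope(
                rng, spec.t, spec.global_env_depth, spec.env_smooth_frames
            )
            sig += net_lam[:, None] * h[None, :]
        # dALFF region: shared carrier, group-dependent envelope depth
        depth = depth_by_group[group]
        cd = _band_limited(rng, spec.t, spec.tr, spec.band)[0]
        ed = _smooth_envelope(rng, spec.t, depth, spec.env_smooth_frames)
        sig[idx["dalff"]] += spec.dalff_amp * (cd * ed)[None, :]
        # ReHo region: common + private carriers
        k = idx["reho"].size
        cr = _band_limited(rng, spec.t, spec.tr, spec.band)[0]
        er = _smooth_envelope(rng, spec.t, 0.4, spec.env_smooth_frames)
        private = _band_limited(rng, spec.t, spec.tr, spec.band, n=k)
        rho = spec.reho_coherence
        sig[idx["reho"]] += spec.reho_amp * (
            np.sqrt(rho) * (cr * er)[None, :] + np.sqrt(1 - rho) * private
        )
        # VMHC pairs: per-pair shared carrier + private parts
        np_pairs = left_idx.size
        shared = _band_limited(rng, spec.t, spec.tr, spec.band, n=np_pairs)
        ev = _smooth_envelope(rng, spec.t, 0.4, spec.env_smooth_frames)
        shared = shared * ev[None, :]
        c = spec.vmhc_coupling
        for side_idx in (left_idx, right_idx):
            priv = _band_limited(rng, spec.t, spec.tr, spec.band, n=np_pairs)
            sig[side_idx] += spec.vmhc_amp * (
                np.sqrt(c) * shared + np.sqrt(1 - c) * priv
            )
        # DC hub: hub and satellites share a latent
        ch = _band_limited(rng, spec.t, spec.tr, spec.band)[0]
        eh = _smooth_envelope(rng, spec.t, 0.4, spec.env_smooth_frames)
        ch = ch * eh
        sig[hub] += spec.hub_amp * 1.2 * ch
        priv = _band_limited(rng, spec.t, spec.tr, spec.band, n=satellites.size)
        sig[satellites] += spec.hub_amp * (0.9 * ch[None, :] + 0.45 * priv)

        data = np.zeros(spec.shape + (spec.t,))
        data[mask] = sig
        series = BoldSeries(data, voxel_size, spec.tr, mask)
        subjects.append(SimulatedSubject(sid, group, series))
        subject_depths.append(depth)
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age": float(np.clip(rng.normal(8.6, 1.8), 6.0, 14.0)),
                "gender": "male" if rng.random() < 0.7 else "female",
                "iq": float(rng.normal(119.0, 16.0)),
            }
        )
    table = pd.DataFrame(rows)
    truth = {
        "regions": truth_regions,
        "hub_index": int(hub),
        "satellite_indices": satellites,
        "global_loading": lam3d,
        "network_loadings": net_loadings,
        "total_loading_masked": lam + (sum(net_loadings) if net_loadings else 0.0),
        "dalff_depth": np.array(subject_depths),
        "mirror_pairs": (left_idx, right_idx),
    }
    return SimulatedCohort(subjects=subjects, table=table, truth=truth, spec=spec)


def simulate_variability_maps(
    n_subjects: int,
    mask: np.ndarray,
    fwhm_mm: float = 4.0,
    voxel_size_mm: float = 3.0,
    effect_region: np.ndarray | None = None,
    effect_size: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-subject 3D maps emulating smoothed, normalized variability maps.

    Each map is white Gaussian noise smoothed at `fwhm_mm` (matching the
    pipeline's output smoothing), rescaled to unit voxel SD, NaN outside
    the mask. If an effect region is given, `effect_size` (in units of the
    map's voxel SD) is added there — used to plant group mean shifts for
    calibration/power studies of the cluster inference.
    """
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, dtype=bool)
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)) * voxel_size_mm)
    maps = np.empty((n_subjects,) + mask.shape)
    for s in range(n_subjects):
        m = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma)
        m = m / m[mask].std()
        if effect_region is not None and effect_size != 0.0:
            m = m + effect_size * effect_region
        m[~mask] = np.nan
        maps[s] = m
    return maps


def simulate_motion(
    n_subjects: int, t: int, violator_fraction: float, seed: int = 0
) -> dict[str, MotionTrace]:
    """Random-walk motion traces; a designated fraction of subjects get at
    least one frame violating the 3 mm / 3 degree rule."""
    if not 0 <= violator_fraction <= 1:
        raise ValueError("violator_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_viol = int(round(violator_fraction * n_subjects))
    violators = set(rng.choice(n_subjects, size=n_viol, replace=False).tolist())
    traces = {}
    for s in range(n_subjects):
        steps = rng.normal(0.0, 0.02, size=(t, 6))
        steps[0] = 0.0
        params = np.cumsum(steps, axis=0)
        if s in violators:
            frame = int(rng.integers(1, t))
            axis = int(rng.integers(0, 6))
            params[frame, axis] = 3.5 if axis < 3 else 3.5  # mm or degrees
        traces[f"sub-{s + 1:03d}"] = MotionTrace(params)
    return traces


def simulate_clinical_scores(
    truth_values: np.ndarray,
    beta: float,
    noise_sd: float,
    seed: int = 0,
    covariates: np.ndarray | None = None,
    loadings: np.ndarray | None = None,
) -> np.ndarray:
    """Clinical scores linear in a planted per-subject concordance scalar.

    score = beta * truth + covariates @ loadings + N(0, noise_sd).
    With standardized truth orthogonal to the covariates, the true partial
    correlation is beta / sqrt(beta^2 + noise_sd^2).
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    rng = np.random.default_rng(seed)
    truth_values = np.asarray(truth_values, dtype=float).reshape(-1)
    score = beta * truth_values
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != truth_values.size:
            C = C.T
        if loadings is None:
            loadings = np.full(C.shape[1], 0.5)
        score = score + C @ np.asarray(loadings, dtype=float)
    return score + rng.normal(0.0, noise_sd, size=truth_values.size)


def partial_r_to_beta(target_r: float, noise_sd: float = 1.0) -> float:
    """Carrier beta giving a desired true partial correlation (truth ~ N(0,1),
    independent of covariates): r = beta / sqrt(beta^2 + noise_sd^2)."""
    if not -1 < target_r < 1:
        raise ValueError("target partial correlation must be in (-1, 1)")
    return target_r * noise_sd / np.sqrt(1.0 - target_r**2)
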