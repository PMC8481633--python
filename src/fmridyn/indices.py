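"""The five voxel-wise resting-state indices, evaluated per sliding window.

ALFF  - mean single-sided DFT amplitude in the low-frequency band
        (default 0.01-0.08 Hz): local oscillation strength.
ReHo  - Kendall's W of a voxel's time series with its 26 nearest in-mask
        neighbors (27-voxel cube): local synchrony.
DC    - binary degree centrality: count of other in-mask voxels whose
        Pearson correlation exceeds a threshold (default signed r > 0.25),
        z-scored across the mask per window: hubness.
VMHC  - Fisher-z Pearson correlation between a voxel and its mirror across
        the midplane of the first spatial axis: homotopic coupling.
GSC   - Fisher-z Pearson correlation with the mask-mean (global) signal.

`compute_dynamic_stack` evaluates all five on every window of a plan,
yielding a (5, n_windows, n_mask_voxels) stack. When band-pass filtering
is enabled it applies to ReHo/DC/VMHC/GSC only; ALFF always sees the
unfiltered spectrum (its band selection happens in the frequency domain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .concordance import tie_correction
from .preprocess import bandpass_filter
from .volio import AnalysisConfig, BoldSeries
from .windows import WindowPlan, extract_window

logger = logging.getLogger("fmridyn")

INDEX_NAMES = ("ALFF", "ReHo", "DC", "VMHC", "GSC")

FISHER_CLAMP = 1.0 - 1e-7


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clamped to 1 - 1e-7 so degenerate r = ±1 stays finite."""
    return np.arctanh(np.clip(r, -FISHER_CLAMP, FISHER_CLAMP))


@dataclass
class DynamicIndexStack:
    """Per-subject (5, n_windows, n_mask_voxels) dynamic index array."""

    values: np.ndarray
    mask: np.ndarray
    index_names: tuple = INDEX_NAMES
    provenance: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def index(self, name: str) -> np.ndarray:
        return self.values[self.index_names.index(name)]


def _zscore_mask(values: np.ndarray) -> np.ndarray:
    """z-score over finite entries; all-zeros if the spread is zero."""
    finite = np.isfinite(values)
    v = values[finite]
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    out = np.full_like(values, np.nan, dtype=float)
    out[finite] = (v - v.mean()) / sd if sd > 0 else 0.0
    return out


def alff(segment: np.ndarray, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Mean single-sided amplitude 2|X_k|/L over DFT bins inside the band.

    Only non-DC bins (k >= 1) are eligible; raises if the band contains no
    bin for the given window length and TR (use a longer window).
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    L = segment.shape[1]
    if L < 4:
        raise ValueError("ALFF needs a window of at least 4 frames")
    freqs = np.fft.rfftfreq(L, d=tr)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    in_band[0] = False
    if not in_band.any():
        raise ValueError(
            f"no DFT bin in {band} Hz for L={L}, TR={tr}; use a longer window"
        )
    amp = 2.0 * np.abs(np.fft.rfft(segment, axis=1)) / L
    return amp[:, in_band].mean(axis=1)


def neighbor_table(mask: np.ndarray, neighborhood: int = 27) -> np.ndarray:
    """(V, K) table of in-mask neighbor indices per mask voxel, -1 padded.

    Neighborhoods: 7 = faces, 19 = faces+edges, 27 = full cube (the voxel
    itself is always included).
    """
    if neighborhood not in (7, 19, 27):
        raise ValueError("neighborhood must be 7, 19, or 27")
    mask = np.asarray(mask, dtype=bool)
    lin = np.full(mask.shape, -1, dtype=np.int64)
    lin[mask] = np.arange(mask.sum())
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                dist = abs(dx) + abs(dy) + abs(dz)
                if neighborhood == 7 and dist > 1:
                    continue
                if neighborhood == 19 and dist > 2:
                    continue
                offsets.append((dx, dy, dz))
    coords = np.argwhere(mask)
    V, K = coords.shape[0], len(offsets)
    table = np.full((V, K), -1, dtype=np.int64)
    shape = mask.shape
    for j, (dx, dy, dz) in enumerate(offsets):
        nb = coords + np.array([dx, dy, dz])
        ok = ((nb >= 0) & (nb < shape)).all(axis=1)
        idx = np.flatnonzero(ok)
        table[idx, j] = lin[tuple(nb[idx].T)]
    return table


def reho(segment: np.ndarray, nbr_table: np.ndarray) -> np.ndarray:
    """Per-voxel Kendall's W of each voxel's neighborhood over time.

    `segment` is (V, L); `nbr_table` comes from `neighbor_table`. Voxels
    whose neighborhood has fewer than 2 valid (non-constant-free) series,
    or that are themselves constant, yield NaN.
    """
    segment = np.asarray(segment, dtype=float)
    V, L = segment.shape
    if L < 2:
        raise ValueError("ReHo needs at least 2 time points")
    const = np.ptp(segment, axis=1) == 0
    ranks = rankdata(segment, axis=1)  # (V, L)
    ties = tie_correction(segment, axis=1)  # (V,)
    # padded gather: row V is zeros / invalid
    ranks_p = np.vstack([ranks, np.zeros((1, L))])
    ties_p = np.concatenate([ties, [0.0]])
    const_p = np.concatenate([const, [True]])
    tbl = np.where(nbr_table < 0, V, nbr_table)
    member = ~const_p[tbl]  # (V, K) valid, non-constant neighbors
    tbl_eff = np.where(member, tbl, V)
    K = member.sum(axis=1).astype(float)
    Rsum = ranks_p[tbl_eff].sum(axis=1)  # (V, L)
    Tsum = ties_p[tbl_eff].sum(axis=1)
    S = ((Rsum - K[:, None] * (L + 1) / 2.0) ** 2).sum(axis=1)
    denom = K**2 * (L**3 - L) - K * Tsum
    with np.errstate(invalid="ignore", divide="ignore"):
        W = 12.0 * S / denom
    W[(K < 2) | (denom <= 0) | const] = np.nan
    return W


def _center_normalize(segment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-center and L2-normalize; returns (unit rows, zero-variance flag)."""
    seg = segment - segment.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(seg, axis=1)
    zero = norms == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = seg / norms[:, None]
    unit[zero] = 0.0
    return unit, zero


def degree_centrality(
    segment: np.ndarray, threshold: float = 0.25, zscore: bool = True
) -> np.ndarray:
    """Binary degree: count of other voxels with Pearson r > threshold,
    z-scored across the mask (set zscore=False for the raw count).
    Threshold applies to signed r (positive connections only).
    Zero-variance voxels get NaN.
    """
    if not 0 < threshold < 1:
        raise ValueError("DC threshold must be in (0, 1)")
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    V = segment.shape[0]
    if V < 3:
        raise ValueError("degree centrality needs at least 3 voxels")
    unit, zero = _center_normalize(segment)
    R = unit @ unit.T
    np.fill_diagonal(R, 0.0)
    R[zero] = 0.0
    R[:, zero] = 0.0
    degree = (R > threshold).sum(axis=1).astype(float)
    degree[zero] = np.nan
    return _zscore_mask(degree) if zscore else degree


def mirror_pairs(mask: np.ndarray) -> np.ndarray:
    """Per mask voxel, index of its reflection across the first-axis
    midplane (x -> nx-1-x), or -1 if the mirror voxel is out of mask.
    Requires an even first dimension (no self-paired midline voxels).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] % 2:
        raise ValueError("VMHC mirror map requires an even first dimension")
    lin = np.full(mask.shape, -1, dtype=np.int64)
    lin[mask] = np.arange(mask.sum())
    coords = np.argwhere(mask)
    mirrored = coords.copy()
    mirrored[:, 0] = mask.shape[0] - 1 - coords[:, 0]
    return lin[tuple(mirrored.T)]


def vmhc(segment: np.ndarray, mirror_map: np.ndarray) -> np.ndarray:
    """Fisher-z Pearson correlation of each voxel with its homotopic mirror.

    Unpaired voxels (mirror out of mask) and zero-variance voxels are NaN;
    the map is symmetric: value(v) == value(mirror(v)).
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    unit, zero = _center_normalize(segment)
    paired = mirror_map >= 0
    out = np.full(segment.shape[0], np.nan)
    idx = np.flatnonzero(paired)
    partner = mirror_map[idx]
    r = (unit[idx] * unit[partner]).sum(axis=1)
    bad = zero[idx] | zero[partner]
    z = fisher_z(r)
    z[bad] = np.nan
    out[idx] = z
    return out


def gsc(segment: np.ndarray) -> np.ndarray:
    """Fisher-z correlation of each voxel with the unweighted mask-mean
    (global) signal of the same segment."""
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    if segment.shape[0] < 2:
        raise ValueError("GSC needs at least 2 voxels")
    g = segment.mean(axis=0)
    gc = g - g.mean()
    gn = np.linalg.norm(gc)
    if gn == 0:
        logger.warning("GSC: zero-variance global signal; all NaN")
        return np.full(segment.shape[0], np.nan)
    unit, zero = _center_normalize(segment)
    r = unit @ (gc / gn)
    z = fisher_z(r)
    z[zero] = np.nan
    return z


def compute_dynamic_stack(
    series: BoldSeries, plan: WindowPlan, cfg: AnalysisConfig
) -> DynamicIndexStack:
    """Evaluate all five indices on every window of the plan.

    Band-pass (cfg.bandpass, cfg.alff_band) applies to the four
    correlation/rank indices; ALFF uses the unfiltered series.
    """
    raw = series.masked()
    if cfg.bandpass:
        conn_series = bandpass_filter(series, cfg.alff_band).masked()
    else:
        conn_series = raw
    nbr = neighbor_table(series.mask, cfg.reho_neighborhood)
    mirrors = mirror_pairs(series.mask)
    V = raw.shape[0]
    values = np.empty((5, plan.n_windows, V))
    for w in range(plan.n_windows):
        seg_alff = extract_window(raw, plan, w)
        seg = extract_window(conn_series, plan, w)
        values[0, w] = alff(seg_alff, series.tr, cfg.alff_band)
        values[1, w] = reho(seg, nbr)
        values[2, w] = degree_centrality(seg, cfg.dc_threshold)
        values[3, w] = vmhc(seg, mirrors)
        values[4, w] = gsc(seg)
        # zero-variance voxels carry no signal this window: NaN for all five
        dead = np.ptp(seg_alff, axis=1) == 0
        values[:, w, dead] = np.nan
    n_nan = int((~np.isfinite(values)).any(axis=(0, 1)).sum())
    if n_nan:
        logger.info("dynamic stack: %d voxels with NaN in some window", n_nan)
    return DynamicIndexStack(
        values=values,
        mask=series.mask,
        provenance={"config": cfg.to_dict(), "n_windows": plan.n_windows},
    )
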