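"""Volume discard, head-motion QC, nuisance regression, band-pass filtering.

Framewise displacement uses the Power formulation: backward differences of
the six rigid-body parameters, rotations converted to arc length on a
50 mm sphere. Nuisance regression is voxel-wise OLS against an intercept,
linear drift, the Friston-24 motion expansion and mean WM/CSF signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volio import BoldSeries, MotionTrace

logger = logging.getLogger("fmridyn")


def discard_initial_volumes(series: BoldSeries, n_discard: int) -> BoldSeries:
    """Drop the first `n_discard` frames (scanner equilibration period)."""
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= series.n_frames:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_frames} frames"
        )
    if n_discard == 0:
        return series
    return series.with_data(series.data[..., n_discard:])


def framewise_displacement(
    trace: MotionTrace, sphere_radius: float = 50.0
) -> tuple[np.ndarray, float]:
    """Power-style FD: sum |Δtranslation| + radius * sum |Δrotation (rad)|.

    Returns (per-frame FD with FD[0] = 0, mean FD over frames).
    """
    if trace.n_frames < 2:
        raise ValueError("FD needs at least 2 frames")
    d_trans = np.abs(np.diff(trace.translations, axis=0)).sum(axis=1)
    d_rot = np.abs(np.diff(trace.rotations_rad, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], d_trans + sphere_radius * d_rot])
    return fd, float(fd.mean())


def qc_exclude(
    traces: dict[str, MotionTrace],
    max_translation: float = 3.0,
    max_rotation: float = 3.0,
) -> tuple[list[str], list[str]]:
    """Split subject ids into (retained, excluded) by peak head motion.

    A subject is excluded iff any frame's absolute translation on any axis
    exceeds `max_translation` mm or any rotation exceeds `max_rotation`
    degrees.
    """
    if max_translation <= 0 or max_rotation <= 0:
        raise ValueError("motion thresholds must be positive")
    retained, excluded = [], []
    for sid, trace in traces.items():
        viol = (np.abs(trace.translations) > max_translation).any() or (
            np.abs(trace.rotations_deg) > max_rotation
        ).any()
        (excluded if viol else retained).append(sid)
    logger.info("QC: retained %d, excluded %d", len(retained), len(excluded))
    return retained, excluded


def qc_report(
    traces: dict[str, MotionTrace],
    max_translation: float = 3.0,
    max_rotation: float = 3.0,
    sphere_radius: float = 50.0,
) -> pd.DataFrame:
    """Per-subject motion summary: max displacement/rotation, mean FD, flag."""
    _, excluded = qc_exclude(traces, max_translation, max_rotation)
    rows = []
    for sid, trace in traces.items():
        _, mfd = framewise_displacement(trace, sphere_radius)
        rows.append(
            {
                "subject_id": sid,
                "max_translation_mm": float(np.abs(trace.translations).max()),
                "max_rotation_deg": float(np.abs(trace.rotations_deg).max()),
                "mean_fd_mm": mfd,
                "excluded": sid in excluded,
            }
        )
    return pd.DataFrame(rows)


def friston24_expand(trace: MotionTrace) -> np.ndarray:
    """Friston-24 expansion: [p_t, p_t^2, p_{t-1}, p_{t-1}^2] per parameter.

    The lagged block's first row is zero-filled. Columns 0-5 are the raw
    parameters, 6-11 their squares, 12-17 the one-frame lags, 18-23 the
    squared lags.
    """
    if trace.n_frames < 2:
        raise ValueError("Friston-24 expansion needs at least 2 frames")
    p = trace.params
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, p**2, lag, lag**2])


@dataclass
class NuisanceDesign:
    """Design matrix for nuisance regression: t x k plus column names."""

    columns: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != len(self.names):
            raise ValueError("design shape does not match column names")


def build_nuisance_design(
    trace: MotionTrace,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
) -> NuisanceDesign:
    """Intercept + linear drift + Friston-24 (+ mean WM and CSF signals).

    The drift column is 0..t-1 rescaled to [-0.5, 0.5] for conditioning;
    any affine rescaling spans the same space.
    """
    t = trace.n_frames
    cols = [np.ones(t), np.linspace(-0.5, 0.5, t)]
    names = ["intercept", "drift"]
    f24 = friston24_expand(trace)
    cols.extend(f24.T)
    names.extend(f"friston24_{i}" for i in range(24))
    for sig, name in ((wm_signal, "wm"), (csf_signal, "csf")):
        if sig is not None:
            sig = np.asarray(sig, dtype=float).reshape(-1)
            if sig.size != t:
                raise ValueError(f"{name} signal length {sig.size} != t {t}")
            cols.append(sig)
            names.append(name)
    return NuisanceDesign(np.column_stack(cols), names)


def mean_mask_signal(series: BoldSeries, roi_mask: np.ndarray) -> np.ndarray:
    """Mean time course over an ROI mask (e.g. WM or CSF)."""
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != series.mask.shape:
        raise ValueError("ROI mask shape does not match series")
    if not roi.any():
        raise ValueError("empty ROI mask")
    return series.data[roi].mean(axis=0)


def _drop_constant_duplicates(design: NuisanceDesign) -> NuisanceDesign:
    """Drop all-constant columns beyond the first (intercept duplicates)."""
    X, names = design.columns, design.names
    keep, seen_const = [], False
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            if seen_const or X[0, j] == 0:
                continue
            seen_const = True
        keep.append(j)
    return NuisanceDesign(X[:, keep], [names[j] for j in keep])


def nuisance_regress(series: BoldSeries, design: NuisanceDesign) -> BoldSeries:
    """OLS residuals of every in-mask voxel series on the design columns.

    Raises on a rank-deficient design (after dropping duplicate constant
    columns), naming the collinear columns.
    """
    design = _drop_constant_duplicates(design)
    X = design.columns
    t = series.n_frames
    if X.shape[0] != t:
        raise ValueError(f"design rows {X.shape[0]} != series frames {t}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns fully explained by the others
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(X[:, j]), 1.0):
                bad.append(design.names[j])
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    Y = series.masked().T  # t x V
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = series.data.copy()
    out[series.mask] = resid.T
    return series.with_data(out)


def bandpass_filter(series: BoldSeries, band: tuple[float, float]) -> BoldSeries:
    """FFT-domain band-pass of every in-mask voxel series.

    Frequency bins strictly outside [f_lo, f_hi] (including DC) are zeroed.
    """
    f_lo, f_hi = band
    t = series.n_frames
    freqs = np.fft.rfftfreq(t, d=series.tr)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    if not keep.any():
        raise ValueError(
            f"band {band} Hz contains no DFT bin for t={t}, TR={series.tr}"
        )
    Y = series.masked()
    spec = np.fft.rfft(Y, axis=1)
    spec[:, ~keep] = 0.0
    out = series.data.copy()
    out[series.mask] = np.fft.irfft(spec, n=t, axis=1)
    return series.with_data(out)
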