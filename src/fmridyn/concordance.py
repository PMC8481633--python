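"""Kendall's coefficient of concordance (W) and the two concordance summaries.

W measures agreement among m "judges" each ranking n "items":

    W = 12 S / (m^2 (n^3 - n) - m * sum_j T_j),
    S = sum_i (R_i - m (n + 1) / 2)^2,

with R_i the rank sum of item i over judges (average ranks for ties) and
T_j = sum over tie groups of (t^3 - t) the per-judge tie correction.
W is 0 for no agreement, 1 for perfect agreement; for two judges on
tie-free data W = (rho_spearman + 1) / 2.

Here the five dynamic indices act as judges. Voxel-wise (temporal)
concordance ranks the sliding windows per voxel; volume-wise (spatial)
concordance ranks the in-mask voxels per window and is averaged over
windows to one scalar per subject.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger("fmridyn")


def tie_correction(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Sum of (t^3 - t) over groups of tied values along `axis`.

    Vectorized over all other axes; exact zeros where no ties occur.
    """
    s = np.sort(np.asarray(values, dtype=float), axis=axis)
    s = np.moveaxis(s, axis, -1)
    eq = s[..., 1:] == s[..., :-1]
    if not eq.any():
        return np.zeros(s.shape[:-1])
    out = np.zeros(s.shape[:-1])
    flat_eq = eq.reshape(-1, eq.shape[-1])
    flat_out = out.reshape(-1)
    rows = np.flatnonzero(flat_eq.any(axis=1))
    for r in rows:
        e = flat_eq[r]
        total = 0.0
        run = 1
        for v in e:
            if v:
                run += 1
            else:
                if run > 1:
                    total += run**3 - run
                run = 1
        if run > 1:
            total += run**3 - run
        flat_out[r] = total
    return out


def kendalls_w(ratings: np.ndarray) -> float:
    """Kendall's W of an m-judges x n-items matrix of real-valued ratings.

    Each judge's values are converted to average ranks; the tie-corrected
    denominator is used. A judge with all-equal values contributes uniform
    ranks; if every judge is constant the result is NaN (no information).
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2D (judges x items) matrix")
    m, n = ratings.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 judges and 2 items")
    if not np.isfinite(ratings).all():
        raise ValueError("non-finite ratings")
    if (np.ptp(ratings, axis=1) == 0).all():
        return float("nan")
    ranks = rankdata(ratings, axis=1)
    R = ranks.sum(axis=0)
    S = ((R - m * (n + 1) / 2.0) ** 2).sum()
    T = tie_correction(ratings, axis=1).sum()
    denom = m**2 * (n**3 - n) - m * T
    if denom <= 0:
        return float("nan")
    return float(12.0 * S / denom)


def _w_stack(values: np.ndarray) -> np.ndarray:
    """Vectorized Kendall's W along axis 1 for a (m, n, ...) array.

    Judges on axis 0, items on axis 1; returns W per trailing index.
    NaN where every judge is constant or any value is non-finite.
    """
    m, n = values.shape[0], values.shape[1]
    ranks = rankdata(values, axis=1)
    R = ranks.sum(axis=0)
    S = ((R - m * (n + 1) / 2.0) ** 2).sum(axis=0)
    T = tie_correction(values, axis=1).sum(axis=0)
    denom = m**2 * (n**3 - n) - m * T
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(denom > 0, 12.0 * S / np.maximum(denom, 1.0), np.nan)
    all_const = (np.ptp(values, axis=1) == 0).all(axis=0)
    bad = all_const | ~np.isfinite(values).all(axis=(0, 1))
    W = np.where(bad, np.nan, W)
    return W


def voxelwise_concordance(stack) -> np.ndarray:
    """Temporal concordance: per voxel, W of the 5 indices across windows.

    Windows in which any index is NaN at a voxel are dropped for that voxel
    (at least 2 valid windows required, else NaN). Returns a 3D map, NaN
    outside the mask.
    """
    values = stack.values  # (5, n_windows, V)
    n_idx, n_win, V = values.shape
    if n_win < 2:
        raise ValueError("voxel-wise concordance needs at least 2 windows")
    valid = np.isfinite(values).all(axis=0)  # (n_windows, V)
    W = np.full(V, np.nan)
    full = valid.all(axis=0)
    if full.any():
        W[full] = _w_stack(values[:, :, full])
    partial = ~full & (valid.sum(axis=0) >= 2)
    for v in np.flatnonzero(partial):
        W[v] = kendalls_w(values[:, valid[:, v], v])
    n_dropped = int((~full).sum())
    if n_dropped:
        logger.info("voxelwise concordance: %d voxels had NaN windows", n_dropped)
    out = np.full(stack.mask.shape, np.nan)
    out[stack.mask] = W
    return out


def volumewise_concordance(stack) -> float:
    """Spatial concordance: mean over windows of W across in-mask voxels.

    The item set is the fixed intersection of voxels that are finite for
    all five indices in every window, so every window ranks the same
    voxels. Windows with fewer than 2 valid voxels are skipped (logged).
    """
    values = stack.values
    n_idx, n_win, V = values.shape
    valid = np.isfinite(values).all(axis=(0, 1))  # fixed per-subject item set
    if valid.sum() < 2:
        raise ValueError("fewer than 2 voxels valid across all indices/windows")
    vals = values[:, :, valid]
    per_window = []
    for w in range(n_win):
        per_window.append(kendalls_w(vals[:, w, :]))
    per_window = np.asarray(per_window)
    skipped = int(np.isnan(per_window).sum())
    if skipped:
        logger.info("volumewise concordance: %d windows skipped", skipped)
    return float(np.nanmean(per_window))
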