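"""Temporal-variability maps: SD across windows, normalization, smoothing.

For each dynamic index the standard deviation across sliding windows is
taken per voxel (population SD), the resulting 3D map is normalized across
mask voxels (z-scoring by default), and finally smoothed with a separable
Gaussian (FWHM in mm). Pipeline order is fixed: normalize, then smooth.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .indices import INDEX_NAMES, DynamicIndexStack


def sd_across_windows(stack: DynamicIndexStack) -> dict[str, np.ndarray]:
    """Population SD across windows per voxel, one 3D map per index.

    Windows where an index is NaN at a voxel are dropped for that voxel.
    """
    if stack.n_windows < 2:
        raise ValueError("SD across windows needs at least 2 windows")
    maps = {}
    for i, name in enumerate(stack.index_names):
        vals = stack.values[i]  # (n_windows, V)
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(vals, axis=0, ddof=0)
        sd[np.isnan(vals).all(axis=0)] = np.nan
        out = np.full(stack.mask.shape, np.nan)
        out[stack.mask] = sd
        maps[name] = out
    return maps


def zscore_across_mask(map3d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Subtract the mask mean and divide by the mask SD (ddof=1)."""
    out = np.full(map3d.shape, np.nan)
    vals = map3d[mask]
    finite = np.isfinite(vals)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite mask voxels to normalize")
    v = vals[finite]
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread across mask; cannot z-score")
    vals = (vals - v.mean()) / sd
    out[mask] = vals
    return out


def mean_normalize_across_mask(map3d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Divide by the mask mean (alternative normalization)."""
    out = np.full(map3d.shape, np.nan)
    vals = map3d[mask]
    m = np.nanmean(vals)
    if not np.isfinite(m) or m == 0:
        raise ValueError("mask mean is zero or undefined; cannot normalize")
    out[mask] = vals / m
    return out


def normalize_map(
    map3d: np.ndarray, mask: np.ndarray, method: str = "zscore"
) -> np.ndarray:
    if method == "zscore":
        return zscore_across_mask(map3d, mask)
    if method == "mean":
        return mean_normalize_across_mask(map3d, mask)
    raise ValueError(f"unknown normalization {method!r}")


def fwhm_to_sigma_voxels(fwhm: float, voxel_size: np.ndarray) -> np.ndarray:
    """Per-axis Gaussian sigma in voxels: fwhm / (2 sqrt(2 ln 2) * size)."""
    voxel_size = np.asarray(voxel_size, dtype=float)
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)) * voxel_size)


def gaussian_smooth(
    map3d: np.ndarray,
    fwhm: float,
    voxel_size: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """NaN-aware separable Gaussian smoothing restricted to the mask.

    The map (NaN and out-of-mask entries zero-filled) and the valid-voxel
    indicator are smoothed with the same kernel and divided, so edge
    voxels are renormalized rather than dragged toward zero. fwhm = 0 is
    the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    map3d = np.asarray(map3d, dtype=float)
    if mask is None:
        mask = np.ones(map3d.shape, dtype=bool)
    if fwhm == 0:
        out = np.full(map3d.shape, np.nan)
        out[mask] = map3d[mask]
        return out
    sigma = fwhm_to_sigma_voxels(fwhm, voxel_size)
    valid = mask & np.isfinite(map3d)
    filled = np.where(valid, map3d, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma, mode="constant")
    den = ndimage.gaussian_filter(valid.astype(float), sigma=sigma, mode="constant")
    out = np.full(map3d.shape, np.nan)
    inside = mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out


def variability_maps(
    stack: DynamicIndexStack,
    voxel_size: np.ndarray,
    fwhm: float = 4.0,
    normalization: str = "zscore",
) -> dict[str, np.ndarray]:
    """SD-across-windows maps, normalized across the mask, then smoothed."""
    raw = sd_across_windows(stack)
    out = {}
    for name in INDEX_NAMES:
        norm = normalize_map(raw[name], stack.mask, normalization)
        out[name] = gaussian_smooth(norm, fwhm, voxel_size, stack.mask)
    return out
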