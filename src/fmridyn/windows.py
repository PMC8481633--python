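"""Sliding-window planning and tapered segment extraction.

Windows are half-open 0-based frame ranges [start, start + length) spaced
by a fixed step; each extracted segment is demeaned per voxel and then
multiplied by the taper weights (hamming or none). With 230 frames, a
32-TR window and a 4-TR step this yields 50 windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volio import BoldSeries


def hamming_weights(length: int) -> np.ndarray:
    """Classical hamming taper w(n) = 0.54 - 0.46 cos(2 pi n / (L-1))."""
    if length < 2:
        raise ValueError("taper length must be >= 2")
    n = np.arange(length)
    return 0.54 - 0.46 * np.cos(2 * np.pi * n / (length - 1))


@dataclass
class WindowPlan:
    starts: np.ndarray
    length: int
    step: int
    taper_weights: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def plan_windows(
    t: int, length: int, step: int, taper: str = "hamming"
) -> WindowPlan:
    """Plan floor((t - length) / step) + 1 sliding windows over t frames."""
    if length > t:
        raise ValueError(f"window length {length} exceeds series length {t}")
    if step < 1:
        raise ValueError("step must be >= 1")
    if length < 2:
        raise ValueError("window length must be >= 2")
    n = (t - length) // step + 1
    starts = np.arange(n) * step
    if taper == "hamming":
        w = hamming_weights(length)
    elif taper == "none":
        w = np.ones(length)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    return WindowPlan(starts=starts, length=length, step=step, taper_weights=w)


def extract_window(
    series: BoldSeries | np.ndarray, plan: WindowPlan, w: int
) -> np.ndarray:
    """Extract window w as a (n_voxels, L) matrix: demeaned, then tapered."""
    if not 0 <= w < plan.n_windows:
        raise IndexError(f"window index {w} out of range 0..{plan.n_windows - 1}")
    data = series.masked() if isinstance(series, BoldSeries) else np.asarray(series)
    start = plan.starts[w]
    seg = data[:, start : start + plan.length].astype(float)
    seg = seg - seg.mean(axis=1, keepdims=True)
    return seg * plan.taper_weights
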