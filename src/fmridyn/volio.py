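"""Data model and I/O: 4D BOLD volumes, motion traces, cohort tables, config.

Volumes are NIfTI-1 (via nibabel); motion traces are whitespace-delimited
6-column text files (3 translations in mm, then 3 rotations in degrees);
cohort tables are CSV/TSV. Voxel indices are 0-based and no reorientation
is performed: inputs are assumed to be in a common space already, with the
geometry (voxel size in mm, TR in s) read from the image header.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fmridyn")

GROUP_LABELS = ("patient", "control")


class FormatError(ValueError):
    """Input file does not have the expected structure."""


class GeometryError(ValueError):
    """Spatial dimensions or geometry of paired images disagree."""


@dataclass
class BoldSeries:
    """One subject's 4D BOLD signal plus geometry and analysis mask.

    Attributes
    ----------
    data : (x, y, z, t) float array, arbitrary BOLD units.
    voxel_size : length-3 array, mm.
    tr : repetition time, seconds.
    mask : (x, y, z) boolean array; analysis is restricted to True voxels,
        out-of-mask outputs are NaN.
    affine : 4x4 voxel-to-world matrix carried through for output files.
    """

    data: np.ndarray
    voxel_size: np.ndarray
    tr: float
    mask: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        if self.data.ndim != 4:
            raise FormatError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise FormatError("BOLD series needs at least 2 time points")
        if self.tr <= 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if self.mask.shape != self.data.shape[:3]:
            raise GeometryError(
                f"mask shape {self.mask.shape} != spatial dims {self.data.shape[:3]}"
            )
        if not self.mask.any():
            raise ValueError("mask has no True voxels")
        if not np.isfinite(self.data[self.mask]).all():
            raise ValueError("non-finite BOLD values inside mask")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    def masked(self) -> np.ndarray:
        """Return the in-mask signal as a (n_mask_voxels, t) matrix."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return BoldSeries(data, self.voxel_size, self.tr, self.mask, self.affine)

    def unmask(self, values: np.ndarray) -> np.ndarray:
        """Scatter per-mask-voxel values into a 3D map, NaN outside mask."""
        out = np.full(self.mask.shape, np.nan)
        out[self.mask] = values
        return out


@dataclass
class MotionTrace:
    """Rigid-body motion parameters: t x 6, translations mm then rotations deg."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise FormatError(
                f"motion trace must be t x 6, got shape {self.params.shape}"
            )
        if not np.isfinite(self.params).all():
            raise ValueError("non-finite motion parameters")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.params[:, 3:]

    @property
    def rotations_rad(self) -> np.ndarray:
        return np.deg2rad(self.params[:, 3:])


@dataclass
class AnalysisConfig:
    """Every tunable parameter of the pipeline, with field-standard defaults.

    Defaults follow common dynamic R-fMRI practice: 10 discarded volumes,
    3 mm / 3 deg motion exclusion, hamming windows of 32 TR stepped by 4 TR,
    the 0.01-0.08 Hz low-frequency band, DC threshold r > 0.25 on a
    27-voxel ReHo neighborhood, FWHM 4 mm smoothing, and cluster inference
    at voxel p < 0.001 / cluster p < 0.05 (two-tailed, permutation-based).
    """

    window_length: int = 32
    window_step: int = 4
    taper: str = "hamming"
    alff_band: tuple = (0.01, 0.08)
    dc_threshold: float = 0.25
    reho_neighborhood: int = 27
    smooth_fwhm: float = 4.0
    n_permutations: int = 1000
    cluster_forming_p: float = 0.001
    cluster_p: float = 0.05
    n_discard: int = 10
    max_translation_mm: float = 3.0
    max_rotation_deg: float = 3.0
    fd_sphere_radius_mm: float = 50.0
    bandpass: bool = True
    normalization: str = "zscore"  # or "mean" (divide-by-mask-mean)
    seed: int = 0

    def __post_init__(self) -> None:
        self.alff_band = tuple(float(f) for f in self.alff_band)
        if self.taper not in ("hamming", "none"):
            raise ValueError(f"unknown taper {self.taper!r}")
        if self.window_step < 1:
            raise ValueError("window_step must be >= 1")
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not (0 <= self.alff_band[0] < self.alff_band[1]):
            raise ValueError(f"invalid ALFF band {self.alff_band}")
        if not (0 < self.dc_threshold < 1):
            raise ValueError("dc_threshold must be in (0, 1)")
        if self.reho_neighborhood not in (7, 19, 27):
            raise ValueError("reho_neighborhood must be one of 7, 19, 27")
        if self.normalization not in ("zscore", "mean"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Readers / writers


def read_bold(path: str | Path, mask_path: str | Path) -> BoldSeries:
    """Read a 4D NIfTI BOLD image and a 3D mask (binarized at > 0)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected a 4D BOLD image, got {data.ndim}D: {path}")
    mask_img = nib.load(str(mask_path))
    mask = np.asanyarray(mask_img.dataobj) > 0
    if mask.ndim != 3:
        raise FormatError(f"expected a 3D mask image, got {mask.ndim}D: {mask_path}")
    if mask.shape != data.shape[:3]:
        raise GeometryError(
            f"mask {mask.shape} does not match BOLD spatial dims {data.shape[:3]}"
        )
    zooms = img.header.get_zooms()
    voxel_size = np.array(zooms[:3], dtype=float)
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return BoldSeries(data, voxel_size, tr, mask, affine=np.asarray(img.affine))


def write_bold(series: BoldSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    img.header.set_zooms(tuple(series.voxel_size) + (series.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_map(map3d: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3D (or windows-as-4th-dim 4D) map as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(map3d, dtype=np.float32), affine), str(path))


def write_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def read_motion_trace(path: str | Path) -> MotionTrace:
    """Read a whitespace-delimited t x 6 motion-parameter file."""
    try:
        arr = np.loadtxt(str(path), ndmin=2)
    except ValueError as exc:  # ragged rows
        raise FormatError(f"cannot parse motion file {path}: {exc}") from exc
    if arr.shape[1] != 6:
        raise FormatError(
            f"motion file must have 6 columns, got {arr.shape[1]}: {path}"
        )
    return MotionTrace(arr)


def write_motion_trace(trace: MotionTrace, path: str | Path) -> None:
    np.savetxt(str(path), trace.params, fmt="%.10f")


REQUIRED_COHORT_COLUMNS = ("subject_id", "group")


def load_cohort_table(path: str | Path) -> pd.DataFrame:
    """Load and validate the cohort table (CSV or TSV, inferred).

    Required columns: subject_id (unique), group ('patient'/'control').
    Any further columns (age, gender, iq, mean_fd, clinical scores) pass
    through typed by pandas.
    """
    path = Path(path)
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise FormatError(f"cannot parse cohort table {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"cohort table has no rows: {path}")
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table missing columns {missing}: {path}")
    df["subject_id"] = df["subject_id"].astype(str)
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate subject ids: {sorted(set(dupes))}")
    bad = sorted(set(df["group"]) - set(GROUP_LABELS))
    if bad:
        raise ValueError(f"unknown group labels {bad}; expected {GROUP_LABELS}")
    sizes = df["group"].value_counts().to_dict()
    logger.info("cohort loaded: %s", sizes)
    return df.reset_index(drop=True)
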