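"""Domain types and file I/O for dynamic PET analysis.

Core containers
---------------
``FrameSchedule``
    Frame timing (start/duration in seconds relative to tracer injection;
    pre-injection frames have negative start).
``DynamicImage``
    A 4-D voxel grid of activity concentration (kBq/mL) over frames,
    axis order (x, y, z, frame), plus mm spacing and a schedule.
``LabelVolume``
    Integer 3-D region labels; 0 is background.
``TACTable``
    Per-voxel (or per-region) time-activity curves with optional voxel
    coordinates.

Cohort tables are plain :class:`pandas.DataFrame` objects with the fixed
header documented at :data:`COHORT_COLUMNS`; :func:`read_cohort` /
:func:`write_cohort` validate against it. Unknown extra columns are
preserved untouched.

File formats: 4-D NIfTI for dynamic images, 3-D NIfTI for labels/masks,
CSV for schedules, TAC tables and cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "FrameSchedule",
    "DynamicImage",
    "LabelVolume",
    "TACTable",
    "CohortRecord",
    "COHORT_COLUMNS",
    "read_dynamic",
    "write_dynamic",
    "read_labels",
    "write_labels",
    "read_schedule",
    "write_schedule",
    "read_tacs",
    "write_tacs",
    "read_cohort",
    "write_cohort",
    "cohort_to_records",
    "records_to_cohort",
]


class SchemaError(ValueError):
    """Input violates the structural contract (wrong shape/columns/type)."""


class ValidationError(ValueError):
    """Input is structurally fine but violates a value invariant."""


# --------------------------------------------------------------------------
# frame schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing in seconds relative to injection (t = 0).

    Pre-injection frames carry negative start times so that frame mid-times
    align unambiguously with tracer kinetics.
    """

    start: np.ndarray
    duration: np.ndarray
    injection_time: float = 0.0

    def __post_init__(self):
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or duration.ndim != 1 or start.size != duration.size:
            raise SchemaError("start and duration must be 1-D of equal length")
        if start.size == 0:
            raise SchemaError("schedule must contain at least one frame")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(duration)):
            raise ValidationError("schedule contains non-finite times")
        if np.any(duration <= 0):
            raise ValidationError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValidationError("frame starts must be strictly increasing")
        ends = start + duration
        if np.any(start[1:] < ends[:-1] - 1e-9):
            raise ValidationError("frames overlap")
        if np.any(np.diff(self.mid_times) <= 0):
            raise ValidationError("frame mid-times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-times, seconds."""
        return self.start + self.duration / 2.0

    @property
    def mid_times_min(self) -> np.ndarray:
        """Frame mid-times, minutes."""
        return self.mid_times / 60.0

    @property
    def duration_min(self) -> np.ndarray:
        return self.duration / 60.0

    def __len__(self) -> int:
        return self.n_frames

    def __eq__(self, other) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return (
            np.array_equal(self.start, other.start)
            and np.array_equal(self.duration, other.duration)
            and self.injection_time == other.injection_time
        )

    @classmethod
    def default_simulation(cls) -> "FrameSchedule":
        """45-frame, 60-min phantom schedule with denser early sampling.

        One 60-s pre-injection frame followed by 8x15 s, 8x30 s, 8x60 s,
        8x120 s and 12x150 s post-injection frames (60 min total).
        """
        durations = np.concatenate([
            [60.0],
            np.full(8, 15.0),
            np.full(8, 30.0),
            np.full(8, 60.0),
            np.full(8, 120.0),
            np.full(12, 150.0),
        ])
        starts = np.concatenate([[-60.0], np.cumsum(durations[1:]) - durations[1:]])
        return cls(start=starts, duration=durations)

    @classmethod
    def clinical_25frame(cls) -> "FrameSchedule":
        """25-frame, 60-min dynamic breast protocol.

        One 60-s pre-injection frame, then 4x20 s, 4x40 s, 4x60 s, 4x180 s
        and 8x300 s.
        """
        durations = np.concatenate([
            [60.0],
            np.full(4, 20.0),
            np.full(4, 40.0),
            np.full(4, 60.0),
            np.full(4, 180.0),
            np.full(8, 300.0),
        ])
        starts = np.concatenate([[-60.0], np.cumsum(durations[1:]) - durations[1:]])
        return cls(start=starts, duration=durations)


def read_schedule(path) -> FrameSchedule:
    """Read a frame schedule from CSV (columns start,duration) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        return FrameSchedule(
            start=np.asarray(obj["start"], dtype=float),
            duration=np.asarray(obj["duration"], dtype=float),
            injection_time=float(obj.get("injection_time", 0.0)),
        )
    df = pd.read_csv(path)
    missing = {"start", "duration"} - set(df.columns)
    if missing:
        raise SchemaError(f"schedule file missing columns: {sorted(missing)}")
    return FrameSchedule(
        start=df["start"].to_numpy(float), duration=df["duration"].to_numpy(float)
    )


def write_schedule(schedule: FrameSchedule, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({
            "start": schedule.start.tolist(),
            "duration": schedule.duration.tolist(),
            "injection_time": schedule.injection_time,
        }))
        return
    pd.DataFrame({"start": schedule.start, "duration": schedule.duration}).to_csv(
        path, index=False
    )


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------

@dataclass
class DynamicImage:
    """4-D dynamic PET volume: activity concentration over frames.

    ``values`` has axis order (x, y, z, frame); ``spacing`` is mm per
    spatial axis.
    """

    values: np.ndarray
    spacing: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        spacing = np.asarray(self.spacing, dtype=float)
        if values.ndim != 4:
            raise SchemaError(f"dynamic image must be 4-D, got {values.ndim}-D")
        if spacing.shape != (3,):
            raise SchemaError("spacing must have 3 entries (mm)")
        if np.any(spacing <= 0):
            raise ValidationError("voxel spacing must be positive")
        if values.shape[3] != self.schedule.n_frames:
            raise ValidationError(
                f"frame axis ({values.shape[3]}) does not match schedule "
                f"({self.schedule.n_frames} frames)"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("dynamic image contains non-finite voxels")
        self.values = values
        self.spacing = spacing

    @property
    def spatial_shape(self) -> tuple:
        return self.values.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    def frame_window(self, t0_min: float, t1_min: float) -> np.ndarray:
        """Indices of frames whose mid-time lies in [t0, t1] minutes."""
        mid = self.schedule.mid_times_min
        idx = np.where((mid >= t0_min) & (mid <= t1_min))[0]
        if idx.size == 0:
            raise ValidationError(f"no frames in window [{t0_min}, {t1_min}] min")
        return idx

    def late_image(self, window=(30.0, 60.0)) -> np.ndarray:
        """Duration-weighted mean concentration over a late time window.

        The (30, 60)-min summed image is the standard static surrogate for
        trapped tracers and is used for SUV-like contrast measurements.
        """
        idx = self.frame_window(*window)
        w = self.schedule.duration[idx]
        return np.tensordot(self.values[..., idx], w / w.sum(), axes=(3, 0))

    def tacs(self, mask: np.ndarray | None = None) -> "TACTable":
        """Extract per-voxel TACs, optionally restricted to a boolean mask."""
        if mask is None:
            mask = np.ones(self.spatial_shape, dtype=bool)
        mask = np.asarray(mask)
        if mask.dtype != bool:
            mask = mask > 0
        if mask.shape != self.spatial_shape:
            raise SchemaError("mask shape does not match image")
        coords = np.argwhere(mask)
        return TACTable(values=self.values[mask], coords=coords)


@dataclass
class LabelVolume:
    """3-D non-negative integer region labels; 0 is background."""

    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise SchemaError(f"label volume must be 3-D, got {labels.ndim}-D")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValidationError("labels must be integers")
            labels = np.round(labels).astype(np.int32)
        if labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        self.labels = labels.astype(np.int32)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def max_label(self) -> int:
        return int(self.labels.max())

    def is_contiguous(self) -> bool:
        present = np.unique(self.labels)
        present = present[present > 0]
        return present.size == 0 or np.array_equal(
            present, np.arange(1, present.size + 1)
        )

    def ensure_contiguous(self, strict: bool = False) -> "LabelVolume":
        """Return a volume with labels forming {0..L}.

        With ``strict`` a gap raises; otherwise labels are compacted in
        ascending order of original value.
        """
        if self.is_contiguous():
            return self
        if strict:
            raise ValidationError("label set has gaps")
        present = np.unique(self.labels)
        lut = np.zeros(present.max() + 1, dtype=np.int32)
        nxt = 1
        for p in present:
            if p == 0:
                continue
            lut[p] = nxt
            nxt += 1
        return LabelVolume(labels=lut[self.labels])

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class TACTable:
    """Time-activity curves, one row per voxel/region.

    ``coords`` optionally maps rows to voxel indices (n, 3).
    """

    values: np.ndarray
    coords: np.ndarray | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise SchemaError("TAC table must be 2-D (rows x frames)")
        self.values = values
        if self.coords is not None:
            coords = np.asarray(self.coords)
            if coords.shape != (values.shape[0], 3):
                raise SchemaError("coords must be (n_rows, 3)")
            self.coords = coords.astype(np.int64)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def read_tacs(path) -> TACTable:
    df = pd.read_csv(path)
    coord_cols = [c for c in ("x", "y", "z") if c in df.columns]
    frame_cols = [c for c in df.columns if c.startswith("frame_")]
    if not frame_cols:
        raise SchemaError("TAC CSV must contain frame_<i> columns")
    coords = df[coord_cols].to_numpy() if len(coord_cols) == 3 else None
    return TACTable(values=df[frame_cols].to_numpy(float), coords=coords)


def write_tacs(tacs: TACTable, path) -> None:
    cols = {}
    if tacs.coords is not None:
        cols.update({k: tacs.coords[:, i] for i, k in enumerate("xyz")})
    cols.update({f"frame_{i}": tacs.values[:, i] for i in range(tacs.n_frames)})
    pd.DataFrame(cols).to_csv(path, index=False)


# --------------------------------------------------------------------------
# NIfTI readers/writers
# --------------------------------------------------------------------------

def _affine_from_spacing(spacing: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_dynamic(img: DynamicImage, path_img, path_schedule=None) -> None:
    """Write a 4-D NIfTI plus (optionally) its frame-schedule CSV/JSON."""
    nii = nib.Nifti1Image(img.values.astype(np.float64), _affine_from_spacing(img.spacing))
    nib.save(nii, str(path_img))
    if path_schedule is not None:
        write_schedule(img.schedule, path_schedule)


def read_dynamic(path_img, path_schedule) -> DynamicImage:
    """Read a 4-D NIfTI and its frame schedule into a validated image."""
    nii = nib.load(str(path_img))
    data = np.asarray(nii.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise SchemaError(f"expected a 4-D image, got {data.ndim}-D")
    schedule = read_schedule(path_schedule) if not isinstance(
        path_schedule, FrameSchedule
    ) else path_schedule
    spacing = np.asarray(nii.header.get_zooms()[:3], dtype=float)
    return DynamicImage(values=data, spacing=spacing, schedule=schedule)


def write_labels(vol: LabelVolume, path) -> None:
    nii = nib.Nifti1Image(vol.labels.astype(np.int16), np.eye(4))
    nib.save(nii, str(path))


def read_labels(path, strict: bool = False) -> LabelVolume:
    nii = nib.load(str(path))
    data = np.asarray(nii.get_fdata())
    if data.ndim != 3:
        raise SchemaError(f"expected a 3-D label image, got {data.ndim}-D")
    vol = LabelVolume(labels=data)
    if not vol.is_contiguous():
        if strict:
            raise ValidationError("label set has gaps")
        warnings.warn("label set has gaps; relabelling to a contiguous range")
        vol = vol.ensure_contiguous()
    return vol


# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------

#: Required cohort CSV header. Extra columns pass through untouched.
#: er/pr/her2/pcr/aln/event are 0/1; tumor_size in cm; k1/ki in mL/cm^3/min;
#: rfs_time in months. Signature columns (bcss_tss, phi12, phi23, phi13,
#: fth_index) are optional and may be NaN before extraction.
COHORT_COLUMNS = [
    "patient_id", "er", "pr", "her2", "pcr", "aln",
    "tumor_size", "suv", "k1", "ki", "rfs_time", "event",
]

SIGNATURE_COLUMNS = ["bcss_tss", "phi12", "phi23", "phi13", "fth_index"]

_BINARY_COLUMNS = ["er", "pr", "her2", "pcr", "aln", "event"]


@dataclass
class CohortRecord:
    """One patient's covariates, kinetic markers, signature and outcome."""

    patient_id: str
    er: int
    pr: int
    her2: int
    pcr: int
    aln: int
    tumor_size: float
    suv: float
    k1: float
    ki: float
    rfs_time: float
    event: int
    bcss_tss: float = np.nan
    phi12: float = np.nan
    phi23: float = np.nan
    phi13: float = np.nan
    fth_index: float = np.nan

    def __post_init__(self):
        for name in _BINARY_COLUMNS:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValidationError(f"{name} must be 0/1, got {v!r}")
        if self.rfs_time < 0:
            raise ValidationError("rfs_time must be >= 0")
        if self.ki < 0:
            raise ValidationError("ki must be >= 0")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"cohort table missing columns: {sorted(missing)}")
    for col in _BINARY_COLUMNS:
        vals = df[col].dropna().unique()
        if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
            raise ValidationError(f"column {col} must be binary 0/1")
    if (df["rfs_time"] < 0).any():
        raise ValidationError("rfs_time must be >= 0")
    if (df["ki"] < 0).any():
        raise ValidationError("ki must be >= 0")
    return df


def read_cohort(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort(df: pd.DataFrame, path) -> None:
    validate_cohort(df).to_csv(path, index=False)


def cohort_to_records(df: pd.DataFrame) -> list:
    validate_cohort(df)
    fields = {f.name for f in dataclasses.fields(CohortRecord)}
    out = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in df.columns if k in fields}
        for b in _BINARY_COLUMNS:
            kwargs[b] = int(kwargs[b])
        kwargs["patient_id"] = str(kwargs["patient_id"])
        out.append(CohortRecord(**kwargs))
    return out


def records_to_cohort(records) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return validate_cohort(df)
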