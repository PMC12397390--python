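"""Reading, writing and assembly of 3-axis accelerometer recordings.

One recording = one animal's continuous 3-axis acceleration trace plus
metadata. On disk a recording is a CSV with header ``time,x,y,z`` (time in
seconds relative to the recording start, axes in the unit named by the
sidecar) accompanied by a YAML sidecar ``<stem>.meta.yaml`` holding
``animal_id, condition, sensor_id, start_time, sampling_rate, unit`` and
optionally ``rotation_rpm``. A cohort is described by a YAML manifest
listing the per-animal CSV files.

The canonical in-memory unit is m/s² with g = 9.81 m/s² exactly. Raw
16-bit sensor counts over a ±4 g range convert as ``count × 4·g/32768``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, time as dtime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

G = 9.81  # m/s², exact by convention
SENSOR_RANGE_G = 4.0
COUNTS_FULL_SCALE = 32768  # 16-bit signed
RAW_COUNT_SCALE = SENSOR_RANGE_G * G / COUNTS_FULL_SCALE
AXIS_LIMIT = SENSOR_RANGE_G * G  # ±39.24 m/s² per axis
TIMESTAMP_TOL_S = 1e-6

VALID_UNITS = ("m_s2", "g", "raw_counts")
VALID_CONDITIONS = ("sham", "pd")


class ParseError(ValueError):
    """Malformed file content (names the offending line where possible)."""


class StructuralError(ValueError):
    """Structurally inconsistent data (ragged axes, bad metadata)."""


class CoverageError(ValueError):
    """Recording does not cover the requested analysis window."""


@dataclass
class AccelerationRecording:
    """One animal's time-stamped 3-axis acceleration trace in m/s².

    Attributes
    ----------
    animal_id : int
        Dataset label d (1-based within a cohort).
    condition : str
        ``"sham"`` (vehicle-injected control) or ``"pd"`` (6-OHDA-lesioned).
    x, y, z : ndarray
        Equal-length per-axis acceleration in m/s².
    sampling_rate : float
        Sampling frequency f_s in Hz; one timestep is 1/f_s seconds.
    start_time : datetime or None
        Wall-clock time of the first sample.
    rotation_rpm : float or None
        Apomorphine-induced net rotation rate (rpm); quantifies the
        dopaminergic deficit, higher = stronger lesion.
    """

    animal_id: int
    condition: str
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sampling_rate: float = 25.0
    start_time: datetime | None = None
    sensor_id: str = ""
    rotation_rpm: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.shape == self.y.shape == self.z.shape) or self.x.ndim != 1:
            raise StructuralError(
                f"axes must be 1-D and equal length, got "
                f"{self.x.shape}/{self.y.shape}/{self.z.shape}"
            )
        if self.condition not in VALID_CONDITIONS:
            raise StructuralError(f"condition must be one of {VALID_CONDITIONS}")
        if not self.sampling_rate > 0:
            raise StructuralError("sampling_rate must be > 0")
        limit = AXIS_LIMIT * (1 + 1e-9)
        for name, axis in (("x", self.x), ("y", self.y), ("z", self.z)):
            if axis.size and np.nanmax(np.abs(axis)) > limit:
                raise StructuralError(
                    f"axis {name} exceeds the ±4 g sensor range "
                    f"(max |{name}| = {np.nanmax(np.abs(axis)):.3f} m/s²)"
                )

    def __len__(self) -> int:
        return self.x.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate


@dataclass
class DatasetMatrix:
    """Cohort data matrix M (D × I) of per-sample magnitudes.

    Row d is one animal's magnitude series; all rows share the trimmed
    length I (1,080,000 samples for 12 h at 25 Hz).
    """

    values: np.ndarray
    animal_ids: list[int]
    labels: list[str]
    rotation_rpm: list[float | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StructuralError("matrix must be 2-D (datasets × samples)")
        if len(self.animal_ids) != self.values.shape[0] or len(self.labels) != self.values.shape[0]:
            raise StructuralError("labels/ids must match the number of rows")
        if self.values.size and self.values.min() < 0:
            raise StructuralError("magnitudes must be non-negative")

    @property
    def n_datasets(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def _convert_to_ms2(arr: np.ndarray, unit: str) -> np.ndarray:
    if unit == "m_s2":
        return arr
    if unit == "g":
        return arr * G
    if unit == "raw_counts":
        return arr * RAW_COUNT_SCALE
    raise StructuralError(f"unknown unit {unit!r}; expected one of {VALID_UNITS}")


def _from_ms2(arr: np.ndarray, unit: str) -> np.ndarray:
    if unit == "m_s2":
        return arr
    if unit == "g":
        return arr / G
    if unit == "raw_counts":
        return np.round(arr / RAW_COUNT_SCALE)
    raise StructuralError(f"unknown unit {unit!r}; expected one of {VALID_UNITS}")


def sidecar_path(csv_path: str | Path) -> Path:
    p = Path(csv_path)
    return p.with_name(p.stem + ".meta.yaml")


def read_recording(path: str | Path, unit: str | None = None) -> AccelerationRecording:
    """Read one recording from a CSV + YAML-sidecar pair.

    Parameters
    ----------
    path : path to the ``time,x,y,z`` CSV.
    unit : unit of the stored axis values (``m_s2``, ``g`` or
        ``raw_counts``); defaults to the sidecar's ``unit`` field.

    Timestamps must be uniform at 1/f_s spacing within 1e-6 s — gap-free
    input is a precondition of the analysis, packet loss is not modelled.
    """
    path = Path(path)
    meta_path = sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not meta_path.exists():
        raise StructuralError(f"missing metadata sidecar {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    unit = unit or meta.get("unit", "m_s2")

    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path}: {exc}") from exc
    expected = ["time", "x", "y", "z"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: header must be {','.join(expected)}, got {list(df.columns)}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        # +2: 1-based lines plus the header line
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(f"{path}: malformed row at line {line}")

    fs = float(meta.get("sampling_rate", 25.0))
    t = numeric["time"].to_numpy()
    if t.size >= 2:
        dt = np.diff(t)
        if np.max(np.abs(dt - 1.0 / fs)) > TIMESTAMP_TOL_S:
            i = int(np.argmax(np.abs(dt - 1.0 / fs)))
            raise ParseError(
                f"{path}: non-uniform timestep at line {i + 3} "
                f"(Δt = {dt[i]:.6g} s, expected {1.0 / fs:.6g} s)"
            )

    start = meta.get("start_time")
    if isinstance(start, str):
        start = datetime.fromisoformat(start)
    return AccelerationRecording(
        animal_id=int(meta["animal_id"]),
        condition=str(meta["condition"]),
        x=_convert_to_ms2(numeric["x"].to_numpy(), unit),
        y=_convert_to_ms2(numeric["y"].to_numpy(), unit),
        z=_convert_to_ms2(numeric["z"].to_numpy(), unit),
        sampling_rate=fs,
        start_time=start,
        sensor_id=str(meta.get("sensor_id", "")),
        rotation_rpm=meta.get("rotation_rpm"),
    )


def write_recording(rec: AccelerationRecording, path: str | Path, unit: str = "m_s2") -> Path:
    """Write a recording as CSV + YAML sidecar; returns the CSV path."""
    path = Path(path)
    t = np.arange(len(rec)) / rec.sampling_rate
    axes = {name: _from_ms2(arr, unit) for name, arr in
            (("x", rec.x), ("y", rec.y), ("z", rec.z))}
    if unit == "raw_counts":
        axes = {k: v.astype(np.int64) for k, v in axes.items()}
    df = pd.DataFrame({"time": t, **axes})
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {
        "animal_id": int(rec.animal_id),
        "condition": rec.condition,
        "sensor_id": rec.sensor_id,
        "sampling_rate": float(rec.sampling_rate),
        "unit": unit,
        "start_time": rec.start_time.isoformat() if rec.start_time else None,
        "rotation_rpm": None if rec.rotation_rpm is None else float(rec.rotation_rpm),
    }
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def write_manifest(csv_paths: list[str | Path], path: str | Path) -> Path:
    """Write a cohort manifest (YAML list of recording CSVs, relative paths)."""
    path = Path(path)
    rels = [str(Path(p).name) for p in csv_paths]
    path.write_text(yaml.safe_dump({"recordings": rels}, sort_keys=False))
    return path


def read_manifest(path: str | Path) -> list[AccelerationRecording]:
    """Read every recording listed in a cohort manifest."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "recordings" not in doc:
        raise StructuralError(f"{path}: manifest must map 'recordings' to a list of CSVs")
    return [read_recording(path.parent / p) for p in doc["recordings"]]


def trim_to_window(
    rec: AccelerationRecording,
    window_start: dtime | str | None,
    duration_s: float,
) -> AccelerationRecording:
    """Trim a recording to a fixed analysis window.

    ``window_start`` is a wall-clock time (e.g. ``"19:45"``, the onset of
    the dark/active phase); the first occurrence at or after the recording
    start is used. ``None`` trims from the first sample. Partial seconds at
    the window edge are truncated toward the window interior, and the
    returned length is exactly ``duration_s × f_s`` samples.
    """
    fs = rec.sampling_rate
    n_out = duration_s * fs
    if abs(n_out - round(n_out)) > 1e-9:
        raise StructuralError("duration_s × sampling_rate must be an integer sample count")
    n_out = int(round(n_out))

    if window_start is None:
        start_idx = 0
        new_start = rec.start_time
    else:
        if isinstance(window_start, str):
            hh, mm = window_start.split(":")
            window_start = dtime(int(hh), int(mm))
        if rec.start_time is None:
            raise StructuralError("recording has no start_time; cannot locate the clock window")
        day = rec.start_time.date()
        target = datetime.combine(day, window_start)
        if target < rec.start_time:
            target += timedelta(days=1)
        offset_s = (target - rec.start_time).total_seconds()
        start_idx = math.ceil(offset_s * fs - 1e-9)  # truncate toward interior
        new_start = rec.start_time + timedelta(seconds=start_idx / fs)

    end_idx = start_idx + n_out
    if end_idx > len(rec):
        short = (end_idx - len(rec)) / fs
        raise CoverageError(
            f"animal {rec.animal_id}: recording ends {short:.1f} s before the "
            f"requested {duration_s:.0f} s window"
        )
    return replace(
        rec,
        x=rec.x[start_idx:end_idx],
        y=rec.y[start_idx:end_idx],
        z=rec.z[start_idx:end_idx],
        start_time=new_start,
    )


def build_matrix(
    recordings: list[AccelerationRecording],
    magnitudes: list[np.ndarray],
) -> DatasetMatrix:
    """Stack per-animal magnitude series into the cohort matrix M (D × I).

    Rows are ordered by animal_id; condition labels and rotation rates are
    carried along row-wise.
    """
    if len(recordings) != len(magnitudes):
        raise StructuralError("one magnitude series required per recording")
    lengths = {len(m) for m in magnitudes}
    if len(lengths) > 1:
        raise StructuralError(f"ragged magnitude lengths {sorted(lengths)}; trim first")
    order = np.argsort([r.animal_id for r in recordings], kind="stable")
    return DatasetMatrix(
        values=np.vstack([np.asarray(magnitudes[i], dtype=float) for i in order]),
        animal_ids=[recordings[i].animal_id for i in order],
        labels=[recordings[i].condition for i in order],
        rotation_rpm=[recordings[i].rotation_rpm for i in order],
    )
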