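"""Domain types and JSON I/O for grouped, time-stamped health measurements.

The data source is a JSON document organising measurements into named
groups (blood pressure, sleep, nutrition, ...).  Each measurement carries a
recommended range, optional warning bounds, and a time series of samples
whose timestamps are Unix epoch seconds (seconds since 1970-01-01 00:00:00
GMT).  The canonical dialect is::

    {"groups": [
        {"label": "Blood Pressure",
         "measurements": [
             {"label": "Systolic",
              "units": "mmHg",
              "recommended": {"min": 90, "max": 120},
              "warning": {"min": 80, "max": 140},        # optional, either bound
              "samples": [{"timestamp": 1420798224, "value": 125.0}, ...]}
         ]}
    ]}

A machine-readable schema for this dialect ships with the package as
``data_source.schema.json``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Sample",
    "Measurement",
    "MeasurementGroup",
    "HealthDataset",
    "Snapshot",
    "SnapshotMode",
    "DataValidationError",
    "parse_dataset",
    "serialize_dataset",
    "validate_dataset",
    "epoch_to_utc",
    "utc_to_epoch",
    "extract_snapshots",
]


class DataValidationError(ValueError):
    """A data-source document violates the dialect.

    ``path`` names the offending location, e.g.
    ``groups[0].measurements[1].samples[2].value``.
    """

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


@dataclass(frozen=True)
class Sample:
    """One observation: epoch timestamp (seconds, GMT) and numeric value."""

    timestamp: int
    value: float

    def __post_init__(self):
        if self.timestamp < 0:
            raise DataValidationError("timestamp", "must be >= 0 (pre-epoch)")
        if not math.isfinite(self.value):
            raise DataValidationError("value", "must be finite")


@dataclass(frozen=True)
class Measurement:
    """A named quantity with a recommended range, optional warning bounds and samples.

    ``rec_min``/``rec_max`` bound the recommended band; ``warn_min``/``warn_max``,
    when present, extend it with a warning zone on that side.  Samples are kept
    sorted ascending by timestamp.
    """

    label: str
    units: str
    rec_min: float
    rec_max: float
    samples: tuple[Sample, ...]
    warn_min: float | None = None
    warn_max: float | None = None

    def __post_init__(self):
        if not self.label:
            raise DataValidationError("label", "must be non-empty")
        if not self.rec_min < self.rec_max:
            raise DataValidationError(
                "recommended", f"min ({self.rec_min}) must be < max ({self.rec_max})"
            )
        if self.warn_min is not None and self.warn_min > self.rec_min:
            raise DataValidationError(
                "warning.min", f"({self.warn_min}) must be <= recommended.min ({self.rec_min})"
            )
        if self.warn_max is not None and self.warn_max < self.rec_max:
            raise DataValidationError(
                "warning.max", f"({self.warn_max}) must be >= recommended.max ({self.rec_max})"
            )
        ts = [s.timestamp for s in self.samples]
        if ts != sorted(ts):
            raise DataValidationError("samples", "must be sorted ascending by timestamp")


@dataclass(frozen=True)
class MeasurementGroup:
    """A named category holding one or more measurements, in display order."""

    label: str
    measurements: tuple[Measurement, ...]

    def __post_init__(self):
        if not self.label:
            raise DataValidationError("label", "group label must be non-empty")
        if not self.measurements:
            raise DataValidationError("measurements", "group must hold >= 1 measurement")


@dataclass(frozen=True)
class HealthDataset:
    """The parsed tree of groups -> measurements -> samples."""

    groups: tuple[MeasurementGroup, ...]

    def __post_init__(self):
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise DataValidationError("groups", "group labels must be unique")
        keys = [(g.label, m.label) for g in self.groups for m in g.measurements]
        if len(set(keys)) != len(keys):
            raise DataValidationError(
                "groups", "(group label, measurement label) pairs must be unique"
            )

    def iter_measurements(self) -> Iterable[tuple[MeasurementGroup, Measurement]]:
        for g in self.groups:
            for m in g.measurements:
                yield g, m

    @property
    def n_measurements(self) -> int:
        return sum(len(g.measurements) for g in self.groups)


@dataclass(frozen=True)
class Snapshot:
    """One sample per measurement at one logical time point.

    ``entries`` maps (group label, measurement label) to the chosen Sample.
    """

    index: int
    entries: dict[tuple[str, str], Sample]


class SnapshotMode(str, Enum):
    BY_INDEX = "by_index"
    NEAREST_TIME = "nearest_time"


# ---------------------------------------------------------------------------
# JSON reading / writing

def _require(obj: dict, key: str, path: str):
    if key not in obj:
        raise DataValidationError(f"{path}.{key}", "missing required key")
    return obj[key]


def _number(x, path: str) -> float:
    if isinstance(x, bool) or not isinstance(x, (int, float)):
        raise DataValidationError(path, f"expected a number, got {type(x).__name__}")
    if not math.isfinite(x):
        raise DataValidationError(path, "must be finite")
    return float(x)


def _string(x, path: str) -> str:
    if not isinstance(x, str):
        raise DataValidationError(path, f"expected a string, got {type(x).__name__}")
    return x


def _parse_sample(obj, path: str) -> Sample:
    if not isinstance(obj, dict):
        raise DataValidationError(path, "expected an object")
    ts = _number(_require(obj, "timestamp", path), f"{path}.timestamp")
    if ts < 0:
        raise DataValidationError(f"{path}.timestamp", "must be >= 0 (pre-epoch)")
    if ts != int(ts):
        warnings.warn(
            f"{path}.timestamp: fractional seconds truncated ({ts})", stacklevel=4
        )
    value = _number(_require(obj, "value", path), f"{path}.value")
    return Sample(timestamp=int(ts), value=value)


def _parse_measurement(obj, path: str) -> Measurement:
    if not isinstance(obj, dict):
        raise DataValidationError(path, "expected an object")
    label = _string(_require(obj, "label", path), f"{path}.label")
    units = _string(obj.get("units", ""), f"{path}.units")
    rec = _require(obj, "recommended", path)
    if not isinstance(rec, dict):
        raise DataValidationError(f"{path}.recommended", "expected an object")
    rec_min = _number(_require(rec, "min", f"{path}.recommended"), f"{path}.recommended.min")
    rec_max = _number(_require(rec, "max", f"{path}.recommended"), f"{path}.recommended.max")
    warn_min = warn_max = None
    if "warning" in obj:
        warn = obj["warning"]
        if not isinstance(warn, dict):
            raise DataValidationError(f"{path}.warning", "expected an object")
        if "min" in warn:
            warn_min = _number(warn["min"], f"{path}.warning.min")
        if "max" in warn:
            warn_max = _number(warn["max"], f"{path}.warning.max")
    raw_samples = _require(obj, "samples", path)
    if not isinstance(raw_samples, list):
        raise DataValidationError(f"{path}.samples", "expected an array")
    samples = [
        _parse_sample(s, f"{path}.samples[{i}]") for i, s in enumerate(raw_samples)
    ]
    if [s.timestamp for s in samples] != sorted(s.timestamp for s in samples):
        warnings.warn(f"{path}.samples: unsorted timestamps, sorting", stacklevel=3)
        samples.sort(key=lambda s: s.timestamp)
    try:
        return Measurement(
            label=label,
            units=units,
            rec_min=rec_min,
            rec_max=rec_max,
            warn_min=warn_min,
            warn_max=warn_max,
            samples=tuple(samples),
        )
    except DataValidationError as e:
        raise DataValidationError(f"{path}.{e.path}", str(e).split(": ", 1)[1]) from None


def parse_dataset(json_text: str) -> HealthDataset:
    """Parse a JSON data-source document into a :class:`HealthDataset`.

    Document order of groups, measurements and samples is preserved.
    Raises ``json.JSONDecodeError`` (with position) on malformed JSON and
    :class:`DataValidationError` (with a path) on dialect violations.
    """
    doc = json.loads(json_text)
    if not isinstance(doc, dict):
        raise DataValidationError("$", "top level must be an object")
    raw_groups = _require(doc, "groups", "$")
    if not isinstance(raw_groups, list):
        raise DataValidationError("groups", "expected an array")
    groups = []
    for gi, g in enumerate(raw_groups):
        gpath = f"groups[{gi}]"
        if not isinstance(g, dict):
            raise DataValidationError(gpath, "expected an object")
        glabel = _string(_require(g, "label", gpath), f"{gpath}.label")
        raw_ms = _require(g, "measurements", gpath)
        if not isinstance(raw_ms, list) or not raw_ms:
            raise DataValidationError(
                f"{gpath}.measurements", "expected a non-empty array"
            )
        ms = [
            _parse_measurement(m, f"{gpath}.measurements[{mi}]")
            for mi, m in enumerate(raw_ms)
        ]
        if not glabel:
            raise DataValidationError(f"{gpath}.label", "must be non-empty")
        groups.append(MeasurementGroup(label=glabel, measurements=tuple(ms)))
    return HealthDataset(groups=tuple(groups))


def serialize_dataset(ds: HealthDataset) -> str:
    """Write a dataset back to JSON text in the canonical dialect.

    Round-trips: ``parse_dataset(serialize_dataset(ds)) == ds``.  Warning
    keys are emitted only where the bounds are present.
    """
    def m_obj(m: Measurement) -> dict:
        obj: dict = {
            "label": m.label,
            "units": m.units,
            "recommended": {"min": m.rec_min, "max": m.rec_max},
        }
        if m.warn_min is not None or m.warn_max is not None:
            warn: dict = {}
            if m.warn_min is not None:
                warn["min"] = m.warn_min
            if m.warn_max is not None:
                warn["max"] = m.warn_max
            obj["warning"] = warn
        obj["samples"] = [
            {"timestamp": s.timestamp, "value": s.value} for s in m.samples
        ]
        return obj

    doc = {
        "groups": [
            {"label": g.label, "measurements": [m_obj(m) for m in g.measurements]}
            for g in ds.groups
        ]
    }
    return json.dumps(doc, indent=2)


def validate_dataset(ds: HealthDataset) -> list[str]:
    """Return a list of problems that make a dataset non-renderable (empty if none)."""
    issues = []
    if not ds.groups:
        issues.append("dataset has no groups")
    for g, m in ds.iter_measurements():
        if not m.samples:
            issues.append(f"{g.label}/{m.label}: no samples")
    return issues


# ---------------------------------------------------------------------------
# Epoch timestamps

def epoch_to_utc(ts: int) -> datetime:
    """Convert Unix epoch seconds to a timezone-aware GMT datetime.

    No local-timezone adjustment is ever applied: 1420798224 maps to
    2015-01-09 10:10:24 GMT regardless of host configuration.
    """
    if ts < 0:
        raise ValueError(f"pre-epoch timestamp: {ts}")
    return datetime.fromtimestamp(ts, tz=timezone.utc)


def utc_to_epoch(dt: datetime) -> int:
    """Convert a GMT datetime to Unix epoch seconds (inverse of epoch_to_utc).

    Naive datetimes are interpreted as GMT.
    """
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    ts = int(dt.timestamp())
    if ts < 0:
        raise ValueError(f"pre-epoch datetime: {dt.isoformat()}")
    return ts


# ---------------------------------------------------------------------------
# Snapshot extraction

def extract_snapshots(
    ds: HealthDataset,
    mode: SnapshotMode | str = SnapshotMode.BY_INDEX,
    targets: Sequence[int] = (0,),
) -> list[Snapshot]:
    """Pick one sample per measurement for each target, yielding one Snapshot per target.

    ``by_index`` (strict) requires every measurement to have the same sample
    count and takes the i-th sample everywhere; ``nearest_time`` picks, per
    measurement, the sample minimizing ``|timestamp - target|`` (earlier
    sample wins ties).
    """
    mode = SnapshotMode(mode)
    pairs = list(ds.iter_measurements())
    if not pairs:
        raise ValueError("cannot extract snapshots from an empty dataset")
    for g, m in pairs:
        if not m.samples:
            raise ValueError(f"{g.label}/{m.label} has no samples")

    snapshots = []
    if mode is SnapshotMode.BY_INDEX:
        counts = {(g.label, m.label): len(m.samples) for g, m in pairs}
        if len(set(counts.values())) > 1:
            detail = ", ".join(f"{g}/{m}={c}" for (g, m), c in counts.items())
            raise ValueError(f"ragged sample counts across measurements: {detail}")
        n = next(iter(counts.values()))
        for si, idx in enumerate(targets):
            if not 0 <= idx < n:
                raise IndexError(f"snapshot index {idx} out of range [0, {n})")
            entries = {(g.label, m.label): m.samples[idx] for g, m in pairs}
            snapshots.append(Snapshot(index=si, entries=entries))
    else:
        for si, t in enumerate(targets):
            entries = {
                (g.label, m.label): min(m.samples, key=lambda s: (abs(s.timestamp - t), s.timestamp))
                for g, m in pairs
            }
            snapshots.append(Snapshot(index=si, entries=entries))
    return snapshots
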