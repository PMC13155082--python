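"""Reading, validating, and writing raw wrist-accelerometer recordings.

A recording is a 100 Hz tri-axial acceleration time series with a free-text
annotation column that embeds the activity label and its MET value, e.g.
``"sleeping; MET 0.95"``.  MET (metabolic equivalent of task) expresses
energy expenditure as a multiple of resting metabolic rate, so 1.0 is quiet
rest and values below 1.0 indicate sleep.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Nominal sampling rate of the wristband sensor.
SAMPLING_HZ = 100

#: Samples per hour at 100 Hz: 100 * 60 * 60.
SAMPLES_PER_HOUR = 360_000

#: Canonical CSV header of the raw format.
COLUMNS = ("time", "x", "y", "z", "annotation")

#: Age bins used for the cohort demographics.
AGE_GROUPS = ("18-29", "30-37", "38-52", "53+")
SEXES = ("M", "F")

# MET values are embedded as ";MET <d.d>" (the separator may carry a space,
# as in "sleeping; MET 0.95"); the digits on both sides of the point are
# required, so "MET 7" does not match.
MET_PATTERN = re.compile(r";\s*MET\s+(\d+\.\d+)")


class RecordingFormatError(ValueError):
    """The file does not follow the five-column recording dialect."""


class RecordingParseError(ValueError):
    """A row of the file could not be parsed (reported with its line number)."""


class InsufficientDataError(ValueError):
    """The recording is too short for the requested computation."""


def _normalize_age_group(value: str) -> str:
    v = str(value).strip().replace("–", "-").replace("—", "-")
    if v in ("53", ">=53", "≥53", "53+"):
        return "53+"
    return v


@dataclass(frozen=True)
class ParticipantMeta:
    """Demographics attached to one participant: an age bin and sex."""

    age_group: str
    sex: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_group", _normalize_age_group(self.age_group))
        object.__setattr__(self, "sex", str(self.sex).strip().upper())
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}; expected one of {AGE_GROUPS}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {SEXES}")


@dataclass
class Recording:
    """One participant's tri-axial recording.

    ``time`` holds integer millisecond timestamps (monotone non-decreasing so
    duplicate timestamps remain representable for quality checks); ``x``,
    ``y``, ``z`` are accelerations in g; ``annotation`` is an object array of
    ``str`` or ``None``.
    """

    participant_id: str
    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    annotation: np.ndarray
    meta: ParticipantMeta

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        self.annotation = np.asarray(self.annotation, dtype=object)
        n = len(self.time)
        if n < 1:
            raise ValueError("a recording needs at least one sample")
        for name in ("x", "y", "z", "annotation"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has length {len(getattr(self, name))}, expected {n}")
        if n > 1 and np.any(np.diff(self.time) < 0):
            raise ValueError("timestamps must be monotone non-decreasing")

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class ContinuityReport:
    """Temporal-consistency summary of a recording.

    ``delta_t`` is the absolute difference between the duration implied by
    the sample count at the nominal 100 Hz rate and the duration implied by
    the first/last timestamps; a regular clock drives it to zero.
    """

    n_samples: int
    n_duplicates: int
    modal_interval_s: float
    count_hours: float
    timestamp_hours: float
    delta_t: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def parse_met(annotation: Optional[str]) -> Optional[float]:
    """Extract the MET value embedded in an annotation string.

    Returns the first decimal number following the ``;MET`` marker, or
    ``None`` when the input is ``None`` or carries no parsable MET.
    """
    if annotation is None:
        return None
    m = MET_PATTERN.search(annotation)
    if m is None:
        logger.debug("annotation without parsable MET: %r", annotation)
        return None
    return float(m.group(1))


def samples_to_hours(n: int) -> float:
    """Convert a sample count to hours at the nominal 100 Hz rate (n / 360,000)."""
    if n < 0:
        raise ValueError(f"sample count must be non-negative, got {n}")
    return n / SAMPLES_PER_HOUR


def extract_met_series(rec: Recording) -> np.ndarray:
    """Per-sample MET series parsed from the annotations (NaN where absent).

    Length always equals the recording length; positions whose annotation
    does not match the MET pattern are NaN.
    """
    cache: dict = {}
    out = np.empty(rec.n_samples, dtype=np.float64)
    for i, ann in enumerate(rec.annotation):
        try:
            v = cache[ann]
        except (KeyError, TypeError):
            v = parse_met(ann)
            try:
                cache[ann] = v
            except TypeError:  # pragma: no cover - annotations are hashable strings
                pass
        out[i] = np.nan if v is None else v
    return out


def check_continuity(rec: Recording) -> ContinuityReport:
    """Audit sampling regularity: duplicates, modal inter-sample gap, and the
    deviation between count-derived and timestamp-derived durations."""
    if rec.n_samples < 2:
        raise InsufficientDataError("continuity check needs at least 2 samples")
    d = np.diff(rec.time)
    n_dup = int(np.count_nonzero(d == 0))
    values, counts = np.unique(d, return_counts=True)
    modal_interval_s = float(values[int(np.argmax(counts))]) / 1000.0
    count_hours = rec.n_samples / SAMPLES_PER_HOUR
    timestamp_hours = float(rec.time[-1] - rec.time[0]) / 3_600_000.0
    return ContinuityReport(
        n_samples=rec.n_samples,
        n_duplicates=n_dup,
        modal_interval_s=modal_interval_s,
        count_hours=count_hours,
        timestamp_hours=timestamp_hours,
        delta_t=abs(count_hours - timestamp_hours),
    )


def read_recording(path, meta: ParticipantMeta, participant_id: Optional[str] = None) -> Recording:
    """Load a five-column recording CSV (``time,x,y,z,annotation``).

    Columns may appear in any order but all five must be present.  Empty
    annotation cells become ``None``.  A non-numeric acceleration or
    timestamp cell aborts the load with its 1-based file line number: silent
    row loss would corrupt the 100 Hz clock.  Empty acceleration cells are
    kept as NaN and left for the conditioning stage to drop.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    for col in COLUMNS:
        if col not in df.columns:
            raise RecordingFormatError(f"{path.name}: missing required column {col!r}")

    def numeric(col: str, allow_empty: bool) -> np.ndarray:
        raw = df[col]
        empty = raw.str.strip() == ""
        vals = pd.to_numeric(raw.mask(empty), errors="coerce")
        bad = vals.isna() & ~empty
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 one-based
            raise RecordingParseError(f"{path.name}: non-numeric {col!r} value at line {line}")
        if not allow_empty and empty.any():
            line = int(np.flatnonzero(empty.to_numpy())[0]) + 2
            raise RecordingParseError(f"{path.name}: empty {col!r} value at line {line}")
        return vals.to_numpy(dtype=np.float64)

    time = numeric("time", allow_empty=False).astype(np.int64)
    x = numeric("x", allow_empty=True)
    y = numeric("y", allow_empty=True)
    z = numeric("z", allow_empty=True)
    annotation = np.array([a if a != "" else None for a in df["annotation"]], dtype=object)
    if participant_id is None:
        participant_id = path.stem
    return Recording(participant_id, time, x, y, z, annotation, meta)


def write_recording(rec: Recording, path) -> None:
    """Write a recording back to the five-column CSV dialect.

    Accelerations are printed with six decimals; reading the file back
    reproduces the recording to that precision (and timestamps/annotations
    exactly).
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "time": rec.time,
            "x": rec.x,
            "y": rec.y,
            "z": rec.z,
            "annotation": ["" if a is None else a for a in rec.annotation],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
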