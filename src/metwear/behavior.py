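"""Behavioral interpretation of MET series.

Three consumers of a continuous (gap-free) MET stream:

* intensity summaries — per-sample MET values are bucketed into the five
  standard intensity bands (sleep < 1.0, sedentary [1.0, 1.6), light
  [1.6, 3.0), moderate [3.0, 6.0), vigorous >= 6.0) and converted to hours
  at the 100 Hz rate;
* sleep-stage segmentation — first-order differencing of a window-level
  activity series plus an adaptive threshold theta = mu + k*sigma locates
  abrupt level shifts, which partition the sleep period into ordinal
  stage segments;
* sedentary alerts — maximal runs of low-MET windows at least Ws windows
  long become events, one alert each (further alerts are suppressed until a
  non-sedentary window resets the bout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .records import SAMPLES_PER_HOUR, SAMPLING_HZ


class IntensityLevel(Enum):
    """Standard MET intensity bands; order follows increasing energy."""

    SLEEP = 0
    SEDENTARY = 1
    LIGHT = 2
    MODERATE = 3
    VIGOROUS = 4


#: Half-open internal boundaries of the intensity bands.
_BAND_EDGES = (1.0, 1.6, 3.0, 6.0)
_LEVELS = tuple(IntensityLevel)


def classify_intensity(met: float) -> IntensityLevel:
    """Band lookup for one MET value (half-open at every internal edge)."""
    if met <= 0:
        raise ValueError(f"MET must be positive, got {met}")
    return _LEVELS[int(np.searchsorted(_BAND_EDGES, met, side="right"))]


@dataclass(frozen=True)
class ActivitySummary:
    """Hours spent per intensity level for one participant."""

    participant_id: str
    total_hours: float
    hours: dict

    def as_dict(self) -> dict:
        out = {"participant_id": self.participant_id, "total_hours": self.total_hours}
        out.update({level.name.lower(): h for level, h in self.hours.items()})
        return out


def summarize_activity(met_values: np.ndarray, participant_id: str = "") -> ActivitySummary:
    """Count samples per intensity band and convert to hours (N_k / 360,000).

    The series must already be repaired: any remaining missing value is an
    error.  Per-level hours always sum to the total recording hours.
    """
    met_values = np.asarray(met_values, dtype=np.float64)
    if np.isnan(met_values).any():
        raise ValueError("MET series still contains missing values; repair it first")
    if len(met_values) and met_values.min() <= 0:
        raise ValueError("MET values must be positive")
    band = np.searchsorted(_BAND_EDGES, met_values, side="right")
    counts = np.bincount(band, minlength=len(_LEVELS))
    hours = {level: counts[i] / SAMPLES_PER_HOUR for i, level in enumerate(_LEVELS)}
    return ActivitySummary(
        participant_id=participant_id,
        total_hours=len(met_values) / SAMPLES_PER_HOUR,
        hours=hours,
    )


@dataclass
class ChangePointSet:
    """Detected change points plus the adaptive-threshold trace.

    ``indices`` are positions in the analyzed series (index t means the
    level shifted between t-1 and t); ``thresholds[t-1]`` is the threshold
    in force when the difference into position t was tested.
    """

    indices: np.ndarray
    thresholds: np.ndarray
    k: float
    lam: float
    refractory: int


def detect_changepoints(
    series: np.ndarray,
    k: float = 3.0,
    lam: float = 0.05,
    refractory: int = 2,
) -> ChangePointSet:
    """Adaptive-threshold change-point detection on first differences.

    The base threshold is theta = mu + k*sigma of the differenced series
    over the whole analyzed span.  Scanning in time order, position t is
    flagged when |dx(t)| > theta(t); after each detection the threshold is
    incremented by lam * max|dx(i)|, i <= t (duplicate suppression — applied
    only at detections, since incrementing at every step would silence the
    detector) and the next ``refractory`` positions are skipped.  A constant
    series yields sigma = 0, theta = 0, and no detections.
    """
    series = np.asarray(series, dtype=np.float64)
    if len(series) < 3:
        raise ValueError("change-point detection needs at least 3 points")
    if k <= 0:
        raise ValueError("k must be positive")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if refractory < 0:
        raise ValueError("refractory must be non-negative")
    d = np.diff(series)
    theta = float(d.mean() + k * d.std(ddof=0))
    abs_d = np.abs(d)
    indices: list[int] = []
    thresholds = np.empty(len(d), dtype=np.float64)
    running_max = 0.0
    skip_until = -1
    for t in range(len(d)):
        running_max = max(running_max, abs_d[t])
        thresholds[t] = theta
        if t <= skip_until:
            continue
        if abs_d[t] > theta:
            indices.append(t + 1)
            theta += lam * running_max
            skip_until = t + refractory
    return ChangePointSet(
        indices=np.array(indices, dtype=int),
        thresholds=thresholds,
        k=k,
        lam=lam,
        refractory=refractory,
    )


@dataclass(frozen=True)
class SleepSegment:
    """One ordinal sleep-stage segment, in window coordinates."""

    pattern: int
    start_window: int
    end_window: int  # exclusive
    duration_hours: float


@dataclass
class SleepSegmentation:
    """Ordinal segments tiling the sleep period between change points."""

    total_sleep_hours: float
    segments: list


def find_sleep_period(
    met_values: np.ndarray,
    min_hours: float = 2.0,
    fs: float = SAMPLING_HZ,
) -> tuple[int, int] | None:
    """Locate the sleep period: the longest run of MET < 1.0 lasting at
    least ``min_hours``.  Returns [start, end) sample indices or None."""
    met_values = np.asarray(met_values, dtype=np.float64)
    low = met_values < 1.0
    if not low.any():
        return None
    padded = np.concatenate(([False], low, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    lengths = ends - starts
    best = int(np.argmax(lengths))
    if lengths[best] < min_hours * 3600 * fs:
        return None
    return int(starts[best]), int(ends[best])


def segment_sleep(
    window_series: np.ndarray,
    cps: ChangePointSet,
    samples_per_window: int = 10_000,
) -> SleepSegmentation:
    """Partition the analyzed sleep span into segments between change points.

    Segments are numbered 1..n in time order; with no change points the
    whole span is one segment.  Durations telescope to the span length.
    """
    n = len(window_series)
    if n == 0:
        return SleepSegmentation(total_sleep_hours=0.0, segments=[])
    bounds = [0] + [int(i) for i in cps.indices if 0 < i < n] + [n]
    segments = []
    for pattern, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        segments.append(
            SleepSegment(
                pattern=pattern,
                start_window=a,
                end_window=b,
                duration_hours=(b - a) * samples_per_window / SAMPLES_PER_HOUR,
            )
        )
    total = n * samples_per_window / SAMPLES_PER_HOUR
    return SleepSegmentation(total_sleep_hours=total, segments=segments)


@dataclass(frozen=True)
class SedentaryEvent:
    """A sustained low-MET episode, in window coordinates (inclusive end)."""

    start_window: int
    end_window: int
    onset_sample: int
    onset_timestamp: int | None
    alert_emitted: bool = True


def sedentary_constants(
    window_len: int = 10_000,
    fs: float = SAMPLING_HZ,
    minutes: float = 30.0,
) -> tuple[int, int]:
    """Duration criterion in samples and windows: 30 min at 100 Hz is
    180,000 samples, i.e. Ws = 18 windows of 10,000 samples."""
    if window_len <= 0 or fs <= 0 or minutes <= 0:
        raise ValueError("window length, rate, and duration must be positive")
    n_samples = int(round(minutes * 60 * fs))
    if n_samples % window_len != 0:
        warnings.warn(
            f"{minutes} min is not a whole number of {window_len}-sample windows; rounding down"
        )
    return n_samples, n_samples // window_len


def detect_sedentary_events(
    window_mets: np.ndarray,
    threshold: float = 1.6,
    ws: int = 18,
    window_len: int = 10_000,
    window_start_times: np.ndarray | None = None,
) -> list[SedentaryEvent]:
    """Detect sedentary events from window-mean MET values.

    A window is low when its mean MET is strictly below ``threshold``
    (a window exactly at the threshold is non-sedentary).  An event is a
    maximal run of low windows at least ``ws`` long; its onset is the start
    of the run's first window and it emits exactly one alert — after the
    alert, suppression lasts until a non-low window ends the bout.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if ws < 1:
        raise ValueError("ws must be at least 1")
    window_mets = np.asarray(window_mets, dtype=np.float64)
    if len(window_mets) == 0:
        return []
    low = window_mets < threshold
    padded = np.concatenate(([False], low, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    events = []
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start < ws:
            continue
        onset_sample = int(start) * window_len
        ts = int(window_start_times[start]) if window_start_times is not None else None
        events.append(
            SedentaryEvent(
                start_window=int(start),
                end_window=int(end) - 1,
                onset_sample=onset_sample,
                onset_timestamp=ts,
                alert_emitted=True,
            )
        )
    return events
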