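"""Annotation-gap enumeration, duration clustering, and MET imputation.

Annotation gaps in the raw recordings concentrate around activity-state
transitions, so they are treated as short transition buffers rather than
measurement failure.  The repair stage (1) enumerates maximal runs of
missing MET values, (2) characterizes the gap-duration distribution with
1-D DBSCAN so unusually long gaps are surfaced as anomalies, and
(3) fills every gap with the mean of its flanking MET values (edge gaps
are extended from the single available side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .records import SAMPLING_HZ

logger = logging.getLogger(__name__)


class UnimputableError(ValueError):
    """The series holds no observed value to impute from."""


@dataclass(frozen=True)
class GapSegment:
    """A maximal run of missing MET values: [start, end) sample indices."""

    start: int
    end: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gap end must exceed start")


@dataclass
class GapClusterReport:
    """DBSCAN labelling of gap durations; label -1 marks anomalous gaps."""

    labels: np.ndarray
    eps: float
    min_pts: int
    n_clusters: int
    anomalous_gaps: list = field(default_factory=list)


def enumerate_gaps(values: np.ndarray, fs: float = SAMPLING_HZ) -> list[GapSegment]:
    """Maximal NaN runs of a MET series, in start order.

    The returned segments partition the missing positions exactly: they are
    disjoint and their union is the NaN set.
    """
    isna = np.isnan(np.asarray(values, dtype=np.float64))
    if not isna.any():
        return []
    padded = np.concatenate(([False], isna, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [GapSegment(int(s), int(e), (int(e) - int(s)) / fs) for s, e in zip(starts, ends)]


def cluster_gap_durations(gaps: list[GapSegment], eps: float = 300.0, min_pts: int = 3) -> GapClusterReport:
    """Cluster the 1-D gap-duration set with DBSCAN (Euclidean distance).

    Gaps are processed in ascending (duration, start) order so border points
    reachable from two clusters land deterministically in the
    first-processed cluster.  Noise-labelled gaps (label -1) are the
    anomalous durations; clustering is diagnostic only and does not change
    how gaps are imputed.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be at least 1")
    if not gaps:
        return GapClusterReport(np.empty(0, dtype=int), eps, min_pts, 0, [])
    durations = np.array([g.duration_s for g in gaps], dtype=np.float64)
    starts = np.array([g.start for g in gaps])
    order = np.lexsort((starts, durations))
    sorted_labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(durations[order].reshape(-1, 1))
    labels = np.empty(len(gaps), dtype=int)
    labels[order] = sorted_labels
    n_clusters = len(set(labels.tolist()) - {-1})
    anomalous = [gaps[i] for i in np.flatnonzero(labels == -1)]
    if anomalous:
        logger.info("%d anomalous gap(s) outside every duration cluster", len(anomalous))
    return GapClusterReport(labels, eps, min_pts, n_clusters, anomalous)


def impute_gaps(values: np.ndarray) -> np.ndarray:
    """Fill every gap with the mean of the nearest flanking MET values.

    An interior gap takes the single constant (prev + next) / 2; a trailing
    gap is forward-filled with prev alone, and a leading gap backward-filled
    with next alone by symmetry.  Observed positions are never altered, the
    operation is idempotent, and fills are convex combinations of observed
    values so the output range never exceeds the input range.
    """
    values = np.asarray(values, dtype=np.float64)
    if np.all(np.isnan(values)):
        raise UnimputableError("cannot impute an all-missing MET series")
    out = values.copy()
    for gap in enumerate_gaps(values):
        prev = out[gap.start - 1] if gap.start > 0 else np.nan
        nxt = values[gap.end] if gap.end < len(values) else np.nan
        if np.isnan(prev):
            fill = nxt
        elif np.isnan(nxt):
            fill = prev
        else:
            fill = (prev + nxt) / 2.0
        out[gap.start : gap.end] = fill
    return out
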