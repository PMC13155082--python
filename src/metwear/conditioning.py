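"""Acceleration-signal conditioning: outlier handling and smoothing.

Sensor spikes (loose straps, knocks) are scored per sample with an
isolation forest over the (x, y, z) vectors; the anomaly score follows the
standard definition S(x) = 2^(-E[h(x)]/c(n)) where h is the isolation
depth.  Flagged samples are replaced by the mean of their nearest
non-flagged neighbours, then each axis is smoothed with a short moving
average.  Conditioning touches the acceleration channels only — never the
MET label stream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.ensemble import IsolationForest

from .records import Recording

logger = logging.getLogger(__name__)


@dataclass
class AnomalyScores:
    """Per-sample anomaly scores in (0, 1] and the flagged mask."""

    score: np.ndarray
    flagged: np.ndarray
    contamination: float


@dataclass(frozen=True)
class SmoothingConfig:
    """Moving-average stencil.

    The default window of 10 uses the asymmetric stencil [n-5, n+4]
    (five left neighbours, the point itself, four right neighbours).  At the
    edges the stencil is truncated to the available samples and the divisor
    shrinks accordingly.
    """

    window: int = 10

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be at least 1")

    @property
    def left_span(self) -> int:
        return self.window // 2

    @property
    def right_span(self) -> int:
        return self.window - 1 - self.window // 2


def drop_incomplete_rows(rec: Recording) -> Recording:
    """Remove rows whose acceleration values are missing (NaN).

    Annotation gaps are *not* treated here; they go through the repair
    stage so the label clock stays aligned with the signal clock.
    """
    keep = np.isfinite(rec.x) & np.isfinite(rec.y) & np.isfinite(rec.z)
    if keep.all():
        return rec
    logger.info("%s: dropping %d rows with missing acceleration", rec.participant_id, int((~keep).sum()))
    return Recording(
        rec.participant_id,
        rec.time[keep],
        rec.x[keep],
        rec.y[keep],
        rec.z[keep],
        rec.annotation[keep],
        rec.meta,
    )


def score_anomalies(
    rec: Recording,
    n_trees: int = 100,
    contamination: float = 0.01,
    seed: int = 0,
) -> AnomalyScores:
    """Isolation-forest anomaly score per sample; flag the top quantile.

    Scoring runs per recording rather than pooled across participants so
    inter-individual scale differences cannot mask within-record spikes.
    ``flagged`` marks scores strictly above the (1 - contamination)
    quantile, so a degenerate constant recording flags nothing.
    """
    if rec.n_samples < 2:
        raise ValueError("anomaly scoring needs at least 2 samples")
    if not 0.0 < contamination < 0.5:
        raise ValueError("contamination must lie in (0, 0.5)")
    X = np.column_stack([rec.x, rec.y, rec.z])
    forest = IsolationForest(
        n_estimators=n_trees,
        max_samples=min(256, len(X)),
        random_state=seed,
        n_jobs=1,
    ).fit(X)
    # sklearn's score_samples returns the negated standard score, so negate
    # back to S(x) = 2^(-E[h(x)]/c(n)) in (0, 1].
    score = -forest.score_samples(X)
    cut = np.quantile(score, 1.0 - contamination)
    flagged = score > cut
    if not flagged.any():
        warnings.warn("no sample scored above the flagging quantile (degenerate or tied scores)")
    return AnomalyScores(score=score, flagged=flagged, contamination=contamination)


def replace_outliers(rec: Recording, flags: np.ndarray, span: int = 5) -> Recording:
    """Replace each flagged sample by the mean of nearby non-flagged samples.

    Up to ``span`` non-flagged samples on each side contribute.  A flagged
    sample with no non-flagged neighbour in reach is left unmodified (with a
    warning) rather than invented.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != rec.n_samples:
        raise ValueError("flag mask length must match the recording")
    if not flags.any():
        return rec
    x, y, z = rec.x.copy(), rec.y.copy(), rec.z.copy()
    good_idx = np.flatnonzero(~flags)
    for i in np.flatnonzero(flags):
        pos = np.searchsorted(good_idx, i)
        neighbours = np.concatenate([good_idx[max(0, pos - span) : pos], good_idx[pos : pos + span]])
        if len(neighbours) == 0:
            warnings.warn(f"flagged sample {i} has no non-flagged neighbour; left unmodified")
            continue
        x[i] = rec.x[neighbours].mean()
        y[i] = rec.y[neighbours].mean()
        z[i] = rec.z[neighbours].mean()
    return Recording(rec.participant_id, rec.time, x, y, z, rec.annotation, rec.meta)


def moving_average(signal: np.ndarray, cfg: SmoothingConfig | int = SmoothingConfig()) -> np.ndarray:
    """Moving average over the (possibly asymmetric) stencil of ``cfg``.

    Output is bounded by the input range, commutes with adding a constant
    and with positive scaling, and a window of 1 is the identity.
    """
    if isinstance(cfg, int):
        cfg = SmoothingConfig(cfg)
    signal = np.asarray(signal, dtype=np.float64)
    n = len(signal)
    if n == 0 or cfg.window == 1:
        return signal.copy()
    csum = np.concatenate([[0.0], np.cumsum(signal)])
    idx = np.arange(n)
    lo = np.maximum(idx - cfg.left_span, 0)
    hi = np.minimum(idx + cfg.right_span + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def condition_recording(
    rec: Recording,
    n_trees: int = 100,
    contamination: float = 0.01,
    seed: int = 0,
    window: int = 10,
    span: int = 5,
) -> tuple[Recording, AnomalyScores]:
    """Full conditioning pass: drop incomplete rows, score and replace
    outliers, then smooth each acceleration axis."""
    rec = drop_incomplete_rows(rec)
    scores = score_anomalies(rec, n_trees=n_trees, contamination=contamination, seed=seed)
    rec = replace_outliers(rec, scores.flagged, span=span)
    cfg = SmoothingConfig(window)
    smoothed = Recording(
        rec.participant_id,
        rec.time,
        moving_average(rec.x, cfg),
        moving_average(rec.y, cfg),
        moving_average(rec.z, cfg),
        rec.annotation,
        rec.meta,
    )
    return smoothed, scores
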