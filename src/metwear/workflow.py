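"""End-to-end helpers chaining the pipeline stages.

Order of operations: conditioning first (it may drop rows with missing
acceleration, and the MET label clock must stay aligned with the signal
clock), then annotation repair on the conditioned recording, then windowed
feature extraction and the behavioral analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import detect_changepoints, ChangePointSet
from .conditioning import condition_recording
from .features import WindowSpec, build_feature_table, segment_windows
from .records import Recording, extract_met_series
from .repair import impute_gaps


def repaired_met(rec: Recording) -> np.ndarray:
    """Parse the annotation stream and impute a gap-free MET series."""
    return impute_gaps(extract_met_series(rec))


def process_recording(
    rec: Recording,
    seed: int = 0,
    contamination: float = 0.01,
    window: int = 10,
) -> tuple[Recording, np.ndarray]:
    """Condition the signal, then repair the MET labels on the same rows."""
    conditioned, _ = condition_recording(rec, contamination=contamination, seed=seed, window=window)
    return conditioned, repaired_met(conditioned)


def cohort_feature_table(
    recordings,
    spec: WindowSpec = WindowSpec(),
    seed: int = 0,
    condition: bool = True,
    contamination: float = 0.01,
) -> pd.DataFrame:
    """Feature table for a list of recordings (condition + repair + extract)."""
    items = []
    for i, rec in enumerate(recordings):
        if condition:
            rec, met = process_recording(rec, seed=seed + i, contamination=contamination)
        else:
            met = repaired_met(rec)
        items.append((rec, met))
    return build_feature_table(items, spec)


def window_met_means(met: np.ndarray, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Window-mean MET values over the recording's full windows."""
    return np.array([met[a:b].mean() for a, b in segment_windows(len(met), spec)])


def window_magnitude_means(rec: Recording, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Window means of the per-sample acceleration vector magnitude.

    This is the default series for sleep change-point detection: the mean
    of |a| per window tracks activity level, whereas the magnitude of the
    window-mean vector would average zero-mean oscillations away.
    """
    mag = np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)
    return np.array([mag[a:b].mean() for a, b in segment_windows(rec.n_samples, spec)])


def sleep_changepoint_series(
    rec: Recording,
    met: np.ndarray,
    sleep_span: tuple[int, int],
    spec: WindowSpec = WindowSpec(),
    signal: str = "magnitude",
) -> np.ndarray:
    """Window-level series over the sleep span for change-point analysis."""
    start, end = sleep_span
    sub = Recording(
        rec.participant_id,
        rec.time[start:end],
        rec.x[start:end],
        rec.y[start:end],
        rec.z[start:end],
        rec.annotation[start:end],
        rec.meta,
    )
    if signal == "magnitude":
        return window_magnitude_means(sub, spec)
    if signal == "met":
        return window_met_means(met[start:end], spec)
    raise ValueError(f"unknown change-point signal {signal!r}; use 'magnitude' or 'met'")
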