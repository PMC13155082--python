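"""Windowed feature extraction for MET regression.

Recordings are cut into non-overlapping 10,000-sample windows (100 s at
100 Hz).  Each window yields 20 features: per-axis mean, standard
deviation, dominant frequency, spectral amplitude, and spectral centroid
(5 x 3 axes), the three pairwise Pearson correlations between axes, and two
demographic codes.  The supervised target is the mean labelled MET over the
window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import Recording, ParticipantMeta, SAMPLING_HZ

#: Representative value per age bin.
AGE_CODES = {"18-29": 24, "30-37": 34, "38-52": 45, "53+": 53}
SEX_CODES = {"M": 1, "F": 0}

#: Fixed feature-column layout of the model matrix (20 features).
FEATURE_COLUMNS = (
    "mean_x", "mean_y", "mean_z",
    "sd_x", "sd_y", "sd_z",
    "fmax_x", "fmax_y", "fmax_z",
    "specamp_x", "specamp_y", "specamp_z",
    "fcenter_x", "fcenter_y", "fcenter_z",
    "corr_xy", "corr_xz", "corr_yz",
    "age_code", "sex_code",
)

ID_COLUMNS = ("participant_id", "window_index", "start_sample")
TARGET_COLUMN = "target_met"


@dataclass(frozen=True)
class WindowSpec:
    """Window length and step, in samples (defaults: 10,000 / 10,000)."""

    length: int = 10_000
    step: int = 10_000

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("window length must be at least 2")
        if self.step < 1:
            raise ValueError("window step must be at least 1")


def segment_windows(n_samples: int, spec: WindowSpec = WindowSpec()) -> list[tuple[int, int]]:
    """Half-open [k*S, k*S + L) ranges that fit entirely in the recording;
    any trailing partial window is dropped."""
    if n_samples < 0:
        raise ValueError("sample count must be non-negative")
    out = []
    start = 0
    while start + spec.length <= n_samples:
        out.append((start, start + spec.length))
        start += spec.step
    return out


def time_features(window: np.ndarray) -> tuple[float, float]:
    """Mean and population standard deviation (divisor N) of a window."""
    window = np.asarray(window, dtype=np.float64)
    if len(window) < 2:
        raise ValueError("time features need at least 2 samples")
    return float(window.mean()), float(window.std(ddof=0))


def freq_features(window: np.ndarray, fs: float = SAMPLING_HZ) -> tuple[float, float, float]:
    """Dominant frequency, spectral amplitude, and spectral centroid.

    The window mean is removed before the transform — otherwise the gravity
    (DC) bin would always dominate the spectrum of raw accelerometer data
    and the dominant frequency would be uninformative.  Magnitudes are taken
    over the one-sided bins i = 0..N/2 (bin i maps to i*fs/N Hz, no zero
    padding); ties in the argmax resolve to the lowest frequency, and a
    window that is zero after mean removal returns (0, 0, 0).
    """
    window = np.asarray(window, dtype=np.float64)
    n = len(window)
    if n < 4:
        raise ValueError("frequency features need at least 4 samples")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    mag = np.abs(np.fft.rfft(window - window.mean()))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec_amp = float(mag.sum())
    if spec_amp == 0.0:
        return 0.0, 0.0, 0.0
    f_max = float(freqs[int(np.argmax(mag))])
    f_center = float((freqs * mag).sum() / spec_amp)
    return f_max, spec_amp, f_center


def axis_correlations(wx: np.ndarray, wy: np.ndarray, wz: np.ndarray) -> tuple[float, float, float]:
    """Pairwise Pearson correlations between the three axis windows.

    A pair involving a zero-variance axis gets r = 0 by convention (the
    coefficient is undefined there and 0 encodes "no linear coupling").
    """
    wx, wy, wz = (np.asarray(w, dtype=np.float64) for w in (wx, wy, wz))
    if not (len(wx) == len(wy) == len(wz)) or len(wx) < 2:
        raise ValueError("axis windows must share a length of at least 2")

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        sa, sb = a.std(ddof=0), b.std(ddof=0)
        if sa == 0.0 or sb == 0.0:
            return 0.0
        return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))

    return corr(wx, wy), corr(wx, wz), corr(wy, wz)


def encode_demographics(meta: ParticipantMeta) -> tuple[int, int]:
    """Numeric codes: representative age per bin, male 1 / female 0."""
    try:
        return AGE_CODES[meta.age_group], SEX_CODES[meta.sex]
    except KeyError as err:  # pragma: no cover - ParticipantMeta already validates
        raise ValueError(f"cannot encode demographics: {err}") from err


@dataclass
class NormalizationModel:
    """Per-feature min/max learned on training rows (min-max scaling)."""

    mins: pd.Series
    maxs: pd.Series


def fit_normalizer(train_rows: pd.DataFrame, columns=FEATURE_COLUMNS) -> NormalizationModel:
    """Learn per-feature min/max on the training rows only."""
    if len(train_rows) < 1:
        raise ValueError("cannot fit a normalizer on an empty training set")
    cols = list(columns)
    sub = train_rows[cols].astype(np.float64)
    return NormalizationModel(mins=sub.min(axis=0), maxs=sub.max(axis=0))


def apply_normalizer(model: NormalizationModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Scale features as (x - min) / (max - min) with the training min/max.

    A feature constant in training maps to 0 everywhere; values outside the
    training range are extrapolated, not clipped, so test rows may fall
    outside [0, 1].
    """
    out = rows.copy()
    span = model.maxs - model.mins
    for col in model.mins.index:
        if span[col] == 0:
            out[col] = 0.0
        else:
            out[col] = (rows[col].astype(np.float64) - model.mins[col]) / span[col]
    return out


def window_features(rec: Recording, start: int, end: int, fs: float = SAMPLING_HZ) -> dict:
    """The 20-feature dictionary for one window of a recording."""
    wx, wy, wz = rec.x[start:end], rec.y[start:end], rec.z[start:end]
    row: dict = {}
    for axis, w in zip("xyz", (wx, wy, wz)):
        row[f"mean_{axis}"], row[f"sd_{axis}"] = time_features(w)
        row[f"fmax_{axis}"], row[f"specamp_{axis}"], row[f"fcenter_{axis}"] = freq_features(w, fs)
    row["corr_xy"], row["corr_xz"], row["corr_yz"] = axis_correlations(wx, wy, wz)
    row["age_code"], row["sex_code"] = encode_demographics(rec.meta)
    return row


def build_feature_table(
    items,
    spec: WindowSpec = WindowSpec(),
    fs: float = SAMPLING_HZ,
) -> pd.DataFrame:
    """Assemble the window-level feature table for a cohort.

    ``items`` is an iterable of ``(Recording, met)`` pairs where ``met`` is
    the per-sample imputed MET series (or ``None`` for prediction-only
    rows).  Each window contributes one row; the target is the mean MET
    over the window.  Recordings shorter than one window contribute no rows
    (with a warning).
    """
    rows = []
    for rec, met in items:
        windows = segment_windows(rec.n_samples, spec)
        if not windows:
            warnings.warn(f"{rec.participant_id}: recording shorter than one window, no feature rows")
            continue
        if met is not None and len(met) != rec.n_samples:
            raise ValueError(f"{rec.participant_id}: MET series length does not match the recording")
        for k, (start, end) in enumerate(windows):
            row = {"participant_id": rec.participant_id, "window_index": k, "start_sample": start}
            row.update(window_features(rec, start, end, fs))
            row[TARGET_COLUMN] = float(np.mean(met[start:end])) if met is not None else np.nan
            rows.append(row)
    columns = list(ID_COLUMNS) + list(FEATURE_COLUMNS) + [TARGET_COLUMN]
    return pd.DataFrame(rows, columns=columns)
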