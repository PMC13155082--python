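"""Synthetic cohort generator with planted ground truth.

Emulates the study's recording conditions — 100 Hz tri-axial wrist
acceleration over a full day–night cycle (~24–27 h) with a diurnal state
schedule, per-state MET labels inside the standard intensity bands, and
intermittent annotation gaps concentrated at state transitions — so every
pipeline stage can be exercised and verified against known ground truth
without any external download.

Signal model per sample: a slowly rotating unit gravity vector plus a
state-dependent sinusoidal oscillation (amplitude and frequency encode the
activity: none while asleep, ~0.2 Hz fidgeting while sedentary, ~1.8 Hz
walking, ~2.8 Hz running) plus white Gaussian sensor noise.  The annotation
stream carries "<state>; MET <value>" with a MET value constant within each
state bout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .records import (
    AGE_GROUPS,
    SAMPLES_PER_HOUR,
    SAMPLING_HZ,
    SEXES,
    ParticipantMeta,
    Recording,
    write_recording,
)

#: Internal MET band edges used to keep sampled labels inside their band.
_BAND_EDGES = (0.0, 1.0, 1.6, 3.0, 6.0, np.inf)


@dataclass(frozen=True)
class StateSpec:
    """One scheduled activity state: duration, MET label, oscillation."""

    name: str
    hours: float
    met: float
    osc_amp: float = 0.0
    osc_freq: float = 0.0

    def __post_init__(self) -> None:
        if self.hours <= 0:
            raise ValueError("state duration must be positive")
        if self.met <= 0:
            raise ValueError("state MET must be positive")


# Canonical 26 h day: a 7 h sleep block with planted sub-stages (quiet /
# restless / movement — distinct oscillation levels so stage boundaries are
# recoverable), morning and evening sedentary stretches, walking bouts, one
# moderate bout and one short vigorous bout, so every intensity band —
# including the sparse high-MET regime — is populated.
DEFAULT_SCHEDULE = (
    StateSpec("sleep_quiet", 1.9, 0.90, 0.0, 0.0),
    StateSpec("sleep_restless", 1.5, 0.95, 0.28, 0.25),
    StateSpec("sleep_quiet", 1.5, 0.90, 0.0, 0.0),
    StateSpec("sleep_movement", 0.3, 0.98, 0.32, 0.5),
    StateSpec("sleep_quiet", 1.8, 0.92, 0.0, 0.0),
    StateSpec("sedentary_morning", 2.0, 1.30, 0.05, 0.2),
    StateSpec("walking", 3.0, 2.20, 0.30, 1.8),
    StateSpec("sedentary", 1.5, 1.20, 0.05, 0.2),
    StateSpec("moderate_activity", 1.0, 4.00, 0.60, 2.2),
    StateSpec("sedentary", 2.0, 1.40, 0.05, 0.2),
    StateSpec("walking", 2.0, 2.50, 0.35, 1.8),
    StateSpec("running", 0.1, 7.00, 1.00, 2.8),
    StateSpec("sedentary_evening", 2.4, 1.30, 0.05, 0.2),
    StateSpec("light_chores", 1.0, 1.80, 0.25, 1.8),
    StateSpec("sedentary_night", 4.0, 1.15, 0.05, 0.2),
)


@dataclass(frozen=True)
class CohortProfile:
    """Generator conditions for one synthetic cohort.

    Gap model: a small fraction ``gap_transition_rate`` of state
    transitions carries an annotation gap centered on the transition; gap
    durations are a mixture of short gaps (90 %, uniform 0.5–10 min) and
    longer outliers (10 %, uniform 20–40 min).  Gaps are deliberately
    sparse: in the real cohort only a handful of participants showed them,
    most were shorter than 20 min, and total missingness stayed below ~1 %.
    """

    n_participants: int = 10
    duration_hours: float = 26.0
    schedule: tuple = DEFAULT_SCHEDULE
    met_jitter: float = 0.03
    noise_sd: float = 0.02
    gap_transition_rate: float = 0.05
    gap_short_minutes: tuple = (0.5, 10.0)
    gap_long_minutes: tuple = (20.0, 40.0)
    gap_long_weight: float = 0.1
    fs: float = SAMPLING_HZ
    seed: int = 1

    def __post_init__(self) -> None:
        total = sum(s.hours for s in self.schedule)
        if total > self.duration_hours + 1e-9:
            raise ValueError(
                f"schedule spans {total:.4f} h, exceeding the {self.duration_hours} h recording"
            )


def default_profile(duration_hours: float = 26.0, n_participants: int = 10, seed: int = 1, **kwargs) -> CohortProfile:
    """The canonical day scaled proportionally to ``duration_hours``."""
    scale = duration_hours / sum(s.hours for s in DEFAULT_SCHEDULE)
    schedule = tuple(replace(s, hours=s.hours * scale) for s in DEFAULT_SCHEDULE)
    return CohortProfile(
        n_participants=n_participants,
        duration_hours=duration_hours,
        schedule=schedule,
        seed=seed,
        **kwargs,
    )


@dataclass
class Bout:
    """A realized state bout in sample coordinates ([start, end))."""

    start: int
    end: int
    name: str
    met: float


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    bouts: list
    true_met: np.ndarray
    gaps: list  # (start, end) sample ranges with missing annotations
    sleep_period: tuple | None  # [start, end) samples of the sleep block
    sleep_changepoints: list  # sample indices of internal sleep-stage shifts
    low_met_episodes: list  # merged [start, end) sample ranges with MET < 1.6

    def as_dict(self) -> dict:
        return {
            "bouts": [[b.start, b.end, b.name, b.met] for b in self.bouts],
            "gaps": [list(g) for g in self.gaps],
            "sleep_period": list(self.sleep_period) if self.sleep_period else None,
            "sleep_changepoints": [int(i) for i in self.sleep_changepoints],
            "low_met_episodes": [list(e) for e in self.low_met_episodes],
        }


def participant_seed(cohort_seed: int, index: int) -> int:
    """Derived per-participant seed, documented for reproducibility."""
    return (cohort_seed * 10_007 + index) % (2**31)


def _band_bounds(met: float) -> tuple[float, float]:
    edges = np.asarray(_BAND_EDGES)
    i = int(np.searchsorted(edges, met, side="right")) - 1
    return float(edges[i]), float(edges[i + 1])


def _sample_bout_met(rng: np.random.Generator, state: StateSpec, jitter: float) -> float:
    lo, hi = _band_bounds(state.met)
    lo = lo + 0.01 if lo > 0 else 0.05
    hi = state.met + 10 * jitter if not np.isfinite(hi) else hi - 0.01
    return float(np.clip(state.met + jitter * rng.standard_normal(), lo, hi))


def sample_demographics(rng: np.random.Generator, n: int) -> list[ParticipantMeta]:
    """Uniform draws over the four age bins and two sexes."""
    return [
        ParticipantMeta(
            age_group=AGE_GROUPS[int(rng.integers(len(AGE_GROUPS)))],
            sex=SEXES[int(rng.integers(len(SEXES)))],
        )
        for _ in range(n)
    ]


def generate_recording(
    profile: CohortProfile,
    participant_index: int = 0,
    participant_id: str | None = None,
    meta: ParticipantMeta | None = None,
) -> tuple[Recording, GroundTruth]:
    """Generate one labeled recording plus its planted ground truth.

    Byte-identical for a fixed profile and participant index.
    """
    rng = np.random.default_rng(participant_seed(profile.seed, participant_index))
    fs = profile.fs
    n_total = int(round(profile.duration_hours * 3600 * fs))
    if participant_id is None:
        participant_id = f"P{participant_index + 1:03d}"
    if meta is None:
        meta = sample_demographics(rng, 1)[0]

    # Realize bouts; the final state absorbs rounding so the total matches.
    bouts: list[Bout] = []
    cursor = 0
    for i, state in enumerate(profile.schedule):
        length = int(round(state.hours * 3600 * fs))
        if i == len(profile.schedule) - 1:
            length = n_total - cursor
        met = _sample_bout_met(rng, state, profile.met_jitter)
        bouts.append(Bout(cursor, cursor + length, state.name, met))
        cursor += length

    time = np.arange(n_total, dtype=np.int64) * 10  # ms at 100 Hz
    t_s = np.arange(n_total, dtype=np.float64) / fs

    # Slowly rotating gravity direction (periods of ~100 min tilt, ~5 h yaw).
    p_tilt, p_yaw = rng.uniform(0, 2 * np.pi, size=2)
    tilt = 0.4 + 0.15 * np.sin(2 * np.pi * t_s / 6000.0 + p_tilt)
    yaw = 2 * np.pi * t_s / 18000.0 + p_yaw
    x = np.sin(tilt) * np.cos(yaw)
    y = np.sin(tilt) * np.sin(yaw)
    z = np.cos(tilt)
    del tilt, yaw

    true_met = np.empty(n_total, dtype=np.float64)
    annotation = np.empty(n_total, dtype=object)
    for state, b in zip(profile.schedule, bouts):
        sl = slice(b.start, b.end)
        true_met[sl] = b.met
        annotation[sl] = f"{b.name}; MET {b.met:.2f}"
        if state.osc_amp > 0 and state.osc_freq > 0:
            phase = rng.uniform(0, 2 * np.pi)
            arg = 2 * np.pi * state.osc_freq * t_s[sl] + phase
            x[sl] += state.osc_amp * np.sin(arg)
            y[sl] += 0.6 * state.osc_amp * np.cos(arg)
            z[sl] += 0.3 * state.osc_amp * np.sin(arg + 1.1)

    x += profile.noise_sd * rng.standard_normal(n_total)
    y += profile.noise_sd * rng.standard_normal(n_total)
    z += profile.noise_sd * rng.standard_normal(n_total)

    # Annotation gaps centered on a random subset of state transitions.
    gaps: list[tuple[int, int]] = []
    for b_prev, b_next in zip(bouts[:-1], bouts[1:]):
        if rng.random() >= profile.gap_transition_rate:
            continue
        if rng.random() < profile.gap_long_weight:
            minutes = rng.uniform(*profile.gap_long_minutes)
        else:
            minutes = rng.uniform(*profile.gap_short_minutes)
        half = int(round(minutes * 60 * fs / 2))
        start = max(0, b_next.start - half)
        end = min(n_total, b_next.start + half)
        annotation[start:end] = None
        gaps.append((start, end))

    rec = Recording(participant_id, time, x, y, z, annotation, meta)

    # Sleep block = the contiguous run of bouts with MET < 1.0.
    sleep_period = None
    sleep_changepoints: list[int] = []
    run_start = None
    for i, b in enumerate(bouts):
        if b.met < 1.0:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            break
    if run_start is not None:
        run_end = run_start
        while run_end + 1 < len(bouts) and bouts[run_end + 1].met < 1.0:
            run_end += 1
        sleep_period = (bouts[run_start].start, bouts[run_end].end)
        sleep_changepoints = [bouts[i].end for i in range(run_start, run_end)]

    # Merged low-MET (< 1.6) episodes: sleep + sedentary stretches.
    low_met_episodes: list[tuple[int, int]] = []
    for b in bouts:
        if b.met < 1.6:
            if low_met_episodes and low_met_episodes[-1][1] == b.start:
                low_met_episodes[-1] = (low_met_episodes[-1][0], b.end)
            else:
                low_met_episodes.append((b.start, b.end))

    truth = GroundTruth(
        bouts=bouts,
        true_met=true_met,
        gaps=gaps,
        sleep_period=sleep_period,
        sleep_changepoints=sleep_changepoints,
        low_met_episodes=low_met_episodes,
    )
    return rec, truth


def generate_cohort(
    profile: CohortProfile,
    n: int | None = None,
    out_dir=None,
) -> list[tuple[Recording, GroundTruth]]:
    """Generate ``n`` participants (ids P001..) with sampled demographics.

    With ``out_dir`` set, each recording is written as a five-column CSV
    next to a cohort metadata YAML and a per-participant ground-truth JSON.
    """
    if n is None:
        n = profile.n_participants
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    demo_rng = np.random.default_rng(profile.seed % (2**31))
    metas = sample_demographics(demo_rng, n)
    cohort = []
    for i in range(n):
        rec, truth = generate_recording(profile, i, meta=metas[i])
        cohort.append((rec, truth))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta_doc = {}
        for rec, truth in cohort:
            write_recording(rec, out_dir / f"{rec.participant_id}.csv")
            meta_doc[rec.participant_id] = {"age_group": rec.meta.age_group, "sex": rec.meta.sex}
            import json

            (out_dir / f"{rec.participant_id}.truth.json").write_text(
                json.dumps(truth.as_dict(), indent=1)
            )
        (out_dir / "cohort.yaml").write_text(yaml.safe_dump(meta_doc, sort_keys=True))
    return cohort
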