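"""Counterbalanced playback schedules: sessions, trials, presentations.

A playback session consists of trials that strictly alternate between
the two stimulus types (the subject's father's song vs a song from a
non-imprinted lineage). Within a trial, stimuli play at a constant
rate — one song every ``stimulus_period`` seconds for
``trial_duration`` seconds — cycling through ``songs_per_male``
different songs of the same male, so the default 2-minute trial holds
12 presentations: 4 repetitions of each of 3 songs. Trials are
separated by ``inter_trial_gap`` seconds. Each subject receives
``sessions_per_comparison`` sessions; the second session starts with
the opposite stimulus type from the first, and the starting type
alternates across subjects (counterbalancing).

The paradigm's third and fourth sessions (same-lineage vs
different-lineage songs) reuse this structure with a different pair of
labels; they are supported via ``stimulus_labels`` but not modelled
further. Sessions are run on different days (two-day intervals); that
is metadata, not scheduled here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FATHER = "father"
NON_IMPRINTED = "non_imprinted"


@dataclass(frozen=True)
class DesignConfig:
    """Schedule parameters; defaults give the standard 2-min/10-s design."""

    trial_duration: float = 120.0
    stimulus_period: float = 10.0
    inter_trial_gap: float = 30.0
    trials_per_session: int = 4
    songs_per_male: int = 3
    sessions_per_comparison: int = 2
    stimulus_labels: tuple[str, str] = (FATHER, NON_IMPRINTED)

    def __post_init__(self) -> None:
        if min(self.trial_duration, self.stimulus_period, self.inter_trial_gap) <= 0:
            raise ValueError("durations must be positive")
        if min(self.trials_per_session, self.songs_per_male,
               self.sessions_per_comparison) < 1:
            raise ValueError("counts must be >= 1")
        n = self.trial_duration / self.stimulus_period
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_duration must be divisible by stimulus_period")

    @property
    def presentations_per_trial(self) -> int:
        return int(round(self.trial_duration / self.stimulus_period))


@dataclass(frozen=True)
class Trial:
    """One trial: a stimulus type and its timed presentations."""

    stimulus_type: str
    presentations: tuple[tuple[float, int], ...]  # (time_s offset, song_index 1..S)


@dataclass(frozen=True)
class Session:
    trials: tuple[Trial, ...]


@dataclass(frozen=True)
class PlaybackSchedule:
    subject_id: str
    sessions: tuple[Session, ...]
    start_with: str = FATHER


@dataclass
class ValidationReport:
    """Invariant check results for one schedule; empty list means clean."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def build_trial(stimulus_type: str, cfg: DesignConfig | None = None) -> Trial:
    """One trial: presentations at 0, period, 2*period, ... cycling songs 1..S.

    With defaults: 12 presentations, songs cycling 1,2,3,1,2,3,... so
    each of the 3 songs plays exactly 4 times.
    """
    cfg = cfg or DesignConfig()
    n = cfg.presentations_per_trial
    pres = tuple((i * cfg.stimulus_period, i % cfg.songs_per_male + 1)
                 for i in range(n))
    return Trial(stimulus_type=stimulus_type, presentations=pres)


def build_subject_schedule(subject_id: str, start_with: str = FATHER,
                           cfg: DesignConfig | None = None) -> PlaybackSchedule:
    """All sessions for one subject with strict within-session alternation.

    Trial types alternate within a session starting from ``start_with``;
    each subsequent session starts with the opposite type from the one
    before, so presentation counts balance across the comparison.
    """
    cfg = cfg or DesignConfig()
    labels = cfg.stimulus_labels
    if start_with not in labels:
        raise ValueError(f"start_with must be one of {labels}")
    other = labels[1] if start_with == labels[0] else labels[0]
    sessions = []
    for s in range(cfg.sessions_per_comparison):
        first, second = (start_with, other) if s % 2 == 0 else (other, start_with)
        trials = tuple(build_trial(first if t % 2 == 0 else second, cfg)
                       for t in range(cfg.trials_per_session))
        sessions.append(Session(trials=trials))
    return PlaybackSchedule(subject_id=subject_id, sessions=tuple(sessions),
                            start_with=start_with)


def counterbalance(subject_ids: list[str], cfg: DesignConfig | None = None,
                   shuffle_seed: int | None = None) -> list[PlaybackSchedule]:
    """Schedules for several subjects with alternating starting type.

    Subjects alternate ``start_with`` in list order (first subject
    starts with the first stimulus label), so an even number of
    subjects splits exactly in half. Pass ``shuffle_seed`` to shuffle
    the subject order reproducibly before assignment. An odd number of
    subjects is necessarily unbalanced by one; this is logged.
    """
    cfg = cfg or DesignConfig()
    if not subject_ids:
        raise ValueError("need at least one subject")
    ids = list(subject_ids)
    if shuffle_seed is not None:
        np.random.default_rng(shuffle_seed).shuffle(ids)
    if len(ids) % 2:
        logger.info("odd number of subjects (%d): starting types split %d/%d",
                    len(ids), (len(ids) + 1) // 2, len(ids) // 2)
    return [build_subject_schedule(sid, cfg.stimulus_labels[i % 2], cfg)
            for i, sid in enumerate(ids)]


def validate_schedule(s: PlaybackSchedule,
                      cfg: DesignConfig | None = None) -> ValidationReport:
    """Check every schedule invariant; returns a report, never raises.

    Checked: strict alternation of trial types within each session,
    presentation times on the stimulus-period grid inside the trial,
    and equal repetition counts for every song index in every trial.
    """
    cfg = cfg or DesignConfig()
    report = ValidationReport()
    expected_reps = cfg.presentations_per_trial // cfg.songs_per_male
    for si, session in enumerate(s.sessions, start=1):
        types = [t.stimulus_type for t in session.trials]
        for a, b in zip(types, types[1:]):
            if a == b:
                report.violations.append(
                    f"alternation: session {si} has consecutive {a!r} trials")
        for ti, trial in enumerate(session.trials, start=1):
            counts: dict[int, int] = {}
            for time_s, song in trial.presentations:
                counts[song] = counts.get(song, 0) + 1
                if not (0 <= time_s < cfg.trial_duration):
                    report.violations.append(
                        f"timing: session {si} trial {ti} presentation at {time_s}s "
                        f"outside [0, {cfg.trial_duration})")
                elif abs(time_s / cfg.stimulus_period
                         - round(time_s / cfg.stimulus_period)) > 1e-9:
                    report.violations.append(
                        f"timing: session {si} trial {ti} presentation at {time_s}s "
                        f"not a multiple of {cfg.stimulus_period}s")
            for song in range(1, cfg.songs_per_male + 1):
                if counts.get(song, 0) != expected_reps:
                    report.violations.append(
                        f"repetition count: session {si} trial {ti} song {song} "
                        f"played {counts.get(song, 0)}x, expected {expected_reps}")
    return report


def schedules_to_frame(schedules: list[PlaybackSchedule]) -> pd.DataFrame:
    """Flatten schedules to one row per presentation.

    Columns: subject_id, session_order, trial_order, stimulus_type,
    presentation_time_s, song_index — the CSV exchange format.
    """
    rows = []
    for s in schedules:
        for si, session in enumerate(s.sessions, start=1):
            for ti, trial in enumerate(session.trials, start=1):
                for time_s, song in trial.presentations:
                    rows.append((s.subject_id, si, ti, trial.stimulus_type,
                                 time_s, song))
    return pd.DataFrame(rows, columns=["subject_id", "session_order",
                                       "trial_order", "stimulus_type",
                                       "presentation_time_s", "song_index"])


def trial_frame(schedules: list[PlaybackSchedule]) -> pd.DataFrame:
    """One row per *trial* (the unit of behavioural observation).

    Columns: subject_id, session_order, trial_order, stimulus_type.
    """
    df = schedules_to_frame(schedules)
    return (df.drop(columns=["presentation_time_s", "song_index"])
              .drop_duplicates()
              .reset_index(drop=True))
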