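"""Parametric generator of Java-sparrow-like songs with known ground truth.

Each note is built by additive synthesis: a fundamental gliding linearly
between ``f0_start`` and ``f0_end`` with an optional sinusoidal FM
"wiggle", optional harmonics (2*f0, 3*f0, ...) and an optional
subharmonic at f0/2, shaped by a slow amplitude envelope. Notes are
separated by silences and the song is peak-normalized.

The generator exists to provide fixtures whose true contours, envelopes
and onsets are known exactly, closing the loop with the contour-scanning
and resynthesis code. ``sample_song_spec`` draws species-plausible
random songs: note counts follow a truncated Poisson with mean 29.48 and
gaps are scaled so the expected song length is about 5.16 s, matching
the average Java sparrow song in the stimulus archive this toolkit
emulates. Fundamental frequencies are drawn from 1.5–6 kHz, the band a
Java sparrow song occupies on a spectrogram; this is a fixture choice,
not a measurement.

Every note receives a 5 ms raised-cosine onset/offset ramp in addition
to its envelope shape: real notes never start with a discontinuity, and
the ramp keeps rendered fixtures free of broadband clicks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from songtool.audio_core import Waveform

EDGE_RAMP_S = 0.005

#: Mean note count of the emulated song archive.
MEAN_NOTE_COUNT = 29.48
#: Mean song duration (s) of the emulated song archive.
MEAN_SONG_DURATION_S = 5.16

_AM_SHAPES = ("flat", "ramp", "bell")


@dataclass(frozen=True)
class NoteSpec:
    """Parameters of one synthetic note.

    ``harmonic_levels`` are dB offsets (<= 0) of the partials at 2*f0,
    3*f0, ...; ``subharmonic_level`` is the dB offset of a partial at
    f0/2 (``None`` for no subharmonic). ``am_shape`` is one of
    ``flat | ramp | bell``.
    """

    onset: float
    duration: float
    f0_start: float
    f0_end: float
    fm_wiggle_hz: float = 0.0
    fm_wiggle_rate: float = 30.0
    harmonic_levels: tuple[float, ...] = ()
    subharmonic_level: float | None = None
    am_shape: str = "bell"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.am_shape not in _AM_SHAPES:
            raise ValueError(f"am_shape must be one of {_AM_SHAPES}")
        if any(lv > 0 for lv in self.harmonic_levels):
            raise ValueError("harmonic levels must be <= 0 dB")
        if self.subharmonic_level is not None and self.subharmonic_level > 0:
            raise ValueError("subharmonic level must be <= 0 dB")


@dataclass(frozen=True)
class SongSpec:
    """An ordered, non-overlapping sequence of notes plus render settings."""

    notes: tuple[NoteSpec, ...]
    sample_rate: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        prev_end = -np.inf
        max_partial = 0.0
        for n in self.notes:
            if n.onset < prev_end:
                raise ValueError("notes must be sorted and non-overlapping")
            prev_end = n.onset + n.duration
            top = max(n.f0_start, n.f0_end) * (1 + len(n.harmonic_levels))
            max_partial = max(max_partial, top)
        if max_partial >= self.sample_rate / 2:
            raise ValueError("highest partial exceeds the Nyquist frequency")


@dataclass
class NoteTruth:
    """Exact per-note ground truth for a rendered song."""

    onset_sample: int
    end_sample: int
    times: np.ndarray       # s from note onset, per-sample
    f0: np.ndarray          # Hz, instantaneous fundamental per sample
    envelope: np.ndarray    # dimensionless amplitude per sample (pre-normalization)


@dataclass
class SongTruth:
    notes: list[NoteTruth] = field(default_factory=list)
    normalization: float = 1.0


def _am_envelope(shape: str, t: np.ndarray, duration: float) -> np.ndarray:
    if shape == "flat":
        env = np.ones_like(t)
    elif shape == "ramp":
        env = 0.2 + 0.8 * t / duration
    else:  # bell
        env = 0.25 + 0.75 * np.sin(np.pi * t / duration) ** 2
    ramp_n = t.searchsorted(EDGE_RAMP_S)
    if ramp_n > 0:
        fade = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        env[:ramp_n] *= fade
        env[-ramp_n:] *= fade[::-1]
    return env


def render(spec: SongSpec) -> tuple[Waveform, SongTruth]:
    """Render a :class:`SongSpec` to audio with exact ground truth.

    Returns the peak-normalized (to 0.9) waveform and a
    :class:`SongTruth` holding each note's true per-sample fundamental
    contour, amplitude envelope and sample positions. Rendering is
    deterministic: the same spec yields bit-identical output.
    """
    fs = spec.sample_rate
    total = 0
    for n in spec.notes:
        total = max(total, int(round(n.onset * fs)) + int(round(n.duration * fs)))
    samples = np.zeros(total)
    truth = SongTruth()

    for note in spec.notes:
        start = int(round(note.onset * fs))
        n_samp = int(round(note.duration * fs))
        t = np.arange(n_samp) / fs
        f0 = (note.f0_start + (note.f0_end - note.f0_start) * t / note.duration
              + note.fm_wiggle_hz * np.sin(2 * np.pi * note.fm_wiggle_rate * t))
        phase = 2 * np.pi * np.cumsum(f0) / fs
        env = _am_envelope(note.am_shape, t, note.duration)

        wave = np.sin(phase)
        for k, level_db in enumerate(note.harmonic_levels, start=2):
            wave = wave + 10 ** (level_db / 20) * np.sin(k * phase)
        if note.subharmonic_level is not None:
            wave = wave + 10 ** (note.subharmonic_level / 20) * np.sin(phase / 2)
        samples[start:start + n_samp] += env * wave
        truth.notes.append(NoteTruth(onset_sample=start, end_sample=start + n_samp,
                                     times=t, f0=f0, envelope=env))

    peak = np.max(np.abs(samples)) if total else 0.0
    if peak > 0:
        norm = 0.9 / peak
        samples *= norm
        truth.normalization = norm
    return Waveform(samples=samples, sample_rate=fs), truth


def sample_song_spec(seed: int, n_notes: int | str = "typical",
                     sample_rate: int = 44100) -> SongSpec:
    """Draw a random species-plausible :class:`SongSpec`.

    With ``n_notes="typical"`` the note count is Poisson with mean
    29.48 truncated at >= 5, and note/gap durations are drawn so the
    expected song duration is about 5.16 s. Note parameters come from
    documented uniform ranges: f0 in [1.5, 6] kHz with glides up to
    +/-25%, FM wiggle depth up to 250 Hz at 20–80 Hz, zero to two
    harmonics at -20..-6 dB, an occasional subharmonic at -30..-12 dB.
    """
    rng = np.random.default_rng(seed)
    if n_notes == "typical":
        count = 0
        while count < 5:
            count = rng.poisson(MEAN_NOTE_COUNT)
    else:
        count = int(n_notes)
        if count < 1:
            raise ValueError("n_notes must be >= 1")

    # mean duration 0.12 s + mean gap 0.055 s = 0.175 s per note,
    # matching 29.48 notes in ~5.16 s.
    notes = []
    t = 0.0
    for _ in range(count):
        duration = rng.uniform(0.06, 0.18)
        f0_start = rng.uniform(1500.0, 6000.0)
        glide = rng.uniform(-0.25, 0.25)
        f0_end = float(np.clip(f0_start * (1 + glide), 1500.0, 6000.0))
        n_harm = rng.integers(0, 3)
        harmonics = tuple(rng.uniform(-20.0, -6.0) for _ in range(n_harm))
        if max(f0_start, f0_end) * (1 + n_harm) >= sample_rate / 2:
            harmonics = ()
        sub = float(rng.uniform(-30.0, -12.0)) if rng.random() < 0.3 else None
        notes.append(NoteSpec(
            onset=t,
            duration=duration,
            f0_start=f0_start,
            f0_end=f0_end,
            fm_wiggle_hz=rng.uniform(0.0, 250.0),
            fm_wiggle_rate=rng.uniform(20.0, 80.0),
            harmonic_levels=harmonics,
            subharmonic_level=sub,
            am_shape=str(rng.choice(_AM_SHAPES)),
        ))
        t += duration + rng.uniform(0.01, 0.10)
    return SongSpec(notes=tuple(notes), sample_rate=sample_rate, seed=seed)
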