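"""Fundamental-frequency contour scanning, simplification and resynthesis.

This is the stimulus-synthesis core of the toolkit. A song note is
simplified in four steps:

1. **scan** — one (time, frequency) point per voiced STFT frame; the
   frequency is the *lowest* spectral peak within ``peak_tolerance_db``
   of the frame's maximum inside the search band, so the fundamental
   wins over a louder harmonic while weak subharmonics are ignored.
2. **sectionize** — points are split into maximal runs that are
   temporally adjacent (gap of at most one hop) and spectrally smooth
   (frequency jump of at most ``jump_threshold_hz``).
3. **simplify** — every section is reduced to its first and last point.
4. **resynthesize** — a phase-continuous sine whose instantaneous
   frequency interpolates linearly between each section's endpoints,
   amplitude-matched frame-by-frame to the original note's RMS
   envelope. Harmonics, subharmonics and fine frequency modulation are
   gone; amplitude modulation, rhythm and note order are untouched.

Times inside a contour are seconds from the *start of the note
segment* (frame centres). The contour carries its own hop duration so
that single-point sections can be widened deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from songtool.audio_core import (
    NoteSegment,
    Waveform,
    compute_spectrogram,
    extract_amplitude_envelope,
    segment_notes,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthesisConfig:
    """Analysis/synthesis parameters.

    ``f_min``/``f_max`` bound the fundamental search band (Hz);
    ``voicing_threshold_db`` marks frames quieter than the note's peak
    frame by more than this as unvoiced; ``peak_tolerance_db`` is how
    far below the frame maximum a lower spectral peak may lie and still
    be taken as the fundamental; ``jump_threshold_hz`` splits contour
    sections at instantaneous frequency jumps. Window and hop are STFT
    samples (defaults 512/128 at 44.1 kHz: ~11.6 ms / 2.9 ms frames,
    ~86 Hz bins — enough to resolve ~100 ms Java sparrow notes).
    """

    f_min: float = 500.0
    f_max: float = 12000.0
    voicing_threshold_db: float = 25.0
    peak_tolerance_db: float = 12.0
    jump_threshold_hz: float = 400.0
    window_length: int = 512
    hop_length: int = 128

    def __post_init__(self) -> None:
        if not 0 < self.f_min < self.f_max:
            raise ValueError("require 0 < f_min < f_max")
        if min(self.voicing_threshold_db, self.peak_tolerance_db,
               self.jump_threshold_hz) <= 0:
            raise ValueError("thresholds must be positive")
        if self.hop_length > self.window_length:
            raise ValueError("hop_length must not exceed window_length")

    def hop_s(self, sample_rate: int) -> float:
        return self.hop_length / sample_rate


@dataclass(frozen=True)
class FrequencyContour:
    """Scanned contour: sections of (time_s, freq_hz) points.

    ``sections`` is a list of float arrays of shape (n_points, 2) with
    strictly increasing times inside each section; sections are sorted
    and non-overlapping in time. ``hop_s`` is the STFT hop in seconds.
    """

    sections: list[np.ndarray] = field(default_factory=list)
    hop_s: float = 128 / 44100

    def __post_init__(self) -> None:
        for sec in self.sections:
            if sec.ndim != 2 or sec.shape[1] != 2 or len(sec) == 0:
                raise ValueError("each section must be a non-empty (n, 2) array")
            if len(sec) > 1 and not np.all(np.diff(sec[:, 0]) > 0):
                raise ValueError("times must be strictly increasing in a section")

    @property
    def n_points(self) -> int:
        return sum(len(s) for s in self.sections)

    def points(self) -> np.ndarray:
        """All points of all sections as one (n, 2) array."""
        if not self.sections:
            return np.empty((0, 2))
        return np.concatenate(self.sections, axis=0)


@dataclass(frozen=True)
class SimplifiedContour:
    """One ((t_start, f_start), (t_end, f_end)) pair per section."""

    sections: list[tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=list)

    def __post_init__(self) -> None:
        for (t0, _), (t1, _) in self.sections:
            if not t0 < t1:
                raise ValueError("require t_start < t_end per section")


def _parabolic_refine(db: np.ndarray, i: int) -> float:
    """Sub-bin peak offset from a parabola through dB bins i-1, i, i+1."""
    if i <= 0 or i >= len(db) - 1:
        return 0.0
    a, b, c = db[i - 1], db[i], db[i + 1]
    denom = a - 2 * b + c
    if denom >= 0:  # not a local maximum of the parabola
        return 0.0
    return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local maxima of a 1-D array."""
    n = len(x)
    if n == 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.array([0])
    left = np.empty(n, dtype=bool)
    right = np.empty(n, dtype=bool)
    left[0] = True
    left[1:] = x[1:] >= x[:-1]
    right[-1] = True
    right[:-1] = x[:-1] > x[1:]
    return np.flatnonzero(left & right)


def scan_frequency_contour(w: Waveform, seg: NoteSegment,
                           cfg: SynthesisConfig) -> FrequencyContour:
    """Track the fundamental frequency of one note segment.

    Produces one (time, frequency) point per voiced frame. The
    fundamental is acquired on the note's loudest frame as the
    *lowest* spectral peak within ``peak_tolerance_db`` of that
    frame's maximum inside [f_min, f_max] — so the fundamental wins
    over a louder harmonic and weak subharmonics are ignored — and is
    then tracked outward in both directions with a continuity
    preference: in each frame the peak nearest the previous frame's
    frequency (within ``jump_threshold_hz`` and no more than
    ``voicing_threshold_db`` below the frame maximum) is kept, even if
    a partial at another octave momentarily looks stronger. Where
    continuity is lost the tracker re-acquires with the
    lowest-qualifying-peak rule; without the continuity preference a
    subharmonic hovering at the tolerance edge makes the raw rule
    flicker between octaves frame by frame. Frequencies are refined by
    parabolic interpolation over the three bins around the peak.
    Frames whose RMS is more than ``voicing_threshold_db`` below the
    note's loudest frame contribute no point; a fully unvoiced
    segment yields an empty contour.
    """
    fs = w.sample_rate
    chunk = w.samples[seg.start_sample:seg.end_sample]
    if len(chunk) < cfg.window_length:
        chunk = np.pad(chunk, (0, cfg.window_length - len(chunk)))
    spec = compute_spectrogram(Waveform(chunk, fs),
                               cfg.window_length, cfg.hop_length)
    band = (spec.freq_bins >= cfg.f_min) & (spec.freq_bins <= cfg.f_max)
    band_idx = np.flatnonzero(band)
    if band_idx.size == 0:
        raise ValueError("search band [f_min, f_max] contains no frequency bin")

    frame_rms = np.sqrt(np.mean(
        np.square(_frames_of(chunk, cfg.window_length, cfg.hop_length)), axis=1))
    peak_rms = frame_rms.max()
    if peak_rms <= 0:
        return FrequencyContour(sections=[], hop_s=cfg.hop_s(fs))
    voiced = frame_rms > peak_rms * 10 ** (-cfg.voicing_threshold_db / 20)
    voiced_idx = np.flatnonzero(voiced)
    if voiced_idx.size == 0:
        return FrequencyContour(sections=[], hop_s=cfg.hop_s(fs))

    bin_hz = spec.freq_bins[1] - spec.freq_bins[0]
    tol = 10 ** (-cfg.peak_tolerance_db / 20)
    floor = 10 ** (-cfg.voicing_threshold_db / 20)

    def pick(k: int, prev_freq: float | None) -> float | None:
        mag_band = spec.magnitudes[k, band_idx]
        frame_max = mag_band.max()
        if frame_max <= 0:
            return None
        peaks = _local_maxima(mag_band)
        j = None
        if prev_freq is not None and peaks.size:
            freqs = spec.freq_bins[band_idx[peaks]]
            near = (np.abs(freqs - prev_freq) <= cfg.jump_threshold_hz) \
                & (mag_band[peaks] >= frame_max * floor)
            if near.any():
                cand = peaks[near]
                j = band_idx[cand[np.argmin(
                    np.abs(spec.freq_bins[band_idx[cand]] - prev_freq))]]
        if j is None:
            qualifying = peaks[mag_band[peaks] >= frame_max * tol]
            if qualifying.size == 0:
                return None
            j = band_idx[qualifying[0]]  # lowest-frequency qualifying peak
        with np.errstate(divide="ignore"):
            db = 20 * np.log10(np.maximum(spec.magnitudes[k], 1e-300))
        freq = spec.freq_bins[j] + _parabolic_refine(db, j) * bin_hz
        return float(np.clip(freq, cfg.f_min, cfg.f_max))

    anchor_pos = int(np.argmax(frame_rms[voiced_idx]))
    freqs_at: dict[int, float] = {}
    anchor_freq = pick(int(voiced_idx[anchor_pos]), None)
    if anchor_freq is not None:
        freqs_at[int(voiced_idx[anchor_pos])] = anchor_freq
    prev = anchor_freq
    for pos in range(anchor_pos + 1, len(voiced_idx)):
        f = pick(int(voiced_idx[pos]), prev)
        if f is not None:
            freqs_at[int(voiced_idx[pos])] = f
            prev = f
    prev = anchor_freq
    for pos in range(anchor_pos - 1, -1, -1):
        f = pick(int(voiced_idx[pos]), prev)
        if f is not None:
            freqs_at[int(voiced_idx[pos])] = f
            prev = f

    if not freqs_at:
        return FrequencyContour(sections=[], hop_s=cfg.hop_s(fs))
    points = [(spec.frame_times[k], freqs_at[k]) for k in sorted(freqs_at)]
    return FrequencyContour(sections=[np.array(points)], hop_s=cfg.hop_s(fs))


def _frames_of(x: np.ndarray, window: int, hop: int) -> np.ndarray:
    n_frames = 1 + (len(x) - window) // hop
    idx = np.arange(window)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def sectionize(contour: FrequencyContour,
               cfg: SynthesisConfig) -> FrequencyContour:
    """Split contour points into maximal smooth, contiguous sections.

    A new section starts whenever consecutive points are separated by
    more than one hop in time (a voicing gap) or by more than
    ``jump_threshold_hz`` in frequency (an instantaneous jump).
    """
    pts = contour.points()
    if len(pts) == 0:
        return FrequencyContour(sections=[], hop_s=contour.hop_s)
    dt = np.diff(pts[:, 0])
    df = np.abs(np.diff(pts[:, 1]))
    # allow a small numerical slack on the one-hop adjacency rule
    breaks = np.flatnonzero((dt > 1.5 * contour.hop_s)
                            | (df > cfg.jump_threshold_hz)) + 1
    sections = [np.asarray(s) for s in np.split(pts, breaks)]
    return FrequencyContour(sections=sections, hop_s=contour.hop_s)


def simplify_to_endpoints(contour: FrequencyContour) -> SimplifiedContour:
    """Keep only the first and last point of every section.

    This is the linear-FM simplification: interior points — all the
    detailed frequency up-and-downs — are discarded. A single-point
    section becomes a constant-frequency pair one hop long.
    """
    pairs = []
    for sec in contour.sections:
        t0, f0 = sec[0]
        t1, f1 = sec[-1]
        if len(sec) == 1:
            t1, f1 = t0 + contour.hop_s, f0
        pairs.append(((float(t0), float(f0)), (float(t1), float(f1))))
    return SimplifiedContour(sections=pairs)


def resynthesize_note(w: Waveform, seg: NoteSegment, sc: SimplifiedContour,
                      envelope: np.ndarray,
                      hop_length: int = 128,
                      window_length: int = 512) -> Waveform:
    """Synthesize a tonal note from a simplified contour.

    The output is a pure sine whose instantaneous frequency is linearly
    interpolated between each section's endpoints, with phase carried
    continuously across section boundaries (cumulative-phase
    oscillator, so boundaries add no clicks). Samples outside voiced
    sections are silent, except that each section is widened by half an
    analysis window so note onsets are not shaved off by frame
    centring. The amplitude is the note's original RMS envelope
    (``envelope`` rows of (time_s, rms) from
    :func:`~songtool.audio_core.extract_amplitude_envelope`), followed
    by a per-frame RMS correction so synthetic frame RMS matches the
    original within a few percent. Output length equals the segment
    length exactly.

    An empty simplified contour yields a silent note of the correct
    length, with a logged warning.
    """
    fs = w.sample_rate
    n = len(seg)
    if not sc.sections:
        logger.warning("empty simplified contour: emitting %d silent samples", n)
        return Waveform(np.zeros(n), fs)

    # breakpoints for linear frequency interpolation
    bp_t = np.array([t for pair in sc.sections for t, _ in pair])
    bp_f = np.array([f for pair in sc.sections for _, f in pair])
    t = np.arange(n) / fs
    freq = np.interp(t, bp_t, bp_f)
    phase = 2 * np.pi * np.cumsum(freq) / fs
    tone = np.sin(phase)

    half_win = window_length / 2 / fs
    voiced = np.zeros(n, dtype=bool)
    for (t0, _), (t1, _) in sc.sections:
        i0 = max(0, int(round((t0 - half_win) * fs)))
        i1 = min(n, int(round((t1 + half_win) * fs)) + 1)
        voiced[i0:i1] = True

    amp = np.interp(t, envelope[:, 0], envelope[:, 1])
    out = np.sqrt(2.0) * amp * tone
    out[~voiced] = 0.0

    # per-frame RMS correction toward the original note; two passes so
    # frames on steep envelope edges also land within the 5% contract
    orig = w.samples[seg.start_sample:seg.end_sample]
    if n >= hop_length:
        frames_orig = _frames_of(orig, hop_length, hop_length)
        rms_orig = np.sqrt(np.mean(frames_orig ** 2, axis=1))
        centres = (np.arange(len(rms_orig)) * hop_length + hop_length / 2) / fs
        for _ in range(2):
            frames_out = _frames_of(out, hop_length, hop_length)
            rms_out = np.sqrt(np.mean(frames_out ** 2, axis=1))
            gain = np.ones(len(rms_out))
            ok = rms_out > 1e-12
            gain[ok] = rms_orig[ok] / rms_out[ok]
            np.clip(gain, 0.0, 4.0, out=gain)
            out *= np.interp(t, centres, gain)
    return Waveform(out, fs)


def synthesize_song(w: Waveform, cfg: SynthesisConfig | None = None) -> Waveform:
    """Simplify every note of a song: the full synthesis pipeline.

    Notes are segmented, each note's contour is scanned, sectionized,
    reduced to endpoints and resynthesized, and the tonal notes are
    written back at their original sample positions with the original
    silences. Output length equals input length; silent input yields
    silent output. If the resynthesized song would clip, the whole
    output is rescaled to peak 0.999 with a logged warning.
    """
    cfg = cfg or SynthesisConfig()
    out = np.zeros(len(w))
    for seg in segment_notes(w, window_length=cfg.window_length,
                             hop_length=cfg.hop_length):
        contour = scan_frequency_contour(w, seg, cfg)
        contour = sectionize(contour, cfg)
        simplified = simplify_to_endpoints(contour)
        env = extract_amplitude_envelope(w, seg, cfg.hop_length)
        note = resynthesize_note(w, seg, simplified, env,
                                 cfg.hop_length, cfg.window_length)
        out[seg.start_sample:seg.end_sample] = note.samples
    peak = np.max(np.abs(out)) if len(out) else 0.0
    if peak > 1.0:
        logger.warning("resynthesized song clips (peak %.3f); rescaling", peak)
        out *= 0.999 / peak
    return Waveform(out, w.sample_rate)


def tonality_report(w: Waveform, cfg: SynthesisConfig | None = None) -> np.ndarray:
    """Per-voiced-frame separation (dB) between the two largest spectral peaks.

    For every voiced frame of every detected note, returns the level
    difference between the largest spectral peak and the largest
    magnitude more than five bins away from it. Large values mean the
    frame is tonal (a single partial); harmonics or subharmonics pull
    the separation down to their dB offset.
    """
    cfg = cfg or SynthesisConfig()
    seps = []
    for seg in segment_notes(w, window_length=cfg.window_length,
                             hop_length=cfg.hop_length):
        chunk = w.samples[seg.start_sample:seg.end_sample]
        if len(chunk) < cfg.window_length:
            continue
        spec = compute_spectrogram(Waveform(chunk, w.sample_rate),
                                   cfg.window_length, cfg.hop_length)
        frame_rms = np.sqrt(np.mean(
            np.square(_frames_of(chunk, cfg.window_length, cfg.hop_length)), axis=1))
        voiced = frame_rms > frame_rms.max() * 10 ** (-cfg.voicing_threshold_db / 20)
        for k in np.flatnonzero(voiced):
            mag = spec.magnitudes[k]
            top = int(np.argmax(mag))
            masked = mag.copy()
            masked[max(0, top - 5):top + 6] = 0.0
            second = masked.max()
            if second <= 0:
                seps.append(np.inf)
            else:
                seps.append(20 * np.log10(mag[top] / second))
    return np.asarray(seps)
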