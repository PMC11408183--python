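"""Audio I/O, spectrograms, note segmentation and amplitude envelopes.

All downstream song processing is built on the small set of primitives
here: 16-bit PCM WAV reading/writing, a Hann-window magnitude STFT,
energy-threshold note segmentation and frame-RMS amplitude envelopes.

Conventions
-----------
* Samples are dimensionless floats in [-1, 1]; mono only.
* Sample indices are 0-based, half-open ``[start, end)``.
* STFT frames start at sample ``k * hop_length`` and cover
  ``window_length`` samples; the frame time is the frame centre.
* Segmentation thresholds are relative to the peak frame energy of the
  recording, so results are invariant to global amplitude scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window

logger = logging.getLogger(__name__)

_INT16_FULL_SCALE = 32768.0


class WavFormatError(ValueError):
    """Raised when a file is not a readable PCM WAV."""


@dataclass(frozen=True)
class Waveform:
    """Mono audio: ``samples`` in [-1, 1] at ``sample_rate`` Hz."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("Waveform must be mono (1-D samples)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Waveform samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class Spectrogram:
    """Magnitude STFT: ``magnitudes[frame, bin]`` with frame/bin axes."""

    magnitudes: np.ndarray        # time x frequency, non-negative
    frame_times: np.ndarray       # s, strictly increasing (frame centres)
    freq_bins: np.ndarray         # Hz, strictly increasing from 0
    window_length: int
    hop_length: int

    def __post_init__(self) -> None:
        if self.magnitudes.shape != (len(self.frame_times), len(self.freq_bins)):
            raise ValueError("magnitudes shape must be (n_frames, n_bins)")
        if self.hop_length > self.window_length:
            raise ValueError("hop_length must not exceed window_length")


@dataclass(frozen=True)
class NoteSegment:
    """Half-open sample range ``[start_sample, end_sample)`` of one note."""

    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_sample < self.end_sample:
            raise ValueError("require 0 <= start_sample < end_sample")

    def __len__(self) -> int:
        return self.end_sample - self.start_sample


def read_wav(path) -> Waveform:
    """Read a PCM WAV file into a :class:`Waveform`.

    Integer samples are normalized to [-1, 1] by the format's full
    scale (e.g. 32768 for 16-bit). Stereo input is down-mixed by the
    channel mean, with a logged warning.

    Raises
    ------
    WavFormatError
        If the file is empty, unreadable, or not PCM WAV.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad files
        raise WavFormatError(f"not a readable PCM WAV file: {path!r} ({exc})") from exc
    if data.size == 0:
        raise WavFormatError(f"WAV file contains no samples: {path!r}")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        full_scale = float(max(abs(info.min), info.max + 1))
        samples = data.astype(np.float64) / full_scale
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        logger.warning("down-mixing %d-channel WAV %r to mono by channel mean",
                       samples.shape[1], path)
        samples = samples.mean(axis=1)
    return Waveform(samples=samples, sample_rate=int(rate))


def write_wav(w: Waveform, path) -> None:
    """Write a :class:`Waveform` as 16-bit PCM mono WAV.

    Raises
    ------
    ValueError
        If any sample lies outside [-1, 1]; nothing is clipped silently.
    """
    peak = np.max(np.abs(w.samples)) if len(w) else 0.0
    if peak > 1.0:
        raise ValueError(
            f"samples exceed [-1, 1] (peak {peak:.4f}); rescale before writing")
    quantized = np.round(w.samples * (_INT16_FULL_SCALE - 1)).astype(np.int16)
    wavfile.write(path, w.sample_rate, quantized)


def frame_signal(samples: np.ndarray, window_length: int, hop_length: int) -> np.ndarray:
    """Slice ``samples`` into overlapping frames (n_frames, window_length).

    Frames start at multiples of ``hop_length`` and must lie fully
    inside the signal; no padding is applied.
    """
    n = len(samples)
    if window_length > n:
        raise ValueError(f"signal ({n}) shorter than window ({window_length})")
    n_frames = 1 + (n - window_length) // hop_length
    idx = np.arange(window_length)[None, :] + hop_length * np.arange(n_frames)[:, None]
    return samples[idx]


def compute_spectrogram(w: Waveform, window_length: int = 512,
                        hop_length: int = 128) -> Spectrogram:
    """Hann-window magnitude STFT of ``w``.

    Frequency bins span 0..sample_rate/2 with spacing
    ``sample_rate / window_length``; frame times are frame centres.

    Raises
    ------
    ValueError
        If the signal is shorter than one window.
    """
    if hop_length > window_length:
        raise ValueError("hop_length must not exceed window_length")
    frames = frame_signal(w.samples, window_length, hop_length)
    window = get_window("hann", window_length, fftbins=True)
    mags = np.abs(np.fft.rfft(frames * window, axis=1))
    n_frames = frames.shape[0]
    frame_times = (np.arange(n_frames) * hop_length + window_length / 2) / w.sample_rate
    freq_bins = np.fft.rfftfreq(window_length, d=1.0 / w.sample_rate)
    return Spectrogram(magnitudes=mags, frame_times=frame_times,
                       freq_bins=freq_bins, window_length=window_length,
                       hop_length=hop_length)


def _frame_rms(samples: np.ndarray, window_length: int, hop_length: int) -> np.ndarray:
    frames = frame_signal(samples, window_length, hop_length)
    return np.sqrt(np.mean(frames ** 2, axis=1))


def segment_notes(w: Waveform, threshold_db: float = 30.0,
                  min_note_ms: float = 10.0, min_gap_ms: float = 10.0,
                  window_length: int = 512, hop_length: int = 128) -> list[NoteSegment]:
    """Segment a recording into notes by relative frame energy.

    Frames whose RMS energy is within ``threshold_db`` of the peak frame
    are voiced; maximal voiced runs become note candidates. Gaps shorter
    than ``min_gap_ms`` are merged into the surrounding note, then
    candidates shorter than ``min_note_ms`` are dropped. The threshold is
    relative, so segmentation is invariant to global amplitude scaling.

    Silent input yields an empty list (no error).
    """
    if len(w) < window_length:
        return []
    rms = _frame_rms(w.samples, window_length, hop_length)
    peak = rms.max()
    if peak <= 0.0:
        return []
    voiced = rms > peak * 10.0 ** (-threshold_db / 20.0)
    runs = _boolean_runs(voiced)
    if not runs:
        return []

    min_gap_frames = max(1, int(round(min_gap_ms / 1000.0 * w.sample_rate / hop_length)))
    merged = [runs[0]]
    for start, end in runs[1:]:
        if start - merged[-1][1] < min_gap_frames:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))

    min_note_frames = max(1, int(round(min_note_ms / 1000.0 * w.sample_rate / hop_length)))
    segments = []
    for start, end in merged:
        if end - start < min_note_frames:
            continue
        # Frame k covers samples [k*hop, k*hop + window). The first voiced
        # frame usually catches only the tail of its window, so the onset
        # sits near the *end* of the preceding unvoiced frame's window;
        # symmetrically the offset sits near the start of the first
        # unvoiced frame after the run. This centring keeps detected
        # boundaries within about one hop of the true ones.
        n_frames = len(rms)
        e = len(w) if end >= n_frames else end * hop_length
        s = 0 if start == 0 else start * hop_length + window_length - hop_length
        s = min(s, e - hop_length)
        segments.append(NoteSegment(max(s, 0), e))
    return segments


def _boolean_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of ``mask`` as half-open (start, end) frame pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def extract_amplitude_envelope(w: Waveform, segment: NoteSegment,
                               hop_length: int = 128) -> np.ndarray:
    """Frame-RMS amplitude envelope of one note segment.

    Returns an array of ``(time_s, rms)`` rows sampled every
    ``hop_length`` samples; times are frame centres measured from the
    *segment start*. Each RMS frame spans four hops so that it covers
    several fundamental periods (sub-percent ripple on a constant
    tone) while still tracking amplitude modulation at the hop rate.
    Linear interpolation between rows defines the envelope at
    intermediate times. A segment shorter than one frame yields a
    single-point envelope over its full extent.
    """
    window = 4 * hop_length
    chunk = w.samples[segment.start_sample:segment.end_sample]
    if len(chunk) < window:
        rms = float(np.sqrt(np.mean(chunk ** 2)))
        return np.array([[len(chunk) / 2 / w.sample_rate, rms]])
    rms = _frame_rms(chunk, window, hop_length)
    times = (np.arange(len(rms)) * hop_length + window / 2) / w.sample_rate
    return np.column_stack([times, rms])
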