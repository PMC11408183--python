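import numpy as np
import pytest

from songtool.audio_core import Waveform
from songtool.contour_synthesis import SynthesisConfig
from songtool.synthetic_song import NoteSpec, SongSpec, render

FS = 44100


@pytest.fixture(scope="session")
def cfg() -> SynthesisConfig:
    return SynthesisConfig()


@pytest.fixture()
def pure_tone() -> Waveform:
    """0.2 s, 2000 Hz, amplitude 0.5."""
    t = np.arange(int(0.2 * FS)) / FS
    return Waveform(0.5 * np.sin(2 * np.pi * 2000 * t), FS)


@pytest.fixture(scope="session")
def three_tone_song() -> tuple[Waveform, SongSpec]:
    """Three 100 ms flat notes separated by 50 ms silences."""
    notes = tuple(
        NoteSpec(onset=0.05 + 0.15 * i, duration=0.1, f0_start=2000 + 500 * i,
                 f0_end=2000 + 500 * i, am_shape="flat")
        for i in range(3))
    spec = SongSpec(notes=notes)
    w, _ = render(spec)
    return w, spec


@pytest.fixture(scope="session")
def harmonic_song() -> tuple[Waveform, object]:
    """Five gliding notes with a -6 dB harmonic and FM wiggle."""
    notes = tuple(
        NoteSpec(onset=0.1 + 0.18 * i, duration=0.12,
                 f0_start=2000 + 300 * i, f0_end=2600 + 300 * i,
                 fm_wiggle_hz=150, fm_wiggle_rate=40,
                 harmonic_levels=(-6.0,), am_shape="bell")
        for i in range(5))
    spec = SongSpec(notes=notes)
    w, truth = render(spec)
    return w, truth
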