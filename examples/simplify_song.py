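"""Simplify a Java-sparrow-like song to tonal, linear-FM notes.

Renders a random synthetic song, runs the full simplification pipeline
(segment -> scan contour -> keep section endpoints -> resynthesize) and
reports how faithful the result is: note timing and amplitude envelope
should survive, harmonics and frequency wiggles should not.
"""

import numpy as np

from songtool import (
    NoteSegment,
    extract_amplitude_envelope,
    render,
    sample_song_spec,
    segment_notes,
    synthesize_song,
    write_wav,
)
from songtool.contour_synthesis import tonality_report

song, _truth = render(sample_song_spec(seed=11, n_notes=12))
simplified = synthesize_song(song)
write_wav(simplified, "simplified_song.wav")

notes_in = segment_notes(song)
notes_out = segment_notes(simplified)
max_shift = max(abs(a.start_sample - b.start_sample)
                for a, b in zip(notes_in, notes_out))

env_in = extract_amplitude_envelope(song, NoteSegment(0, len(song)))
env_out = extract_amplitude_envelope(simplified, NoteSegment(0, len(simplified)))
env_r = np.corrcoef(env_in[:, 1], env_out[:, 1])[0, 1]

sep = tonality_report(simplified)

print(f"notes: {len(notes_in)} in, {len(notes_out)} out")
print(f"largest onset shift: {max_shift} samples "
      f"({max_shift / song.sample_rate * 1000:.2f} ms)")
print(f"amplitude-envelope correlation: {env_r:.4f}")
print(f"tonality: weakest frame has {sep.min():.1f} dB between its "
      f"two largest spectral peaks")
print()
print("Rhythm and loudness contour are preserved (shift ~ a few ms, "
      "correlation ~ 1); every voiced frame is dominated by a single "
      "partial, i.e. harmonics and subharmonics are gone. The simplified "
      "song is in simplified_song.wav.")
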