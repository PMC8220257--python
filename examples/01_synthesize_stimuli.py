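"""Synthesize one session's stochastic figure-ground stimulus set.

Draws the 20-stimulus set (12 figure stimuli, 8 controls), renders one
figure stimulus to audio and writes WAV + JSON metadata next to this script's
output directory.
"""

from pathlib import Path

import numpy as np

from figground import io, stimulus as st

out = Path("scratch/example_stimuli")
stims = st.make_session_stimulus_set(seed=1)

n_fig = sum(s.is_figure for s in stims)
print(f"session set: {len(stims)} stimuli, {n_fig} with figure "
      f"({100 * n_fig / len(stims):.0f}%)")

stim = stims[6]  # a Coh12 stimulus
wave = st.render_waveform(stim)
print(f"example {stim.stimulus_id}: coherence {stim.coherence}, "
      f"figure onset {stim.figure_onset_ms:.0f} ms (chord {stim.figure_onset_chord}), "
      f"waveform {len(wave)} samples at {stim.sample_rate_hz} Hz")
print(f"figure frequencies (Hz): "
      f"{np.round(stim.pool.frequencies_hz[stim.figure_set]).astype(int).tolist()}")

io.write_stimulus(out, stim)
print(f"wrote {out}/{stim.stimulus_id}.wav and .json")
# The figure is defined purely by the 12 frequencies repeating across 20
# chords; every chord still holds exactly 15 elements, so there is no level
# cue at figure onset.
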