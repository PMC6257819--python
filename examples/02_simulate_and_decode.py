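"""Simulate oscillatory EEG with a known element code and decode it back.

One synthetic subject performs six blocks of the 9-element task.  An
alpha-band (8-12 Hz) spatial pattern encoding the current element is injected
during the late preparation period; the frequency-by-time decoder must
recover it there — and nowhere else.
"""

import numpy as np

from seqdecode import (CodePatternSpec, DecodeConfig, ExperimentDesign, NoiseSpec,
                       assign_probes, build_schedule, build_wavelet_bank,
                       decode_map, simulate_dataset, summarize_period, tf_power)
from seqdecode.synth_eeg import ALPHA

design = ExperimentDesign.from_variant("exp1", n_blocks=6)
schedule = assign_probes(build_schedule(design, seed=11), seed=12)

patterns = [CodePatternSpec(code="element", band=ALPHA, window=(-600, 0),
                            amplitude=8.0)]
eeg = simulate_dataset(schedule, patterns, NoiseSpec(noise_sd=10.0), seed=21,
                       analysis_window=(-700, 400))
print(f"simulated {eeg.n_trials} trials x {len(eeg.montage)} electrodes")

bank = build_wavelet_bank(n_freqs=8)  # reduced grid for a quick demo
tf = tf_power(eeg, bank)
res = decode_map(tf, schedule["element"].to_numpy(),
                 DecodeConfig(n_iterations=2, window_step=25, seed=5))

inside = summarize_period(res.accuracy, res.freqs, res.times, (8, 12), (-500, -100))
outside = summarize_period(res.accuracy, res.freqs, res.times, (25, 35), (-500, -100))
print(f"decoding accuracy inside the injected alpha/preparation region: {inside:.3f}")
print(f"decoding accuracy at 25-35 Hz (nothing injected):              {outside:.3f}")
print(f"chance level for 3 classes:                                    {res.chance:.3f}")
print("The decoder recovers the code only where the generator put it; the"
      " confusion tensor columns sum to", float(res.confusion.sum(axis=2).mean()))
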