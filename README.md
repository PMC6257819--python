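# seqdecode

Frequency-by-time EEG decoding of hierarchical serial-order control codes,
packaged with a synthetic-data bench that validates every analysis stage by
parameter recovery.

## The problem

When people produce a memorized sequence (dance steps, digit strings,
keyboard shortcuts), behavior is thought to be organized by *abstract control
codes* that are independent of the sequence content: the identity of the
current element, its ordinal position inside a short chunk, the identity of
the chunk, and the chunk's position in the overall plan. In a cycling-sequence
task — memorize a 9-element sequence of line orientations organized as three
3-element chunks, then step through it trial by trial answering match/mismatch
probes — these four codes can be fully counterbalanced, so each becomes
independently decodable from the spatial pattern of rhythmic EEG activity:
content codes (elements, chunk identity) ride on alpha-band (8–12 Hz)
activity, order codes (within-chunk and chunk position) on theta (4–7 Hz).

`seqdecode` implements the complete analysis chain for this paradigm:

1. **task_model** — task designs, sequence enumeration (6 sequences for the
   three-chunk design, 12 for the six-chunk design with the cyclic
   no-element-repeat rule), counterbalanced trial schedules, Cowan's
   K = S·(H − F) working-memory capacity and median splits.
2. **synth_eeg** — 20-channel, 250 Hz synthetic EEG: 1/f^β background noise
   plus band-limited oscillations whose unit-norm topographies encode each
   code instance in a configurable band, window, and SNR; simulated behavior
   (log-normal RTs with chunk-boundary costs) and injectable blink/flat
   artifacts with ground-truth masks.
3. **spectral** — complex Morlet wavelet power (32 log-spaced frequencies,
   4→35 Hz, σ = n/2πf with n rising 3→10), sliding-window artifact rejection
   (>80 µV blinks, flat-line "blocking"), mid-frontal band-power contrasts.
4. **decode** — the frequency-by-time decoder: 4-fold cross-validation with
   per-class count equating, 100-ms (25-sample) sliding-window trial
   averaging, z-scoring across electrodes, shrinkage-regularized linear
   discriminants at every (frequency, time) cell, repeated over fresh
   partitions; outputs accuracy maps, column-stochastic confusion tensors,
   and per-trial logit posterior evidence. Chance is 1/3 for all paper codes.
5. **cluster_stats** — group-level cluster-mass permutation test (entry
   threshold t > 2.0, 4-connected clusters, sign-flip null of the maximum
   cluster mass, one-sided).
6. **represent** — cross-classification generalization with size-matched
   reference scores, RSA regression of logit confusion frequencies on model
   matrices (discrete vs unique-position-1, element/position/conjunction
   families), and the chaining-asymmetry test
   cor(A_late, B_early) − cor(A_early, B_late).
7. **behavior** — trial exclusions (errors, post-error, RT < 100 ms,
   retrieval > 8 s), chunk-structure contrasts with within-subject CIs,
   RT residualization, and the multilevel evidence→RT model.
8. **pipeline** — seeded end-to-end runs with an HDF5/CSV/JSON results
   bundle and figure-style reports.

Because the generator injects *known* codes at known bands, windows, and
amplitudes, every stage is testable by recovery: decoders must find exactly
what was injected, cluster tests must keep their family-wise error, RSA must
identify the generating model, and behavioral estimators must return the
generator's parameters.

## Worked example

`examples/02_simulate_and_decode.py` simulates one subject (324 trials,
20 electrodes) with an alpha-band element code confined to the late
preparation period, then decodes it:

```
simulated 324 trials x 20 electrodes
decoding accuracy inside the injected alpha/preparation region: 0.975
decoding accuracy at 25-35 Hz (nothing injected):              0.358
chance level for 3 classes:                                    0.333
```

The decoder recovers the element code almost perfectly inside the injected
band and window and stays at chance elsewhere — the generator introduces no
accidental label information. The remaining examples walk through cluster
inference, RSA/generalization, behavior, and the full pipeline the same way.

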