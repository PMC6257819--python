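# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Task model

Sequences are ordered chunks of three distinct elements (A/B/C, standing for
45°/90°/135° line orientations). The three-chunk design uses the pool
{ABC, BCA, CAB}; all 3! orderings are legal, giving 6 sequences. The
six-chunk design uses all six permutations of ABC, takes ordered pairs of
distinct chunks, and forbids an element from repeating at a chunk junction.
Because sequences cycle within a block, the junction rule is applied
cyclically — at the internal junction *and* at the wrap-around junction from
the last chunk back to the first. This is the only reading under which the
enumeration yields 12 sequences (without the wrap-around junction it yields
18); the package enumerates and a test cross-checks by brute force over all
30 ordered pairs. Canonical ordering is lexicographic on chunk labels so
enumerations are stable.

Schedules assign every legal sequence to the same number of blocks in a
seeded random order. With the three-chunk design this makes the four control
codes pairwise exactly counterbalanced (verified by exact count tests), which
is what licenses decoding each code independently of the others.

Probe matches are Bernoulli(0.5) by default (the match proportion is a free
design parameter); mismatch probes are uniform over the two non-target
orientations. Working-memory capacity is K = S·(H − F); median splits assign
subjects exactly at the median to the low group (configurable).

## Synthetic EEG generator

Each trial epoch is the sum of:

* **Background noise** — white noise spectrally shaped to 1/f^β (β = 1 by
  default, SD 10 µV per channel), optionally with a common-mode component
  giving channel correlation ρ. DC is removed.
* **Code patterns** — for each control code, a sinusoidal carrier at the
  band center with ±1 Hz per-trial frequency jitter and random phase,
  multiplied by a smooth 50-ms cosine-ramped envelope confined to the code's
  time window, and by the unit-norm topography of that trial's code
  instance. Topographies are drawn standard normal, unit-normalized, and
  redrawn until all pairs subtend ≥ 30°, so separability is controlled by
  amplitude rather than chance geometry.

Default epoch span is −1250…+700 ms around probe onset plus 400 ms padding on
each side, enough for ≥ 3σ of the widest (4 Hz, 3-cycle) wavelet. The
defaults for band/window assignments mirror the paradigm's finding structure:
elements and chunk identity in alpha, positions in theta; chunk identity as a
preparation-period signal and chunk position around the probe.

Amplitude-to-SNR: the carrier RMS over noise SD ratio is logged. Because the
background is 1/f, a fixed amplitude is a *lower* effective SNR in theta than
in alpha; recovery tests therefore use larger theta amplitudes when "high
SNR" in both bands is required.

A `chaining_drift` parameter morphs element topographies toward the next
within-chunk element's topography during the second half of blocks, which is
the anticipatory-drift signature that associative-chaining accounts predict
and the chaining-asymmetry test must detect.

**Simulated behavior.** RTs are log-normal around rt_base + boundary_cost at
within-chunk position 1, with mean-one multiplicative noise so the expected
position-1 vs 2&3 contrast equals boundary_cost exactly (defaults 480 + 14
ms, SD 0.15 on the log scale). Errors are Bernoulli with a boundary error
cost (defaults 6% + 3.8 points). Low-WM subjects scale both boundary effects.
Evidence coupling acts additively on log RT so the multilevel model's slope
estimates the generative coefficient directly.

**What the generator does not emulate:** volume-conducted dipolar
topographies and realistic channel covariance, non-stationary noise, ERP
transients, muscle/line artifacts, latency jitter of the codes, and any
coupling between neural patterns and accuracy. Passing recovery tests shows
the *estimators* are correct and calibrated, not that real EEG carries these
codes — that is the empirical claim of the paradigm, out of scope here.

## Time-frequency decomposition

Complex Morlet wavelets w(t) = exp(2πi·f·t)·exp(−t²/2σ²) with σ = n/(2πf);
32 frequencies log-spaced 4→35 Hz; cycle counts n interpolated linearly over
the bank index from 3 to 10 (the interpolation rule is a package choice; on a
log-spaced bank this is equivalent to linear in log-frequency). Convolution
runs per frequency in the spectral domain; power is |z|². Wavelets are
normalized to unit gain at the carrier frequency (a unit-amplitude sinusoid
gives power 1.0; verified against the closed form and cross-checked against
an independent implementation). Samples within 3σ of the epoch edge or
outside the analysis window are flagged invalid and excluded downstream.
Average reference is applied before decomposition by default; synthetic
pipelines can disable it.

Artifact screening follows fixed thresholds: blinks are sliding-window
(200 ms, 50 ms step) peak-to-peak > 80 µV on frontal channels; "blocking" is
a total range ≤ 0.1 µV sustained over 200 ms at any alignment (implemented
with rolling min/max so unaligned flat segments are caught); eye movements
use a step detector on the left–right frontal difference signal with a 40 µV
default threshold — a voltage stand-in for a gaze-based criterion, since the
generator has no eye tracker. At these defaults the rejection report
reproduces the artifact generator's ground-truth mask exactly on
well-separated artifacts (blink amplitude ≫ noise, noise SD ≲ 6 µV for the
eye rule's false-alarm-free regime).

## Decoding

For each iteration: trials are randomly partitioned into 4 folds; per-class
counts are equated within and across folds by random dropping; per fold,
class, and electrode, power is smoothed with a centered 25-sample (100 ms)
moving average; each fold's class × electrode matrix is z-scored across
electrodes per (class, frequency, time) cell — removing spatially uniform
effects such as global power shifts; a linear discriminant with automatic
(Ledoit-Wolf) shrinkage of the within-class covariance is trained on three
folds' class rows and tested on the held-out fold's rows. Folds rotate,
partitions are redrawn (30 iterations by default), and accuracy and
column-stochastic confusions are averaged. Shrinkage is required because the
training set is a handful of class-mean rows in 20 dimensions; plain
covariance estimates would be singular.

Per-trial evidence is the logit of the posterior probability of the trial's
correct label, obtained by applying each fold's trained classifier to the
held-out fold's single trials (same smoothing, per-trial z-scoring), averaged
over iterations. Posteriors are clipped to [1e−6, 1−1e−6] before the logit.

Numerical notes: z-scores use the population SD with constant cells mapped to
0; the z-scoring parameters are always computed within the matrix being
transformed (no train→test transfer). The time axis may be decimated via
`window_step` for speed; tests and the acceptance script use 25-sample steps
(one estimate per 100 ms). Chance for three-instance codes is 1/3; a
two-class Gaussian toy matches the closed-form Bayes rate Φ(d/2) within
sampling error once the training set is large enough.

A caution from the validation work: when several analyses share one random
stream (schedule, noise, and fold partitions derived from the same seed),
their sampling errors correlate and small per-subject deviations no longer
average out across subjects. All pipeline stages therefore draw their streams
from decoupled offsets of the master seed.

## Cluster statistics

One-sample t against chance per (f, t) cell; cells with t > 2.0 (the fixed
entry threshold) are grouped by 4-connectivity (adjacent in frequency or
time, no diagonals); cluster mass is the sum of t values. The null is built
by randomly sign-flipping each subject's deviation map and recording the
maximum cluster mass (1000 permutations by default); cluster
p = (1 + #{perm ≥ observed}) / (n_perm + 1), one-sided. Sign-flipping is the
standard one-sample permutation scheme: shuffling condition labels at the
group level for an accuracy-vs-chance test reduces to it. Simulations with
500 null replicates keep the family-wise error within the binomial envelope
of 0.05, and injected rectangular effects are recovered with Jaccard ≥ 0.5.

## Representational analyses

**Generalization.** To test whether a code (e.g. within-chunk position)
transfers across instances of another variable (e.g. elements), training
folds exclude one instance; the trained decoder is scored on (a) the held-out
instance's class rows (generalized) and (b) an equal-sized subsample of
training-instance trials from the held-out fold (reference). The size
matching makes the comparison estimator-fair — filtered training sets lower
both scores equally. These analyses run on band/period-averaged features
(theta/alpha × preparation −600–0 ms / probe 0–300 ms).

**RSA.** Model matrices are column-stochastic theoretical confusion
structures (columns = true class): identity for discrete coding;
unique-position-1 with 0.5 confusability between positions 2 and 3; 9-class
element/position/conjunction models with 1/3 cells; 6-class lag-1 models
over non-repeating element pairs. All confusion cells including the diagonal
are logit-transformed (clip 1e−4) and regressed simultaneously on all model
predictors, fixed effects plus per-subject random intercepts and slopes;
when the mixed fit fails to converge the package falls back to per-subject
least squares with a group t-test, and records which path ran. Predictors
are used raw (0/½/1), matching coefficient reporting on the natural scale;
a standardize option exists for sensitivity checks. Round-robin recovery
(generate from model i → predictor i dominates) holds for every built-in
family.

**Chaining.** For each within-chunk transition A→B, element spatial patterns
(electrode vectors of band/period-averaged power) are computed separately in
the first and second half of blocks; the index is the Fisher-z difference
cor(A_late, B_early) − cor(A_early, B_late), averaged over transitions, with
a group one-sample t. The early/late cut at the median block is a package
choice; transitions missing from a half are excluded with a warning.

## Behavior

Exclusions flag (never delete) error trials, the immediately following trial
within the same block, RT < 100 ms, and self-paced retrieval > 8000 ms.
Repeated-measures contrasts are computed as subject condition means followed
by within-subject contrasts and one-sample t tests; for 1-df contrasts the
equivalent F is t². Within-subject CIs use subject-mean centering with the
C/(C−1) correction. RT residualization regresses log RT per subject on
linear and quadratic trial and block trends, both position contrasts, and
match/mismatch; residuals are exactly orthogonal to the nuisance design.
The evidence→RT model enters alpha-element and theta-position evidence
simultaneously with per-subject random intercepts and slopes (normal
approximation for t values; degrees of freedom are not reported), with the
same two-stage fallback as the RSA fit.

## Problem sizes

The validation suite runs at deliberately reduced scale, chosen as the
smallest sizes at which each property is statistically decisive: 6-block
(324-trial) schedules — the smallest balanced session; an 8-frequency bank;
100-ms decoding steps; 2–3 cross-validation iterations; 4–10 simulated
subjects for decoding properties and 30 for behavioral recovery at the
study's sample size; 200–1000 permutations; 500 replicates for the
family-wise error simulation. Full-scale defaults (32 frequencies, 30
iterations, every-sample maps, 24-block sessions) remain the package
defaults and are exercised by the same code paths.

## Known limitations

* The generator's topographies are random vectors, not physiologically
  plausible scalp fields; electrode identities matter only for the frontal
  screening channels.
* The eye-movement rule is a voltage threshold, not a gaze criterion.
* Mixed-effects fits with random slopes on small simulated samples often
  fall back to the two-stage estimator; on well-conditioned simulations the
  two agree in sign and closely in magnitude, but the fallback's SEs are the
  between-subject ones.
* Accuracy estimates from class-averaged fold rows are far above single-trial
  accuracy by construction; single-trial statements should use the per-trial
  evidence/accuracy outputs.
* Real-data ingestion (EDF/FIF) is an interface only; no empirical claims
  about human EEG are made or tested here.
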