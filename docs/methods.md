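# Methods

`eegattn` decodes which of three auditory attention states a listener is
in — `Rest` (eyes closed, no stimulus), `AOA1` (attending auditory
object 1) or `AOA2` (attending auditory object 2) — from a single
60-second trial of 8-channel EEG, using signal-complexity features and
standard classifiers. This note documents the models, the parameter
choices, and the limits of what the synthetic-data experiments can show.

## Signal model and preprocessing

Trials are 8 channels (T7, T8, P7, P8, Cz, Fz, P3, P4 — this order is
canonical everywhere in the package) sampled at 500 Hz for 60 s, i.e.
N = 30,000 samples per channel.

Each channel is preprocessed independently:

1. **Detrending.** The least-squares polynomial trend (degree 1 by
   default — a straight line) is subtracted.
2. **Wavelet denoising.** A 9-level discrete wavelet transform with
   Daubechies db4 is taken with symmetric boundary extension; the two
   finest detail bands D1 (125–250 Hz) and D2 (62.5–125 Hz) and the
   coarsest approximation A9 (0–0.49 Hz) are zeroed before
   reconstruction. The retained content spans roughly 0.5–62.5 Hz.
   db4 is not a brick-wall filter: a tone at 100 Hz is suppressed to
   ~5 % RMS, but near the 62.5 Hz band edge the roll-off is gentler
   (~15 % RMS residual at 90 Hz). No artifact rejection, re-referencing
   or resampling is performed.

The standard deviation used for entropy tolerances is taken from the
*preprocessed* signal (sample normalization, n−1), since that is the
signal whose complexity is being measured.

## Entropy features

All measures use delay-vector templates of dimension m with lag t and
the Chebyshev (max-norm) distance, with tolerance r expressed as a
multiple of the channel STD. Defaults: m = 2, t = 1, r = 0.15·STD;
r is swept over {0.10, 0.15, 0.20, 0.25} in tolerance studies.

- **ApEn** (self-matches included). Both dimensions are evaluated over
  the same N − m·t templates; with that convention
  ApEn = Φ(m) − Φ(m+1) ≥ 0 holds unconditionally. (Evaluating dimension
  m over N − (m−1)·t templates, as some packages do, loses this
  guarantee; the difference is O(1/N).)
- **SampEn** = −ln(A/B), where B and A are the numbers of template
  pairs (i ≠ j) within r at dimensions m and m+1. Zero counts raise an
  explicit undefined-entropy error carrying (A, B).
- **CmpMSE.** At scale factor τ, all τ phase-shifted coarse-grainings
  (block means of length τ starting at offsets 1..τ) are formed; CmpMSE
  is the mean SampEn over them. The absolute tolerance is anchored to
  the STD of the original scale-1 series and reused at every scale, per
  multiscale-entropy convention. Component series with undefined SampEn
  are skipped with a warning (at realistic lengths and r ≥ 0.10·STD
  this is vanishingly rare); only if all τ components are undefined is
  an error raised. Default τ = 30; the sweep grid is
  {1, 5, 10, 15, 20, 25, 30, 35, 40}.
- **FuzzyEn.** Templates are baseline-removed (each template's own mean
  subtracted) and pairwise similarity is the exponential membership
  exp(−(d/r)^n) with fuzzy power n = 2, self-pairs excluded;
  FuzzyEn = ln φ_m − ln φ_{m+1}. The dimensionless d/r form is used so
  that FuzzyEn, like ApEn and SampEn, is exactly invariant under affine
  transformations of the signal when r ∝ STD; the variant exp(−d^n/r)
  found in parts of the literature loses this invariance for n ≠ 1.
- **Permutation entropy** (optional comparison feature): Shannon
  entropy of the ordinal-pattern distribution normalized by ln(order!),
  ties broken by order of occurrence. Order 3, delay 1 by default —
  the source analyses do not state these, so they are package choices.

**Numerics.** The ApEn/SampEn kernels sort templates by their first
component and only inspect candidate pairs whose first components lie
within r, which counts exactly the same matches as the all-pairs scan
(≈0.2 s per channel at N = 30,000). FuzzyEn has no such pruning —
every pair contributes to the exponential sum — and costs ≈8 s per
channel at N = 30,000, so extracting FuzzyEn for a full 39-trial ×
8-channel dataset takes on the order of 40 minutes, dominating the
full-length pipeline; ApEn/SampEn/CmpMSE together stay within a few
minutes. Correctness of every fast path is pinned to naive O(N²)
oracles at 1e-10 in the test suite.

## Statistical cascade

For each (measure, channel) feature, the three condition groups
(n = 13 each) are compared by:

1. Bartlett's test for equal variances (the p-value is recomputed from
   the statistic via the χ² survival function, which also covers the
   degenerate exactly-equal-variance case);
2. Shapiro–Wilk normality per condition group;
3. one-way ANOVA if *every* group passes normality at α = 0.05 and
   Bartlett does not reject; otherwise Kruskal–Wallis. The dispatch is
   a pure function of those boolean flags;
4. when the omnibus test is significant at 0.05, the three pairwise
   comparisons — Fisher-LSD-style t contrasts on the pooled within-group
   mean square (df = N − k) after ANOVA, two-sided Mann–Whitney
   rank-sum tests after Kruskal–Wallis — flagged at the Bonferroni
   threshold 0.05/3 (p < 0.015). The exact post-hoc procedure used in
   the original analyses is not named, so this choice is validated by
   its type-I calibration, not against published pairwise tables.

**Chance-level test.** A classifier's per-class correct counts
(O_Rest, O_AOA1, O_AOA2), each out of n = 13, are tested against the
uniform expectation E = n/3 with χ² = Σ(O_c − E)²/E, df = 2. This
3-cell goodness-of-fit formulation reproduces every published p-value
that accompanies an identification-rate triple to ±0.001, which the
test suite verifies for all twelve printed triples.

## Classifiers and cross-validation

- **LDA**: Gaussian discriminant with pooled within-class covariance
  and equal priors, implemented directly (and cross-checked against
  scikit-learn's LDA in the tests). If the pooled covariance is
  numerically singular a ridge λ·tr(Σ)/d·I with λ = 1e-6 is added and
  the model flagged.
- **SVM**: scikit-learn's `SVC` (libsvm), RBF kernel with the libsvm
  defaults C = 1 and γ = 1/d, one-vs-one voting, and class-weight
  balancing (see below). Prediction ties are resolved by aggregate
  decision values and then by class order (Rest < AOA1 < AOA2, fixed by
  integer label encoding).

Features are z-scored per training fold by default (RBF SVMs are
scale-sensitive; entropy measures differ in range). Whether the
original analyses standardized is unknown, so the step is switchable.
Evaluation is leave-one-out cross-validation over all 39 trials; the
confusion matrix, per-class identification rates, their average, and
the chi-squared chance-level p-value are reported. n per class is
derived from the label vector, never hard-coded.

**Why the SVM balances class weights.** Leave-one-out folds are never
quite balanced: the held-out trial's class has 12 training samples
against 13 for the others. When classes overlap heavily (as under a
null), each one-vs-one RBF classifier degenerates to predicting its
majority class, so the held-out trial's class receives zero votes in
*every* fold and the measured identification rate collapses to exactly
0 % — a severe anti-learning artifact, not an unlucky draw. Weighting
classes by inverse frequency (natively supported by libsvm) removes the
asymmetry; with it, null-data LOOCV sits near chance. Even so, LOOCV at
n = 39 retains mild below-chance pessimism under a true null, so the
null-behaviour tests check the median rate against the central 95 %
binomial band around chance (17.9–48.7 % for 39 trials) rather than
against 33.3 % exactly. `class_weight=None` restores raw libsvm
behaviour.

## Synthetic-EEG generator

No recordings are distributed with the original study, so a simulator
provides labelled data with a controllable condition effect. Each
trial is

    10 · gain · ( broadband(α) + oscillations + 0.05 · white noise )

- **Broadband component**: Gaussian noise with 1/f^α spectrum
  (spectrally shaped white noise, clamped below 0.5 Hz), normalized to
  unit STD. The per-condition *complexity* knob c ∈ [0, 1] sets
  α = 2(1−c): whiter spectra are more irregular, and sample entropy
  increases monotonically in c. Defaults: Rest 0.36 < AOA2 0.47 <
  AOA1 0.60, chosen so that group-level separations and LOOCV
  identification rates land in the 50–90 % range rather than at a
  trivial 100 %.
- **Channel structure**: all channels share a common broadband source
  with mixing weight 0.3 plus an independent component whose complexity
  carries a small per-channel offset (sd 0.03), so per-channel features
  correlate without being redundant copies of one latent variable.
- **Oscillations**: fixed-amplitude delta/theta/alpha/beta sinusoids
  (2, 6, 10, 20 Hz) with per-trial random phases and ±5 % frequency
  jitter; amplitudes are condition-independent.
- **Subject and trial variability**: each subject carries a random
  gain (±20 %) and a complexity offset (±0.05) shared across their
  three trials; each trial additionally receives a condition-independent
  complexity drift (sd 0.08) representing state fluctuation between
  recordings. Without the trial-level drift the three trials of a
  subject are near-replicas in feature space, and LOOCV under a null
  configuration collapses far below chance because the held-out trial's
  nearest neighbours are its own subject's other-condition trials; the
  drift keeps within-subject variability on the scale of
  between-subject variability, which is what honest chance-level null
  behaviour requires.
- **Seeding**: a single master seed; per-trial and per-subject streams
  are derived by stable CRC-32 hashing of (seed, subject, condition,
  trial seed), so any subset regenerates identically.

**What the generator does and does not emulate.** It reproduces the
complexity structure the entropy features consume — group-mean
orderings AOA1 > AOA2 > Rest, subject heterogeneity, channel
correlation — but not stimulus-locked entrainment, event-related
potentials, artifacts, or realistic scalp topography. Passing pipeline
tests on synthetic data therefore demonstrates that the chain of
estimators, statistics and classifiers recovers an injected complexity
effect at the study's sample size; it does not certify performance on
recorded EEG. One specific limitation: a spectral-slope complexity knob
orders entropy correctly at coarse-graining scales up to about τ = 10,
but at the largest scales the classic multiscale crossover (white noise
loses entropy under averaging faster than correlated noise) inverts
the ordering, so CmpMSE at τ = 30 does not separate the synthetic
conditions the way the published recordings did. Mixture models in
which complexity controls the rhythmic-versus-broadband power fraction
were evaluated and found to have no usable large-scale response either;
the ordering property is accordingly tested at τ = 5. Likewise, the
published observation that ApEn ordered Rest > AOA2 while SampEn
ordered AOA2 > Rest is not reproducible with any single monotone
complexity knob; the generator orders all four measures consistently.

## Problem sizes

Library defaults are study-faithful (13 subjects, 60 s, N = 30,000,
τ = 30). The test suite and the acceptance script run the
pipeline-level experiments at 12 s per trial (N = 6,000) over 10–20
dataset seeds, and oracle-equivalence checks at N ≤ 500 — sizes at
which every qualitative behaviour above is stable while the whole suite
completes in minutes.
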