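# Methods

## Synthetic data model

The generator produces everything the analysis consumes: trial designs,
behavioural responses and 4D BOLD phantoms, on one shared voxel grid per
cohort (spatial normalisation is therefore the identity).

**Design.** Each scanning session has 4 runs of 36 trials: every
(word, speaker) pair of 12 disyllabic words × 3 speakers occurs exactly
once per run, in a pseudo-random order with at most two consecutive
same-speaker trials (sampled sequentially among admissible remaining
pairs, with restart on dead ends). Inter-stimulus intervals are drawn
from an exponential distribution (rate 1/s, configurable) truncated to
[3, 5] s by inverse-CDF sampling. The real task is self-paced — the ISI
runs from the response instant — which the generator approximates with a
fixed nominal 3-s response slot between stimulus offset and ISI onset;
this keeps onsets deterministic at design time, guarantees that 36
trials always fit the 366 × 0.955 s run, and guarantees that simulated
responses (RT ≤ the 5-s answer window) never overlap the next stimulus.
The learning phase is 2 sessions × 36 trials = 72 self-paced trials.

A note on run length: the stated run duration of "5 min and 62 s" is
inconsistent with 366 volumes × 0.955 s ≈ 349.5 s; the generator trusts
the volume count × TR.

**Behaviour.** An answered trial is correct with probability `ability`
(per-trial, in [0, 1]); errors are routed through a row-stochastic
confusability kernel whose default sends 70 % of Betty/Chloe errors to
each other (the two perceptually closest voices) and splits Anne's
errors evenly. A per-speaker additive shift of ability (defaults
+3.9 / +1.3 / −5.9 percentage points) reproduces the observed ordering
in which the third speaker is hardest. Responses are missing with
probability `miss_rate` (default 2 %), independently of correctness
(no accuracy–RT or accuracy–missingness dependence is modelled).
Reaction times are lognormal (location log 1.2 s, scale 0.35) truncated
at the answer window, giving a mean near 1.3 s.

**Cohort.** Ability is uniform on [0.35, 0.90] (mean 62.5 %,
SD 15.9 %), emulating a sample recruited for a wide spread of voice
recognition skill. The neural effect size of subject *i* is the monotone
mixture `f = (1 − c)·g_i + c·ability_i` with `g_i` a subject-specific
uniform draw and `c` the coupling parameter: `c = 0` decouples brain
from behaviour (null for the regression stage), `c = 1` makes
decodability a deterministic monotone function of ability.

**BOLD phantom.** Per run,

    signal = Σ_trials HRF ⊛ boxcar × (baseline + effect × pattern_speaker)
             + drift + ε,   ε ~ N(0, σ²) i.i.d.

Baseline activation (default 2.0 arbitrary units) covers the
sound-responsive mask; speaker-specific patterns are N(0, 1) per-voxel
draws inside designated informative ROIs, drawn once per subject and
held fixed across runs (the across-run stability a cross-validated
decoder requires). Default noise σ = 0.5 yields single-subject ROI
accuracies in the 0.4–0.7 range for abilities in the default span —
the regime where the brain–behaviour correlation is neither at floor
nor at ceiling. Drift is a random-phase sum of cosines with periods
above the 128-s high-pass cutoff, so the GLM's DCT basis can remove it
exactly. An optional word-specific pattern (off by default) adds
speaker-unrelated, word-locked structure; it leaves leave-one-run-out
decoding mostly intact but degrades leave-one-word-out generalisation,
emulating content-specific components of real voice patterns.

What the phantom does **not** emulate: spatial autocorrelation of noise,
physiological and motion artefacts, susceptibility dropout, anatomical
variability across subjects, and temporally autocorrelated noise
(noise is white; the GLM's optional AR(1) pre-whitening exists for
fidelity but is off by default). Passing tests therefore demonstrate
correctness of the analysis machinery under the stated generative model,
not robustness to every property of real fMRI data.

## First-level GLM

Single-trial least-squares-all (LSA): all 36 trial regressors of a run
enter one design together with one zero-duration response-stick
regressor at the response instant (omitted for trials without a
response), optional nuisance columns, an orthonormal DCT high-pass basis
(cutoff 128 s) and a constant. Regressors are built on a 0.1-s grid by
convolving boxcars with the canonical double-gamma HRF (peak 6 s,
undershoot 16 s, unit dispersions, peak:undershoot 6) and sampled at
volume times. Estimation is ordinary least squares via the
pseudo-inverse; rank-deficient designs are estimated anyway (minimum-norm
solution) and reported through a dropped-column list identified by
QR with column pivoting. Zero-variance voxels in group t-maps become
signed infinities with a degeneracy flag rather than NaNs, so
thresholding stays monotone.

## Decoding

The multiclass reduction is explicit one-vs-one voting: one binary
soft-margin SVM (default linear kernel, C = 1) per pair of speakers,
majority vote at prediction, and vote ties — including genuine
3-cycles — broken deterministically to the lexicographically smallest
label. No feature scaling is applied by default (betas are already on a
common scale within a sphere); optional per-feature standardisation is
fit on training folds only. On the kernel question the default is
linear, with RBF available, since linear SVMs are the standard
searchlight practice at these sample sizes.

Cross-validation folds are defined by run (LORO, 4 folds) or word
(LOWO, 12 folds; training on 11 words × 3 speakers × 4 runs). Fold
predictions are pooled before accuracy and confusion matrices are
computed; for balanced folds this equals averaging per-fold accuracies.
The searchlight default sphere boundary is exclusive (distance < r,
895 voxels at r = 12 mm on 2-mm voxels); inclusive (≤ r, 925) is
available. Spheres clipped below 10 voxels by the mask are still
classified but flagged. A fold whose training set lacks a class is an
error at the ROI level and an undefined (NaN, logged) voxel in the map.

One caveat established while validating the null: a *global* label
permutation breaks the within-run class balance of the design and
biases cross-validated accuracy below chance (a well-known CV artefact);
null checks in the tests therefore permute labels within runs, which
preserves balance and centres the null at 1/3.

## Group inference

Accuracy maps are chance-centred (−1/3), smoothed (8-mm FWHM separable
Gaussian with mask renormalisation, so constants are preserved at mask
edges), and tested:

- **Sign-flip one-sample test.** Under the symmetric null each
  subject's centred map may be negated; each permutation draws a ±1 per
  subject, recomputes the voxelwise one-sample t, and records the
  maximum over the analysis mask. `p_FWE(v)` is the fraction of
  permutations (identity always included, so p ≥ 1/N) whose maximum
  reaches `t(v)`.
- **Covariate permutation regression.** The statistic is the t of the
  slope of accuracy on the behavioural covariate; the null permutes the
  covariate across subjects (simple permutation — with a single
  covariate and intercept this is the standard exchangeability
  argument; Freedman–Lane is unnecessary). Spearman R² is attached
  descriptively per voxel; FWE correction is on the slope-t.

Both tests are one-sided by default (above-chance accuracy, positive
brain–behaviour slope), matching the directional hypotheses; two-sided
is a flag. The explicit sound-responsive mask is applied *before* the
max-statistic computation: restricting the mask can only shrink the
permutation maximum, hence never increases corrected p-values inside
the retained region. Cluster reporting uses 26-connectivity, an
extent threshold in mm³, and greedy within-cluster peak selection in
descending order subject to pairwise separation > 8 mm. Variance
smoothing (pseudo-t) and cluster-mass/TFCE inference are not
implemented — plain t only, a stated fidelity gap.

## Confusion analytics

Confusion matrices count answered trials only (missing responses have
no answer cell and are reported separately) and are normalised to sum
100 across all nine cells. Matrix–matrix association uses Spearman rank
correlation on the 9-cell vector by default (the 6 off-diagonal cells
are selectable); for ≤ 9 cells the one-tailed p-value is exact, by
enumeration of all permutations of one rank vector. The all-9-cell
default follows from the observation that a rho of ~0.5 with a
one-tailed p near 0.08 is only consistent with n = 9.

## Problem sizes and tolerances

The test suite and acceptance script run at desk scale as the package's
own choice of problem size: phantom grids of 6³–10×10×8 voxels
(full-size grids change only memory and wall-clock, not code paths),
12–40 subjects, 200–1000 permutations. Calibration of both permutation
tests is checked on 200 null datasets (12 subjects, 1000 voxels,
500 permutations) against a familywise rejection band of [0.03, 0.07]
at α = 0.05; parameter recovery is checked over 20 cohort seeds at
n = 40 with the coupled and the decoupled generator. Exactness checks
use 1e-8 (noiseless GLM recovery), 1e-10 (DCT orthonormality, constant
preservation under smoothing) and a 10 % band on the OLS variance
formula over 1000 replicates. Numerically infinite statistics (zero
residual variance) are compared with a 1e-12 slack so permutation
p-values remain exact.

## Known limitations

- White, spatially independent noise; no AR(1) data generation (only
  estimation-side pre-whitening as an option).
- One shared grid per cohort; no registration or anatomical atlases.
- The OvO SVM is refit per sphere per fold without caching across
  neighbouring spheres; large grids are therefore CPU-bound.
- The response regressor uses the response instant; for missing
  responses it is omitted entirely (the alternative — a stick at the
  window end — is not modelled).
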