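# Methods

## Problem setting

Two-class motor-imagery BCI classifies short multichannel EEG epochs by the
spatial distribution of band power: imagining left- versus right-hand movement
modulates sensorimotor-rhythm variance (ERD/ERS) differently over the two
hemispheres. Common Spatial Patterns (CSP) finds spatial filters `w` that
maximize the variance ratio between the class-conditional signals,

    J(w) = w' C1 w / w' C2 w,

where `C1`, `C2` are the class covariance matrices. The stationary points are
the generalized eigenvectors `C1 w = λ C2 w`; the filters with the largest and
smallest `λ` are the most class-informative. Scalp EEG, however, contains
large-amplitude outliers (ocular and motion artifacts, loose electrodes), and
because covariance is quadratic in amplitude, a handful of contaminated trials
can dominate `C1` and `C2` and redirect the filters entirely.

## The three estimators

**Classical (L2) CSP** — `solve_csp_l2` solves the generalized eigenproblem
with `scipy.linalg.eigh(C1, C2)` and returns the `n_pairs` top and `n_pairs`
bottom eigenvectors, each scaled to `w' C2 w = 1`.

**Tikhonov-regularized CSP** — `solve_csp_tr` maximizes
`w' C1 w / (w' C2 w + α ‖w‖²)` (and the class-swapped quotient for the second
half), i.e. the generalized eigenproblem with penalized denominator
`C2 + αI`. The penalty shrinks high-norm, spatially rough filters. `α` is
selected by stratified cross-validation on the training data
(`tune_tr_alpha`, default 10 folds over the grid
{0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1} on trace-normalized covariances,
ties toward smaller `α`).

**L1-SVD-CSP** — the robust variant. Writing `Y = C2⁻¹ C1`, the L2 route is
equivalent to maximizing `‖W'Y‖₂²` under `W'W = I`; the L1 route replaces the
squared dispersion with the absolute one,

    maximize ‖W'Y‖₁  subject to  W'W = I,

so a column of `Y` inflated by outliers contributes linearly rather than
quadratically. Each direction is found by the fixed-point iteration

    w ← Y sign(Y'w) / ‖·‖₂ ,

initialized at the principal left singular vector of the current matrix. The
update never decreases the objective, so it converges to a local maximum
(convergence: iterate movement below `1e-8` after sign canonicalization; cap
200 iterations; an exactly zero projection `w'yᵢ = 0` is broken by a seeded
`1e-6` perturbation of `w`). Subsequent directions are extracted after
orthogonal deflation `Y ← Y − w (w'Y)`. Reported scores are `‖w'Y‖₁` against
the *original* `Y`; greedy deflation does not guarantee they are
non-increasing.

Two modes are provided. The default `"literal"` mode runs the iteration on
the non-symmetric `C2⁻¹C1` itself (and on `C1⁻¹C2` for the second half). The
`"whitened"` mode runs it on the symmetric `C2^{-1/2} C1 C2^{-1/2}` and maps
the directions back through the whitener; for symmetric input the L1 singular
directions coincide with eigendirections in the L2 limit, so this mode tracks
classical CSP more closely on clean data, at the cost of sensor-space
orthonormality.

Numerical details shared by all three: covariances are symmetrized, and a
denominator matrix with condition number above 1e12 receives a ridge of
`1e-10 · trace/d` (with a warning) before inversion; filter signs are fixed so
the largest-magnitude coefficient is positive (log-variance features are
sign-invariant, fixed signs make outputs reproducible); equal eigenvalues keep
the stable eigendecomposition order.

## Covariance estimation

`estimate_class_covariance` averages per-trial `X X'` over the class. By
default each per-trial matrix is divided by its trace and the average is
re-normalized to unit trace, which makes filters invariant to global amplitude
scaling. The evaluation protocol, however, deliberately uses the **raw**
average (`trace_normalize=False`): trace normalization caps every trial's
leverage at `1/n`, which would suppress exactly the amplitude-driven
contamination whose effect on CSP is under study. A 10-sigma artifact trial
should dominate a raw covariance — that is the failure mode the L1 variant is
designed to resist.

## Features and classifier

Trials are band-pass filtered with a zero-phase (forward–backward) 5th-order
Butterworth filter — default 8–30 Hz, the standard mu+beta motor-imagery
band — and cropped to the 0.5–2.5 s post-cue window. Each trial is projected
onto the `2·n_pairs` filters (default 3 pairs → 6 surrogate channels) and
summarized by the log of each surrogate channel's sample variance (ddof = 1).
Variance sum-normalization before the logarithm is available
(`normalize=True`) but off by default. Classification uses Fisher LDA with
equal priors: `w = Sw⁻¹(m₁ − m₂)` with pooled within-class covariance
(ddof = N − 2) and the bias at the midpoint of the projected class means; the
within-class covariance receives the same ridge repair as above if singular.

## Synthetic data generator

`generate_mi_dataset` emulates the standard linear-mixing picture of EEG:

* sources are white Gaussian processes band-limited to `source_band`
  (default 8–12 Hz, zero-phase 4th-order Butterworth), unit variance;
* one discriminative source's variance is `class_variance_ratio`-fold larger
  in class 1 than class 2 (split symmetrically, ±ratio^(1/4) in amplitude, so
  overall power stays balanced);
* `n_background_sources` class-independent sources;
* sensors are a random full-rank Gaussian mixing of the sources plus white
  sensor noise at power `signal_power / snr`;
* classes are balanced and alternate within each of the train and test sets.

Defaults: 118 channels, 70 trials per class per set (280 pooled trials),
100 Hz, 3.5 s trials, variance ratio 2, 40 background sources, SNR 2. The
montage/pool sizes mirror a full-scalp competition-style recording — the
regime in which a 118-dimensional covariance estimated from ~110 trials per
class is genuinely fragile and spatial-filter estimators separate. The
variance ratio and SNR were set so that clean 5-fold accuracy lands near 0.80,
typical of single-session motor-imagery subjects. At desk scale with few
channels (≤ 32) and many trials per dimension, covariance estimation is so
well conditioned that neither outliers nor estimator choice matters much — a
useful negative control, not a bug.

What the generator does **not** emulate: non-stationarity across trials,
correlated (pink) background spectra, volume-conduction geometry, real
artifact morphology (blinks, EMG bursts), or inter-subject variability.
Passing benchmarks on this generator therefore shows robustness of the
estimator to the modelled contamination, not performance on any particular
real recording.

## Outlier injection

`inject_outliers` corrupts `round(rate · (m + n))` trials drawn uniformly
without replacement from the pooled train+test list (so train and test sets
share one contamination budget; `rate` runs over {0.01 … 0.05} in the
benchmark). Corrupted
samples are replaced by i.i.d. draws from `N(μ + 10σ, Σ)` where `μ` and `σ`
are the pooled scalar mean and standard deviation over all channels and
samples and `Σ` is the pooled channel covariance (per-channel statistics are
available by flag; additive instead of replacement corruption likewise). By
default the **whole trial** is replaced: a corrupted trial is an outlier
trial. A sub-segment mode (`segment_duration` in seconds, uniformly random
onset) exists for milder artifacts, but note the leverage arithmetic: a
100 ms segment inflates a 2 s epoch's power only ~6-fold, which a
118-dimensional CSP shrugs off, whereas whole-trial replacement inflates it
~100-fold and reproduces the qualitative estimator separation.

## Evaluation protocol

`run_protocol` benchmarks the estimators at each contamination rate:

1. band-pass and window all trials once;
2. per repetition (default 50), inject outliers into the analyzed epochs with
   a repetition-specific seed. Injection happens **after** filtering: a
   band-pass above ~1 Hz removes a sustained 10σ offset almost completely
   (measured in-band power inflation ~1.2× for a 100 ms segment under
   8–30 Hz), so injecting before filtering would study a contamination that
   never reaches the covariances;
3. stratified 5-fold cross-validation over the pooled trials: covariances,
   spatial filters, and LDA are fit on training folds only; the Tikhonov
   weight is re-tuned once per repetition on the training portion of the
   first fold (10-fold inner CV);
4. per-repetition accuracy plus pooled held-out predictions are accumulated;
   method pairs are compared with McNemar's test on the pooled predictions.

All randomness derives from one master seed via a splitmix64-style mixer
(`derive_seed`), so each (rate, repetition, purpose) tuple has an independent,
reproducible stream and full runs are byte-deterministic.

**McNemar test**: with discordant counts `b` (A right, B wrong) and `c`, the
statistic is the continuity-corrected `(max(|b−c|−1, 0))² / (b+c)` referred to
chi-square(1) when `b + c ≥ 25`, and an exact two-sided binomial test on
`(b, b+c, ½)` otherwise; `b + c = 0` returns p = 1. The corrected numerator is
clamped at zero so `b = c` yields statistic 0 rather than `1/(b+c)`.

## Problem sizes

The shipped benchmark (`scripts/acceptance.py`) uses the default generator
(118 channels, 280 pooled trials), 50 repetitions, 5-fold CV, rates 0 and
0.05, two methods — about 90 seconds on one CPU. The L1-oracle census uses
200 random 3×8 matrices against exact 2⁸ sign enumeration; the convergence
census 1000 random 5×20 matrices; the diagonalization check 100 random SPD
pairs of dimension 2–16; unmixing recovery 20 seeds of a 4-channel,
square-mixing, near-noiseless configuration (with more channels than sources
and vanishing noise the top filter is only identified up to the sensor null
space, so recovery is only a well-posed question for square mixing).

## Known limitations

* The greedy fixed-point iteration finds local maxima of the L1 dispersion;
  on random 3×8 instances it attains ≥ 95% of the enumerated optimum in about
  94% of cases. No restarts are attempted (single deterministic
  initialization keeps runs reproducible).
* Literal-mode L1-SVD analyzes the non-symmetric `C2⁻¹C1`, whose L1 singular
  directions are not generalized eigenvectors even in the clean L2 limit;
  on low-dimensional, well-conditioned data it therefore trails classical CSP
  slightly. The whitened mode removes this bias at the cost of sensor-space
  orthogonality.
* LDA assumes shared class covariance of the log-variance features; no
  shrinkage is applied beyond the numerical ridge.
* Multi-class extensions, other regularized CSP variants, and subject-specific
  frequency-band selection are out of scope.
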