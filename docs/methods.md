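# Methods

## Signal model

Each channel (brain region) is modelled as a fractionally integrated
process: short-memory innovations m(t) pass through the
fractional-integration filter (1 − B)^(−a), whose impulse response is

    h(t) = Γ(t + a) / (Γ(a) Γ(t + 1)),          t = 0, 1, 2, …

computed by the overflow-free recursion h(t) = h(t−1)(t−1+a)/t. The
memory parameter a lies in the open stationary interval (−½, ½); a = 0
is white noise, a > 0 gives persistent 1/f-type behaviour, and the
Hurst exponent is H = a + ½. (Some of the fMRI literature calls a
itself the "Hurst exponent" while using the stationary range of the
fractional-integration parameter; this package consistently treats a as
the integration parameter d and reports H = a + ½ separately.)

In the multivariate case the innovation vectors are i.i.d. Gaussian,
M(t) ~ N(0, Σₘ), making the channel vector a multivariate fractionally
integrated noise (FIN). The entries η_xy of Σₘ are the *nonfractal*
covariances — the coupling of the underlying activity, free of the
power-law confound. Spectra are defined on f ∈ (−π, π) with the
convention S_white(f) = σ²/(2π); the exact FIN autocovariance

    γ(k) = σ² Γ(1−2a) Γ(k+a) / (Γ(a) Γ(1−a) Γ(k+1−a))

is evaluated by the recursion γ(k) = γ(k−1)(k−1+a)/(k−a) and agrees
with numerical quadrature of the spectrum to 1e−6 over the exponent
grid used in the tests.

## Simulation

Truncated-convolution synthesis: draw N + burn-in innovation vectors,
apply the per-channel filter h (full length), and discard the burn-in
(default max(N, 1000) samples). This is exact up to filter truncation
and keeps the code transparent; the truncation bias is negligible at
the series lengths used here (the sample autocovariance converges to
the closed form as N grows, which is tested). All randomness flows
through `numpy` SeedSequences; the two-group study generator spawns one
child seed per subject from the study seed, so any subject can be
re-simulated in isolation and identical seeds give bit-identical data.

The generator emulates a two-group cohort in which the groups differ
*only* in the innovation covariance (a shift of `effect_delta` on a
chosen edge set, default 0.4 on 20 edges at v = 20 regions, N = 256
timepoints, 30 subjects per group) while every subject receives its own
exponents drawn uniformly from (0.1, 0.45), the persistent regime
reported for BOLD signals. What it does **not** emulate: scanner drift
and motion artefacts, non-Gaussian or non-stationary physiology,
heterogeneous per-subject innovation structure beyond the group shift,
and spatial autocorrelation of neighbouring regions. Passing tests
therefore demonstrate correctness of the estimators and pipeline under
the model's own assumptions, not robustness to everything real rs-fMRI
contains.

## Wavelet analysis

Decimated orthonormal DWT, Daubechies with 4 vanishing moments
(`db4`), periodized boundaries — enough vanishing moments to
decorrelate long memory, and orthonormality gives exact energy
conservation (tested to 1e−8). Depth defaults to Q = ⌊log₂ N⌋ − 2.
The wavelet covariance at scale q is the plain cross-moment of the
detail coefficients with biased (1/n) normalization and no re-centering
(detail coefficients have zero mean by construction).

For a FIN pair the scale covariance obeys
υ_xy(q) ≈ η_xy β_xy 2^{q(a_x+a_y)} with

    β_xy = 2 cos(π(a_x−a_y)/2) (1 − 2^{a_x+a_y−1})/(1 − a_x − a_y) (2π)^{−(a_x+a_y)},

verified against an independent octave-band quadrature oracle to 1e−4.

## Estimators

**Memory parameter (per channel).** Exact Gaussian likelihood with the
Toeplitz covariance built from the closed-form FIN autocovariance. The
innovation variance is a pure scale factor of the covariance, so its
MLE given a is the whitened mean square r'T(a)⁻¹r/N; profiling it out
leaves a bounded 1-D search over a ∈ [−0.49, 0.49] (Brent, xatol
1e−5; estimates at the clip boundary are flagged). The log-determinant
and quadratic form are computed together by a Levinson–Durbin recursion
(O(N²) time, O(N) memory; numba-JIT when present, pure numpy
otherwise), validated against dense `slogdet`/`solve` on small
matrices. The ±0.49 clip keeps the β and B scaling constants finite.

**Short-memory covariance (per pair).** Averaging the detrended
log-covariances, ĉ = mean_q [log₂ υ(q) − (a_x+a_y) q], and inverting
the scaling law, η̂ = 2^ĉ / β_xy. A noiseless power law round-trips to
1e−10 on a 5×5 exponent grid (this fixes the algebra: the equivalent
form 2^{ĉ−1}(2π)^{a_x+a_y}/(B_xy cos(π(a_x−a_y)/2)) is identical).
Negative covariances (anticorrelated channels) have no log₂; the
magnitude is averaged and the sign of the scale-averaged covariance is
reapplied, preserving anticorrelated edges rather than dropping them.

*Scale range.* The finest scale (q = 1) is always excluded — it is the
most biased by the ideal octave-band approximation. In addition, the
default range drops scales with fewer than 16 coefficients (always
keeping at least the three finest usable scales): the log₂ of a
covariance estimated from 4–8 coefficients is noisy enough to dominate
the unweighted scale average, and with the plain 2..Q range the
recovery error *grows* from N = 512 to N = 4096 because deeper, sparser
scales enter; with the cutoff it shrinks (≈0.07 → ≈0.03 RMSE in the
three-channel recovery experiment). An explicit `q_range` overrides
both rules.

## Connectivity matrices

All three kinds are symmetric with unit diagonal and all v·v entries
are kept (both triangles and the diagonal), so v = 116 regions yield
13,456 connection features. η̂ is estimated pairwise, so the implied
matrix need not be positive semi-definite; entries are used entrywise
downstream and a PSD flag is recorded. Noisy variance ratios can push
|A| past 1; such entries are clipped to ±1 and counted
(`n_clipped`). Fractal and nonfractal share one estimation pass; with
a single shared exponent the β factors cancel and the two matrices are
identical, which is tested to float tolerance via the `a_fixed`
override.

## Selection and classification

Per-connection one-way ANOVA across the two groups (algebraically the
squared pooled-variance t-test, checked against scipy), threshold
p ≤ 0.05 inclusive, no multiple-testing correction; constant
connections (e.g. the diagonal) get p = 1. A `top_k` mode selects a
fixed number of smallest-p connections for length-matched comparisons.
Classifiers use fixed presets (linear SVM with C = 1; 11-neighbor
cosine KNN; Gini decision tree; 30-learner bagged trees) under
stratified 10-fold CV with 5 reseeded repeats (mean ± SD reported).
Confusion counts and AUC come from the pooled out-of-fold predictions
of the first repeat; ROC scores are SVM decision values or positive-
class vote fractions. Feature selection is refit inside every training
fold by default; the global pre-CV variant is available as
`paper_protocol` and documented as optimistic. Undefined rates
(zero-denominator) are reported as NaN, never as 0.

## Numerical and degenerate-input choices

* a = 0 short-circuits to the identity filter / white-noise
  autocovariance (no Γ(0) evaluation).
* Constant series and constant regions raise informative errors
  (memory parameter and correlation are undefined there).
* Scales with < 2 coefficients are reported as NaN, not dropped, so
  scale indices stay aligned.
* Selection ties in `top_k` break by connection index; an empty
  fold-internal selection falls back to the single smallest-p
  connection so a fold can never crash the CV loop.
* The group-1 covariance shift is PSD-projected (with a warning) if the
  requested effect breaks positive semi-definiteness.

## Problem sizes

The validation suite runs the estimator ensembles at N = 4096 with 50
seeds, nonfractal recovery at N = 1024 over 20 seeds, and the
end-to-end pipeline at v = 20, N = 256, n = 30 per group (one power
study and three null studies), sizes at which every check completes in
a few minutes on a single CPU while leaving the Monte-Carlo error well
inside the stated tolerances.

## Known limitations

* The univariate-ML-then-pairwise-regression scheme is not a joint
  multivariate MLE; η̂ inherits bias from â errors amplified across
  scales (visible as a mild downward bias at strong coupling).
* The η̂ scale average uses equal weights, not inverse-variance
  weights; the sparse-scale cutoff compensates for the worst of it.
* Classification metrics at cohort sizes of tens of subjects carry
  fold-correlation variance well above the i.i.d. binomial level;
  single-split accuracies should be read with that in mind (the
  pipeline reports the repeat spread for exactly this reason).
* The FIN model assumes Gaussian innovations and stationarity; heavy
  tails or drift violate the likelihood and the scaling law.
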