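# Methods

## Model

The classifier is a Takagi–Sugeno–Kang (TSK) fuzzy system for binary labels
in {+1, −1}. Each of K rules carries one Gaussian fuzzy set per input
dimension, `μ(x_i) = exp(−(x_i − c_i^k)²/(2 δ_i^k))`, and an affine
consequent. The rule firing strength is the product of the per-dimension
memberships; outputs are the firing-strength-weighted average of the rule
consequents. Stacking `μ̃^k(x)·(1, xᵀ)ᵀ` over rules turns that average into
a linear form `p_gᵀ x_g` of a K(d+1)-vector `p_g`, which is what all solvers
estimate. Note that `δ` is the *variance-like* quantity sitting under the 2
in the exponent, not a standard deviation; this convention is kept
throughout (some TSK literature writes `2δ²` instead — we do not
second-guess the `2δ` form).

### Antecedent learning

Fuzzy c-means (own implementation: memberships
`u_jk ∝ d_jk^{−2/(m−1)}`, centers from `u^m`-weighted means; seeded
initialization from data rows, stopping when the largest center displacement
drops below `tol`) partitions the input space; rule centers and widths are
then the *raw*-membership-weighted means and `h`-scaled squared deviations
(the fuzzifier exponent enters FCM's internal updates only). Defaults:
fuzzifier 2.0 (the standard FCM choice), `h` = 1.0 (exposed and
grid-searchable), `tol` = 1e-6, 300 iterations. Widths below 1e-8 are
clamped to 1e-8: degenerate single-point clusters otherwise blow up the
membership exponent; the floor is far below any data-driven width and has
no effect on non-degenerate fits.

In the transfer setting the antecedent space must be shared between
domains, so FCM runs by default on the pooled source+target features
(unsupervised, hence legitimate in the transductive setting); a
source-only mode is available.

Firing strengths are normalized in log space (a log-sum-exp): far from
every rule center the raw membership products underflow to zero, but their
*ratios* remain well defined, and the log-space form computes exactly those
ratios. A uniform 1/K fallback remains only for rows that are non-finite
even in log space (practically unreachable with finite inputs) and warns
when taken.

### Consequent solvers

The classic ridge objective `½pᵀp + (λ₁/2)‖pᵀX_s − y‖²` has the closed-form
minimizer `(I + λ₁X_sX_sᵀ)⁻¹(λ₁X_s y)`. The transfer objective adds
`λ₂ tr(pᵀXMXᵀp) + λ₃‖p_g0 − p‖²`; its stationarity condition is

```
((1 + 2λ₃) I + λ₁ X_s X_sᵀ + λ₂ X (M + Mᵀ) Xᵀ) p = λ₁ X_s y + 2λ₃ p_g0 .
```

Both systems are symmetric positive definite for nonnegative λ (the unit
identity term guarantees it) and are solved by Cholesky factorization,
never explicit inversion. A `literal_form` compatibility mode reproduces a
historical variant of the solve — `(X(M+Mᵀ)/2 Xᵀ + λ₁X_sX_sᵀ + λ₃I)p =
λ₁X_s y + λ₃p_g0` — that omits the λ₂ weight, the unit ridge identity and
the factor 2 on the knowledge term; it is *not* the minimizer of the
objective and exists only for cross-implementation comparison. The default
solver is verified against a BFGS minimizer with analytic gradients
(relative objective agreement ≤ 1e-6, gradient norm ≤ 1e-8 at the returned
point) in the test suite and the acceptance script.

Regression targets are the ±1 labels themselves; predictions are
`sign(p_gᵀx_g)` with an exact zero mapped to +1 for determinism.

### Distribution adaptation

Target pseudo-labels come from a linear-kernel SVM with unit cost trained
on the raw source features (any fit/predict estimator can be plugged in; a
design-space mode exists behind a flag). One pseudo-labelling pass is the
default; `refine_iterations > 1` re-labels the target with the current
transfer fit and re-solves, for users wanting the iterated
joint-distribution-adaptation variant.

The MMD matrices over the pooled (source-then-target) sample axis are
written entry-wise by case — `1/n²`, `1/m²`, `−1/(nm)` for the marginal
matrix, the per-class analogues with class counts for each conditional
matrix — each being the outer product of a signed indicator vector, hence
symmetric PSD with zero row sums (M annihilates constants). A class with no
members on either side contributes a zero matrix with a warning rather than
an error: aborting would make small-sample experiments brittle, and the
conditional distance is simply undefined (taken as 0) there. The assembled
M is symmetrized defensively before entering the solver. The diagnostics
module computes every projected distance twice — by the mean-difference
formulas and by the trace form `tr(pᵀXMXᵀp)` — and raises if the two
disagree beyond 1e-8.

Because the transfer solve is an exact minimizer, the fitted joint distance
at the λ₂ > 0 solution is provably ≤ its value at the λ₂ = 0 solution with
all other terms fixed (compare the two objectives at both minimizers); the
test suite asserts this per seed rather than on average.

## Synthetic domain-shift generator

The generator emulates post-feature-extraction EEG vectors: d = 6 by
default (matching the low-dimensional kernel-PCA-style feature view under
which interpretable five-rule models are usually displayed), isotropic
Gaussian class clusters separated by `separation` along the first axis,
+1 = "healthy", −1 = "epileptic". The target domain is the source
distribution translated by a marginal shift (all samples, along the
diagonal direction) plus per-class conditional shifts (opposite directions
along the second axis), so marginal-only and joint adaptation are
distinguishable. Optional label noise flips training labels.

What it does *not* emulate: raw EEG time series, heavy-tailed or correlated
feature noise, within-class multimodality, and the particular spectral
structure of wavelet/STFT features. Passing tests therefore demonstrate the
estimator's correctness and the direction of the transfer effect, not
clinical-grade accuracy on real recordings. The benchmark accuracy tables
shipped with the package are reference results over the Bonn EEG corpus
pairings; the package reproduces their *analysis* (ranks, Friedman, Holm)
exactly but does not attempt to regenerate the accuracies, which would
require the external corpus and unspecified feature-extraction settings.

The scaled-down transfer-gain benchmark fixes one scenario — d = 6,
n = m = 100, separation 3.0, noise SD 1.0, marginal shift 1.5, conditional
shift 0.75, 20 scenario seeds — with coarse grids K ∈ {2, 5},
λ₁ ∈ {10⁻², 1, 10²} and additionally λ₂, λ₃ ∈ {0, 1, 10²} for the transfer
model, selected by oracle target accuracy (the customary protocol in this
benchmark literature; a source-only cross-validation mode is provided for
honest model selection). These sizes keep a full 20-seed sweep under a
minute while leaving the shift strong enough that adaptation matters.

## Evaluation harness

Ranks are per-dataset, descending in accuracy, ties averaged — required to
reproduce reference average ranks where two methods tie to four decimals.
Friedman's χ² uses the classical formula on k−1 degrees of freedom; the
Iman–Davenport F refinement is computed alongside, and neither p-value
variant is privileged (reference tables in this literature are often
ambiguous about which was printed). Holm's post hoc uses
`SE = √(k(k+1)/(6N))`, two-sided normal p-values, thresholds α/i stepping
down from the largest Z, and the *strict* step-down stopping rule: once a
comparison fails, no smaller-Z comparison may reject (published tables
sometimes mark later comparisons rejected by comparing each p to α
directly; this package does not).

## Numerical choices and limitations

- FCM restarts are not performed; a single seeded run is used so results
  are bit-reproducible. Multi-start users can vary `seed`.
- Grid search re-runs FCM per rule-count cell; per-cell results (including
  failures) are logged exhaustively.
- Binary labels only; the conditional MMD machinery indexes classes
  {+1, −1} (the marginal term is class 0 in the c = 0…C convention).
- Probabilistic outputs, kernelized MMD and streaming updates are out of
  scope.
- `run_trials` varies FCM initialization and any stochastic component of
  the pseudo-labeller across repeats; data resampling is off by default.
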