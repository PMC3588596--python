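# Methods

## The randomization model

A two-arm trial enrolls n patients in a fixed order. Patient order, baseline
covariates and the unknown unit effects y₀ are treated as fixed; the only
random element is the assignment vector δ ∈ {0,1}ⁿ produced by the trial's
randomization rule. Under unit-treatment additivity the observations are
y = y₀ + δτ. Conceptual replications of the trial are independent re-runs of
the randomization on the same patients, so all distributional statements
(bias, variance, test level) are taken over the rerandomization distribution
of δ.

The covariate matrix **X** (n × q) must contain the constant vector in its
column space and have full column rank. With **M** = **I** −
**X**(**X**′**X**)⁻¹**X**′, the treatment-effect estimator is the
normal-equations coefficient τ̂ = δ′My / δ′Mδ, identical to the OLS
treatment coefficient in a fit of y on [**X**, δ].

### The constant-probability condition

All estimation results require Eδ = p·**1** with p = r₁/(r₁+r₂) the planned
allocation fraction: every patient's *unconditional* probability of
experimental assignment equals p, even though the conditional probabilities
given earlier assignments vary by design. Most 1:1 rules satisfy the
condition by label symmetry. For unbalanced allocation it fails easily; the
package's diagnostics compute Eδ exactly (dynamic programming) or by Monte
Carlo and flag deviations (threshold: max |Eδᵢ − p| > 0.005 exact, or 3
Monte-Carlo standard errors otherwise).

### Variance approximation and estimation

First-order expansion of the ratio τ̂ gives

    Var(τ̂) ≈ y₀′MVMy₀ / (tr MV)²,      V = Var(δ),

a quadratic form in the residuals of y₀ after regression on **X** (hence
invariant under y₀ → y₀ + **X**b). The data-based estimator

    v̂ = (y′MVMy − τ̂²·tr(MVMV)) / (tr MV)²

is approximately unbiased for that approximation: the τ̂² subtraction removes
the "sum of squares for treatment" that y carries relative to y₀. In small
samples the subtraction can turn negative; v̂ is then floored at zero and a
warning is issued. Tests and confidence intervals use the normal
approximation z = (τ̂ − τ₀)/√v̂, supported by a CLT for τ̂ under mild
conditions on the design.

### Conditional inference

δ′Mδ is ancillary (in stratified cases a function of per-stratum arm counts
only), so one may condition on it. The engine computes conditional moments
p_c = E(δ | δ′Mδ ∈ bin) and V_c = Var(δ | δ′Mδ ∈ bin) with the ancillary
grouped to the nearest 0.2 (the bin width is a parameter). The conditional
variance estimator implemented is

    v̂_c = (y′MV_cMy − τ̂²·tr(MV_cMV_c)) / ((tr MV_c)² − tr(MV_cMV_c)).

Derivation of the denominator: within a bin where δ′Mδ = c is constant and
the design is a symmetrical 1:1 rule, Mp_c = 0 and τ̂ = τ + δ′My₀/c, so
E[y′MV_cMy | c] = y₀′MV_cMy₀ + τ²·tr(MV_cMV_c) and E[τ̂² | c] = τ² +
y₀′MV_cMy₀/c². Subtracting and dividing by c² − tr(MV_cMV_c) (= (tr MV_c)²
− tr(MV_cMV_c), since tr MV_c = c there) makes the estimator *exactly*
conditionally unbiased for Var(τ̂ | c); the test suite verifies this to
1e−10 by enumeration. The corrected denominator exceeds the naive (tr MV_c)²
choice by an O(1/n) factor, so the two agree asymptotically.

For unbalanced allocation, even designs with Eδ = p·**1** have non-constant
p_c: e.g. 2:1 permuted blocks of six at ten patients, conditional on
δ′Mδ = (1/8 + 1/2)⁻¹ = 1.6, force patients 7–10 onto experimental
treatment. The resulting conditional bias of τ̂ is, to first order,
p_c′My₀ / tr(MV_c) — proportional to the covariance between p_c and the
unit-effect residuals; the normalized version divides by the conditional
standard deviation √(y₀′MV_cMy₀)/tr(MV_c). For the 38-patient fixture with
an increasing linear trend in y₀ this normalized bias is positive in
low-ancillary bins and negative in high-ancillary bins.

### When Eδ ≠ p·1

The first-order unconditional bias is p′My₀ / tr(MV), zero iff the marginal
probability vector p is constant (M annihilates constants). Augmenting **X**
with p (`augment_repair`) zeroes the first-order term exactly; residual
O(1/n) ratio bias remains, so the repair is reliable once the first-order
term dominates (in our enumeration checks, from n ≈ 16 on for the 2:1
biased coin with a linear trend; at n = 12 the unrepaired bias is
accidentally near zero through cancellation and the comparison is not
informative). The randomization test is unaffected by Eδ ≠ p·**1** by
construction — the null distribution is simply not centered at zero.

## Randomization designs

All designs share one contract: a hashable state (the minimal sufficient
statistic of the assignment probability) plus `outcomes(state, stratum)`
returning possible assignments with probabilities and successor states.
Implemented rules, with parameters and defaults:

- **Complete** — P(experimental) = p every time. V = p(1−p)·I.
- **Permuted blocks** (block size, multiple of r₁+r₂; stratified or pooled) —
  draws without replacement from blocks with r₁:r₂ composition; a terminal
  incomplete block is truncated at enrollment end, not re-balanced.
- **2:1 biased coin** (p_low = 0.9, p_high = 0.2, threshold = 1) — applies
  the favoring coin when |n_e/2 − n_c| ≥ threshold (non-strict inequality),
  else assigns experimental with probability 2/3. Violates Eδ = (2/3)·1.
- **2:1 marginal balance** (p_low = 0.9, p_high = 0.2) — for a hypothetical
  assignment to each arm computes the relative imbalance
  |n_e/r₁ − n_c/r₂| / (n_e/r₁ + n_c/r₂) of the resulting counts and favors
  the arm yielding the smaller value; ties (including the first patient) use
  2/3. The *prospective, normalized* form of the metric is the one that
  reproduces the known exact probability sequence of this rule
  (0.433, 0.807, 0.881, 0.342, …, P(δ₂₀=1) = 0.340); a retrospective
  unnormalized comparison does not. Violates Eδ = (2/3)·1 badly.
- **2:1 urn** (add_on_control, add_on_experimental = 1, start 2 E / 1 C) —
  assign experimental with probability E/(E+C); a control assignment adds
  `add_on_control` E balls, an experimental assignment adds one C ball.
  `add_on_control=2` is the defective generalization whose marginal
  probabilities drift to 0.586; `add_on_control=4` restores the 2/3 limit
  (though finite-sample marginals still vary: 0.619, 0.641, 0.656, …).
- **Sequential arm-combining** — randomize 1:1:…:1 to r₁+r₂ arms with any
  arm-symmetric inner rule, then pool the first r₁ arms as experimental.
  Arm symmetry gives Eδ = p·**1** exactly. The default inner rule is
  stratified permuted blocks over r₁+r₂ arms with one slot per arm per
  block; it is pluggable because the inner method used in the original
  38-patient evaluation is not published — our reconstruction matches its
  ancillary expectation to ~0.05 but concentrates δ′Mδ more tightly.
- **Pocock–Simon 1:1 minimization** (per-factor weights, bias_prob = 0.75) —
  favors the arm minimizing the weighted sum over the current patient's
  factor levels of the post-assignment arm-count imbalance; label-symmetric,
  hence unbiased.
- **Efron 1:1 biased coin** (bias = 2/3) — favors the lagging arm.

## Exact engine

`marginal_probs` propagates the exact distribution over design states
patient by patient (cost: n × reachable states; a cap guards pathological
state growth). `enumerate_full` lists all assignment sequences with
probabilities (default cap n = 20, zero-probability branches pruned; paths
that differ only in internal arm labels are merged), supporting exact Eδ, V
and conditional moments. `limiting_prob` reports the DP value at a horizon
(default 500, tolerance 1e−6, warning if not converged — the 2:1 coin rules
oscillate and have no limit). Monte-Carlo counterparts vectorize over
replicates by grouping them by state, so sampling 10⁵–10⁶ rerandomizations
takes seconds. Printed-value comparisons in tests round half-even to 3
decimals.

## Linear-model comparison

The conventional OLS variance estimate s²/(δ′Mδ) is compared with the
randomization variance through its rerandomization expectation
(ratio-of-expectations approximation; τ terms cancel to first order):

    E_r[v̂_lm] ≈ (y₀′My₀ − y₀′MVMy₀/tr MV) / ((n − q − 1)·tr MV).

For pattern-free (i.i.d.) unit-effect residuals both quantities estimate
σ²/tr MV; a low-frequency trend makes the OLS estimate larger than the
randomization variance, high-frequency alternation reverses the order.
Exposure of a design to an unmodeled covariate z is z′MVMz (accidental
bias); blocking suppresses it for smooth trends. Under complete
randomization (V = p(1−p)I) the randomization and OLS variance estimators
agree up to O(1/n) (they differ by the n−q vs n−q−1 divisor and by δ′Mδ vs
its expectation); the suite checks 1% agreement at n = 200.

## Randomization tests

The test holds y and patient order fixed, replays the design, and computes
the add-one p-value (count+1)/(reps+1) (guaranteeing validity). One-sided
tests compare replicate τ̂ to the observed value; two-sided tests compare
|τ̂ − null mean| using the empirical replicate mean as center (robust to
Eδ ≠ p·**1**). Replicates with δ′Mδ = 0 cannot yield an estimate and are
skipped with their count reported. Conditional tests keep replicates in the
observed δ′Mδ bin (nearest 0.2), automatically widening to 0.4 with a
warning when the bin holds fewer than 200 replicates. The closed-form null
variance y′MVMy/(tr MV)² exceeds v̂ by exactly τ̂²·tr(MVMV)/(tr MV)² per
dataset.

## Synthetic data

`make_study38` builds the 38-patient reference trial: two binary
stratification factors with cell counts 10, 8, 11, 9; entry order drawn
once from a seeded generator and then held fixed (the published order is
unavailable; E(δ′Mδ) is order-invariant given the cell composition, so
order only affects patient-level figure shapes); adjustment = intercept +
two main effects; designs = stratified 2:1 permuted blocks of six and the
sequential arm-combining rule. Under stratified permuted blocks the exact
E(δ′Mδ) is 8.337 (reported elsewhere at one-decimal precision as 8.3) and
≈90% of the ancillary mass lies in [7.7, 8.9].

`gen_unit_effects` produces fixed y₀ vectors with a stated variance split:
a systematic component (linear trend, half-cycle sinusoid, or ±1
alternation) scaled to carry fraction r² of the total variance σ²
in expectation, plus i.i.d. normal noise. Defaults (σ² = 1, r² = 0.5)
follow the reference evaluation. The generator emulates only the time
structure of unit effects; it does not model covariate-dependent effects,
heteroscedasticity, or treatment-effect heterogeneity, so green tests
establish properties of the randomization machinery, not robustness to
those features.

Scripted studies (`run_study`) regenerate the probability tables, the
conditional-probability and conditional-bias curves, the variance
comparison and the CLT size/coverage table end-to-end. The original
evaluations used 10⁷/10⁶ replicates; defaults are scaled to 2×10⁵/10⁴ to
run in minutes on one CPU, with `--full` restoring larger counts.

## Numerical choices

- Residual-maker via rank-revealing (pivoted) QR, rank tolerance 1e−10;
  rank deficiency raises an error naming the collinear terms. Factor terms
  use full-rank treatment coding with the intercept retained; M is
  coding-invariant (tested).
- Marginal-balance and allocation arithmetic use exact rationals where ties
  matter; DP masses are floats with a 1e−9 conservation guard per step.
- The 10-patient 2:1 worked example requires M = I − J/10 (a J/12 variant
  circulating in one account is inconsistent with δ′Mδ = 1.6 and is treated
  as an erratum).
- Negative variance estimates floored at zero with a warning rather than
  raising; degenerate assignments (δ′Mδ = 0) raise in estimation and are
  skipped in tests/replications.
- Reproducibility: every stochastic routine takes a seed or Generator;
  replicate streams derive from a single generator per run.

## Known limitations

- Two arms only after pooling; continuous endpoints only.
- The exact engine requires a finite, reasonably small state space;
  enumeration is capped (default n = 20) and the DP falls back to Monte
  Carlo guidance above the state cap.
- Eq-type variance results are first-order approximations; for very small n
  the floor at zero and the conditional-bin widening are blunt instruments.
- The sequential arm-combining fixture is a reconstruction of an
  incompletely specified method; outputs involving it are labeled as such.
- Treatment-effect heterogeneity is out of scope beyond the observation
  that τ̂ then targets the average effect with nearly constant diag(VM).
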