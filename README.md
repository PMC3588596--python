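# randinf

Randomization-model inference for two-arm clinical trials.

In the randomization model, the patients, their order of entry, their
covariates and their unit effects are all fixed; the only source of
randomness is the treatment-assignment mechanism actually used in the trial.
`randinf` implements that mechanism-aware analysis for arbitrary sequential
randomization rules — permuted blocks, biased coins, marginal-balance
minimization, urn designs, Pocock–Simon minimization, and unequal allocation
by combining the arms of a symmetric multi-arm randomization — and is aimed
at trial statisticians who need to check, before unblinding, whether the
planned analysis is valid under the randomization actually performed.

## The model

With assignment indicators δ ∈ {0,1}ⁿ (1 = experimental), unit-treatment
additivity states y = y₀ + δτ for fixed unit effects y₀ and a scalar
treatment effect τ. After adjustment for a covariate matrix **X** (with
residual-maker **M** = **I** − **X**(**X**′**X**)⁻¹**X**′), the
normal-equations estimator is

    τ̂ = δ′My / δ′Mδ.

Provided the *constant-probability condition* Eδ = p·**1** holds (p is the
planned allocation fraction, e.g. 2/3 for 2:1 allocation), τ̂ is
approximately unbiased with randomization variance

    Var(τ̂) ≈ y₀′MVMy₀ / (tr MV)²,     V = Var(δ),

estimated from the data by

    v̂ = (y′MVMy − τ̂²·tr(MVMV)) / (tr MV)².

The package computes **V** and the marginal probabilities Eδ exactly —
by dynamic programming over each design's state abstraction and by full
enumeration for small n — or by Monte-Carlo rerandomization, supports
inference conditional on the ancillary statistic δ′Mδ, runs Monte-Carlo
randomization tests, and diagnoses (and repairs, by augmenting **X** with
the probability vector **p**) violations of Eδ = p·**1**, which are common
among dynamic randomization rules for unbalanced allocation.

## Worked example

A 38-patient 2:1 trial with two binary stratification factors (cell counts
10, 8, 11, 9), randomized by stratified permuted blocks of six, analyzed
with intercept + the two stratum main effects:

```python
import numpy as np
import randinf as ri

fx = ri.make_study38(seed=0)                       # fixture: strata + designs
delta = ri.assign_sequence(fx.pbr, fx.frame.strata, rng=42)
y = np.random.default_rng(7).standard_normal(38) + 1.0 * delta  # true tau = 1
frame = fx.frame.with_assignment(delta).with_response(y)

model = ri.RandomizationModel.from_trialframe(frame, fx.pbr, xspec=fx.xspec)
res = model.fit(method="mc", reps=100_000, seed=1)
print(res.summary())
```

```
Randomization-model inference
==============================================
n patients                      38
design                permuted_blocks
allocation            2:1
moments source         monte_carlo (100000 reps)
ancillary delta'Mdelta      7.7206
----------------------------------------------
tau_hat                    1.23571
randomization var        0.0704775
linear-model var          0.095795
z                           4.6547
two-sided p              3.245e-06
95% CI          [0.715383, 1.75603]
E(delta)=p flag              False
==============================================
```

`tau_hat` is the covariate-adjusted effect estimate (true value 1.0 here);
`randomization var` is v̂ above, computed against the rerandomization
distribution of this specific design; `linear-model var` is the usual OLS
variance for comparison (larger here, as expected when blocking in time is
ignored); the flag at the bottom reports whether the design violates
Eδ = p·**1** (stratified permuted blocks do not). A Monte-Carlo
randomization test of the sharp null is one call:

```python
proj = ri.build_projection(fx.xspec, fx.frame)
rt = ri.randomization_test(y, delta, fx.pbr, proj, strata=fx.frame.strata,
                           reps=100_000, rng=2)
print(rt.p_two_sided)        # 0.00012
```

Exact marginal assignment probabilities expose defective 2:1 dynamic rules
(the biased coin's probabilities oscillate instead of staying at 2/3):

```python
ri.marginal_probs(ri.make_biased_coin_2to1(), 5).round(3)
# array([0.667, 0.744, 0.467, 0.674, 0.761])
```

A thin CLI mirrors the library: `randinf probs|moments|assign|infer|randtest|study`
(see `randinf --help`); design and model configurations are small YAML files.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the package's headline quantities: the exact
dynamic-programming probability sequences and limits for the four dynamic
2:1 rules (biased coin, marginal balance, and the incorrect/corrected urn
generalizations), the conditional-moment worked example for 2:1 permuted
blocks of six at ten patients, and the Monte-Carlo distribution of the
ancillary statistic δ′Mδ for the 38-patient stratified fixture (its mean and
the mass in [7.7, 8.9]). Output is a JSON map of target ids to values.

See `docs/methods.md` for the statistical background, numerical choices and
limitations.
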