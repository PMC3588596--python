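"""Tests for the randomization-model estimator, variances and diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest

from randinf import (AllocationSpec, DesignMatrixSpec, RandomizationModel,
                     ancillary, augment_repair, build_projection,
                     conditional_bias, conditional_moments, conditional_var_hat,
                     enumerate_full, exact_moments, make_biased_coin_2to1,
                     make_complete, make_efron_coin_1to1,
                     make_marginal_balance_2to1, make_permuted_blocks,
                     make_pocock_simon_1to1, make_urn_2to1, sample_assignments,
                     tau_hat, unconditional_bias, var_approx, var_hat, z_test)
from randinf.trial import TrialFrame


def intercept_proj(n):
    return build_projection(DesignMatrixSpec.intercept_only(), n=n)


def enum_expected_tau(design, y0, tau, proj, n, strata=None):
    """Exact E(τ̂) by enumeration, skipping degenerate assignments."""
    tot, acc = 0.0, 0.0
    for s, p in enumerate_full(design, n, strata):
        d = np.array(s, dtype=float)
        if ancillary(proj.M, d) < 1e-9:
            continue
        tot += p
        acc += p * tau_hat(y0 + tau * d, d, proj.M)
    return acc / tot


class TestTauHat:
    def test_recovers_tau_with_null_unit_effects(self):
        proj = intercept_proj(8)
        delta = np.array([1, 0, 1, 1, 0, 1, 0, 0], dtype=float)
        assert tau_hat(2.5 * delta, delta, proj.M) == pytest.approx(2.5)

    def test_intercept_only_is_difference_of_means(self, rng):
        n = 11
        proj = intercept_proj(n)
        y = rng.standard_normal(n)
        delta = np.array([1] * 4 + [0] * 7, dtype=float)
        expected = y[delta == 1].mean() - y[delta == 0].mean()
        assert tau_hat(y, delta, proj.M) == pytest.approx(expected, abs=1e-12)

    def test_equals_ols_treatment_coefficient(self, rng):
        """τ̂ is the coefficient of δ in the least-squares fit on [X, δ]."""
        import statsmodels.api as sm
        n = 20
        df = pd.DataFrame({"x": rng.standard_normal(n),
                           "g": rng.integers(0, 2, n)})
        spec = DesignMatrixSpec(["intercept", ("factor", "g"), ("covariate", "x")])
        proj = build_projection(spec, df)
        y = rng.standard_normal(n)
        delta = rng.integers(0, 2, n).astype(float)
        fit = sm.OLS(y, np.column_stack([proj.X, delta])).fit()
        assert tau_hat(y, delta, proj.M) == pytest.approx(fit.params[-1], abs=1e-10)

    def test_degenerate_assignment_errors(self):
        proj = intercept_proj(5)
        with pytest.raises(ZeroDivisionError):
            tau_hat(np.zeros(5), np.ones(5), proj.M)

    @pytest.mark.parametrize("factory", [
        lambda: make_permuted_blocks(AllocationSpec(1, 1), 2),
        lambda: make_efron_coin_1to1(),
        lambda: make_pocock_simon_1to1(n_factors=1),
    ])
    def test_exact_unbiasedness_symmetric_1to1(self, factory, rng):
        """Symmetrical 1:1 rules give exactly unbiased τ̂ for any fixed y₀."""
        n, tau = 6, 1.3
        proj = intercept_proj(n)
        y0 = rng.standard_normal(n)
        et = enum_expected_tau(factory(), y0, tau, proj, n)
        assert et == pytest.approx(tau, abs=1e-10)


class TestVarApprox:
    def test_zero_when_y0_in_column_space(self, rng):
        n = 10
        proj = intercept_proj(n)
        V = 0.25 * np.eye(n)
        assert var_approx(np.full(n, 3.7), proj.M, V) == pytest.approx(0.0, abs=1e-20)

    def test_quadratic_scaling(self, rng):
        n = 10
        proj = intercept_proj(n)
        V = 0.25 * np.eye(n)
        y0 = rng.standard_normal(n)
        assert var_approx(3 * y0, proj.M, V) == pytest.approx(
            9 * var_approx(y0, proj.M, V))

    def test_invariant_to_covariate_shift(self, rng):
        n = 12
        df = pd.DataFrame({"x": rng.standard_normal(n)})
        spec = DesignMatrixSpec(["intercept", ("covariate", "x")])
        proj = build_projection(spec, df)
        V = exact_moments(make_efron_coin_1to1(), n).V
        y0 = rng.standard_normal(n)
        b = rng.standard_normal(2)
        shifted = y0 + proj.X @ b
        assert var_approx(shifted, proj.M, V) == pytest.approx(
            var_approx(y0, proj.M, V), abs=1e-10)

    def test_equals_variance_of_linearized_statistic(self, rng):
        """Enumeration: Var(δ′My₀)/(tr MV)² is exactly the approximation."""
        n = 4
        proj = intercept_proj(n)
        d = make_complete(AllocationSpec(1, 1))
        mom = exact_moments(d, n)
        y0 = np.array([0.0, 0.0, 1.0, 1.0])
        t = np.trace(proj.M @ mom.V)
        stats = []
        for s, p in enumerate_full(d, n):
            stats.append((float(np.array(s) @ proj.M @ y0) / t, p))
        mean = sum(v * p for v, p in stats)
        var = sum(p * (v - mean) ** 2 for v, p in stats)
        assert var_approx(y0, proj.M, mom.V) == pytest.approx(var, abs=1e-12)


class TestVarHat:
    def test_reduces_to_null_variance_form_at_zero_tau_hat(self, rng):
        """With τ̂ = 0 the estimator equals the null-distribution variance."""
        n = 8
        proj = intercept_proj(n)
        V = exact_moments(make_permuted_blocks(AllocationSpec(1, 1), 2), n).V
        delta = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
        y = rng.standard_normal(n)
        y = y - proj.M @ y @ delta / (delta @ proj.M @ delta) * delta  # force τ̂ = 0
        assert tau_hat(y, delta, proj.M) == pytest.approx(0.0, abs=1e-10)
        My = proj.M @ y
        eq6 = float(My @ V @ My) / np.trace(proj.M @ V) ** 2
        assert var_hat(y, delta, proj.M, V) == pytest.approx(eq6, abs=1e-12)

    def test_negative_estimate_floored_with_warning(self):
        # one lone experimental patient: δ′Mδ = 4/5 < tr(MVMV)/p(1−p) = 1,
        # so a perfectly separated response drives the subtraction negative
        n = 5
        proj = intercept_proj(n)
        V = 0.25 * np.eye(n)
        delta = np.array([1, 0, 0, 0, 0], dtype=float)
        y = 10.0 * delta
        with pytest.warns(RuntimeWarning, match="floored"):
            assert var_hat(y, delta, proj.M, V) == 0.0

    def test_approximately_unbiased_complete_1to1(self, rng):
        """Mean of the estimator tracks the rerandomization Var(τ̂) at n=40."""
        n, tau, reps = 40, 0.5, 30_000
        proj = intercept_proj(n)
        d = make_complete(AllocationSpec(1, 1))
        V = 0.25 * np.eye(n)
        y0 = rng.standard_normal(n)
        D = sample_assignments(d, n=n, reps=reps, rng=101).astype(float)
        DM = D @ proj.M
        anc = np.einsum("ri,ri->r", DM, D)
        Y = y0[None, :] + tau * D
        taus = np.einsum("ri,ri->r", DM, Y) / anc
        MY = Y @ proj.M
        q = np.einsum("ri,ij,rj->r", MY, V, MY)
        t = np.trace(proj.M @ V)
        t2 = np.trace(proj.M @ V @ proj.M @ V)
        vh = (q - taus ** 2 * t2) / t ** 2
        assert vh.mean() == pytest.approx(taus.var(), rel=0.07)


class TestConditionalVarHat:
    def test_exactly_conditionally_unbiased_symmetric_1to1(self, rng):
        """Within each ancillary bin the estimator's mean is Var(τ̂ | bin)."""
        n, tau = 8, 0.8
        d = make_permuted_blocks(AllocationSpec(1, 1), 4)
        proj = intercept_proj(n)
        cm = conditional_moments(d, n, proj.M, mode="exact")
        y0 = rng.standard_normal(n)
        by_bin = {}
        for s, p in enumerate_full(d, n):
            s = np.array(s, dtype=float)
            c = round(ancillary(proj.M, s), 6)
            by_bin.setdefault(c, []).append((s, p))
        for c, items in by_bin.items():
            mass = sum(p for _, p in items)
            taus = [(tau_hat(y0 + tau * s, s, proj.M), p / mass) for s, p in items]
            m = sum(t * w for t, w in taus)
            v = sum(w * (t - m) ** 2 for t, w in taus)
            est = sum((p / mass) * conditional_var_hat(y0 + tau * s, s, proj.M, cm)
                      for s, p in items)
            assert est == pytest.approx(v, abs=1e-10)

    def test_vacuous_conditioning_relation(self, rng):
        """Single-bin design: conditional and unconditional estimators differ
        only by the exact factor t²/(t² − tr(MVMV))."""
        n = 12
        d = make_permuted_blocks(AllocationSpec(2, 1), 6)
        proj = intercept_proj(n)
        cm = conditional_moments(d, n, proj.M, mode="exact")
        assert len(cm.bins) == 1  # full blocks, intercept-only: one ancillary value
        mom = exact_moments(d, n)
        y = rng.standard_normal(n)
        delta = None
        for s, p in enumerate_full(d, n):
            delta = np.array(s, dtype=float)
            break
        vc = conditional_var_hat(y, delta, proj.M, cm)
        vu = var_hat(y, delta, proj.M, mom.V)
        MV = proj.M @ mom.V
        t, t2 = np.trace(MV), np.trace(MV @ MV)
        assert vc == pytest.approx(vu * t ** 2 / (t ** 2 - t2), rel=1e-8)


class TestBiasDiagnostics:
    def test_conditional_bias_zero_for_constant_p(self, rng):
        n = 10
        proj = intercept_proj(n)
        V = 0.2 * np.eye(n)
        assert conditional_bias(np.full(n, 2 / 3), rng.standard_normal(n),
                                proj.M, V) == pytest.approx(0.0, abs=1e-12)

    def test_conditional_bias_positive_for_trend_in_forced_bin(self, alloc21):
        """Late patients forced to experimental + increasing y₀ ⇒ positive bias."""
        n = 10
        proj = intercept_proj(n)
        cm = conditional_moments(make_permuted_blocks(alloc21, 6), n, proj.M,
                                 mode="exact")
        k = cm.bin_of(1.6)
        y0 = np.arange(n, dtype=float)
        b = conditional_bias(cm.p_c[k], y0, proj.M, cm.V_c[k])
        assert b > 0.1

    def test_unconditional_bias_zero_for_constant_p(self, rng):
        n = 9
        proj = intercept_proj(n)
        V = 0.25 * np.eye(n)
        assert unconditional_bias(np.full(n, 0.5), rng.standard_normal(n),
                                  proj.M, V) == pytest.approx(0.0, abs=1e-12)

    def test_biased_coin_first_order_bias_matches_enumeration(self):
        """First-order bias has the sign and magnitude of the exact bias."""
        n = 16
        proj = intercept_proj(n)
        y0 = np.arange(n, dtype=float)
        d = make_biased_coin_2to1()
        mom = exact_moments(d, n)
        exact_bias = enum_expected_tau(d, y0, 0.0, proj, n)
        approx = unconditional_bias(mom.mean, y0, proj.M, mom.V)
        assert exact_bias != 0.0
        assert np.sign(approx) == np.sign(exact_bias)
        assert abs(approx - exact_bias) < 0.5 * abs(exact_bias)

    def test_marginal_balance_bias_exceeds_biased_coin(self):
        """The oscillating marginal-balance p vector produces the larger bias."""
        n = 12
        proj = intercept_proj(n)
        y0 = np.arange(n, dtype=float)
        bias = {}
        for name, d in (("bc", make_biased_coin_2to1()),
                        ("mb", make_marginal_balance_2to1())):
            bias[name] = enum_expected_tau(d, y0, 0.0, proj, n)
        assert abs(bias["mb"]) > abs(bias["bc"])


class TestAugmentRepair:
    def test_constant_p_is_noop(self):
        spec = DesignMatrixSpec.intercept_only()
        with pytest.warns(RuntimeWarning, match="collinear"):
            out = augment_repair(spec, np.full(8, 2 / 3))
        assert out is spec

    def test_repair_reduces_bias_for_biased_coin(self):
        n = 16
        y0 = np.arange(n, dtype=float)
        d = make_biased_coin_2to1()
        mom = exact_moments(d, n)
        proj0 = intercept_proj(n)
        spec1 = augment_repair(DesignMatrixSpec.intercept_only(), mom.mean)
        proj1 = build_projection(spec1, n=n)
        b0 = enum_expected_tau(d, y0, 0.0, proj0, n)
        b1 = enum_expected_tau(d, y0, 0.0, proj1, n)
        assert abs(b1) < abs(b0)


class TestZTest:
    def test_null_value_gives_zero_statistic(self):
        z, p, ci = z_test(1.5, 0.4, tau0=1.5)
        assert z == 0.0 and p == pytest.approx(1.0)
        assert ci[0] < 1.5 < ci[1]

    def test_zero_variance_errors(self):
        with pytest.raises(ZeroDivisionError):
            z_test(1.0, 0.0)

    def test_interval_width_matches_normal_quantile(self):
        z, p, ci = z_test(0.0, 1.0, alpha=0.05)
        assert ci[1] == pytest.approx(1.959963984540054, abs=1e-9)


class TestModelAPI:
    def _trial(self, rng, n=12):
        d = make_permuted_blocks(AllocationSpec(2, 1), 6)
        delta = sample_assignments(d, n=n, reps=1, rng=rng)[0]
        y = rng.standard_normal(n) + 1.0 * delta
        df = pd.DataFrame({"patient_order": np.arange(1, n + 1),
                           "y": y, "delta": delta})
        return TrialFrame(df), d

    def test_fit_summary_and_dict(self, rng):
        frame, design = self._trial(rng)
        model = RandomizationModel.from_trialframe(frame, design)
        res = model.fit(method="exact")
        assert res.moments.source == "exact"
        assert res.ci[0] < res.tau_hat < res.ci[1]
        assert not res.bias_flag  # permuted blocks satisfy Eδ = (2/3)·1
        s = res.summary()
        for token in ("tau_hat", "randomization var", "z", "CI"):
            assert token in s
        d = res.to_dict()
        assert d["n"] == 12 and np.isfinite(d["var_rand"])

    def test_bias_flag_raised_for_biased_coin(self, rng):
        n = 10
        design = make_biased_coin_2to1()
        delta = sample_assignments(design, n=n, reps=1, rng=rng)[0]
        y = rng.standard_normal(n)
        model = RandomizationModel(y, delta, design)
        res = model.fit(method="exact")
        assert res.bias_flag

    def test_exact_and_mc_fits_agree(self, rng):
        frame, design = self._trial(rng)
        model = RandomizationModel.from_trialframe(frame, design)
        r1 = model.fit(method="exact")
        r2 = model.fit(method="mc", reps=50_000, seed=3)
        assert r1.tau_hat == r2.tau_hat
        assert r2.var_rand == pytest.approx(r1.var_rand, rel=0.1)

    def test_conditional_fit(self, rng):
        frame, design = self._trial(rng)
        model = RandomizationModel.from_trialframe(frame, design)
        res = model.fit(method="exact", conditional=True)
        assert res.var_rand_conditional is not None
        assert res.var_rand_conditional >= 0
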