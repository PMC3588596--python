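"""Randomization-model estimation of a treatment effect.

Under unit-treatment additivity the observations are y = y₀ + δτ with fixed
unit effects y₀ and assignment vector δ drawn by the trial's randomization
rule.  After adjustment for a covariate matrix X with residual-maker M, the
normal-equations estimator of τ is

    τ̂ = δ′My / δ′Mδ.

When the constant-probability condition Eδ = p·1 holds, τ̂ is approximately
unbiased (exactly unbiased for symmetrical 1:1 rules) with approximate
randomization variance

    Var(τ̂) ≈ y₀′MVMy₀ / (tr MV)²,          V = Var(δ),

estimated from the data (y₀ is unobservable) by

    v̂ = (y′MVMy − τ̂²·tr(MVMV)) / (tr MV)².

Conditional analogues replace V by the conditional covariance V_c of δ
given the bin of the ancillary δ′Mδ; the conditionally unbiased variance
estimator divides by (tr MV_c)² − tr(MV_cMV_c) instead (see the methods
note for the derivation).  When Eδ = p ≠ p·1 the estimator acquires a
first-order bias p′My₀ / tr(MV), repaired by augmenting X with p.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import engine
from .designs import RandomizationDesign
from .engine import AssignmentMoments, ConditionalMoments, EnumerationCapError
from .projection import DesignMatrixSpec, Projection, ancillary, build_projection
from .trial import TrialFrame

__all__ = [
    "tau_hat", "var_approx", "var_hat", "conditional_var_hat",
    "conditional_bias", "unconditional_bias", "augment_repair", "z_test",
    "RandomizationModel", "RandomizationResults",
]


def _M(M) -> np.ndarray:
    return M.M if isinstance(M, Projection) else np.asarray(M)


def tau_hat(y: np.ndarray, delta: np.ndarray, M) -> float:
    """Adjusted treatment-effect estimator τ̂ = δ′My / δ′Mδ.

    Identical to the coefficient of δ in the least-squares fit of y on
    [X, δ].
    """
    M = _M(M)
    d = np.asarray(delta, dtype=float)
    denom = d @ M @ d
    if denom <= 1e-12:
        raise ZeroDivisionError("degenerate assignment: δ′Mδ = 0")
    return float(d @ M @ np.asarray(y, float)) / denom


def var_approx(y0: np.ndarray, M, V: np.ndarray | AssignmentMoments) -> float:
    """Approximate randomization variance of τ̂: y₀′MVMy₀ / (tr MV)².

    A function of the residuals of the unit effects after regression on X;
    invariant under y₀ → y₀ + Xb.
    """
    M = _M(M)
    V = V.V if isinstance(V, AssignmentMoments) else np.asarray(V)
    t = float(np.trace(M @ V))
    if t <= 0:
        raise ValueError("tr(MV) must be positive")
    r = M @ np.asarray(y0, float)
    return float(r @ V @ r) / t ** 2


def var_hat(y: np.ndarray, delta: np.ndarray, M,
            V: np.ndarray | AssignmentMoments) -> float:
    """Approximately unbiased estimator of the randomization variance of τ̂.

    v̂ = (y′MVMy − τ̂²·tr(MVMV)) / (tr MV)².  Negative values (a small-sample
    artifact of the subtraction) are floored at zero with a warning.
    """
    M = _M(M)
    V = V.V if isinstance(V, AssignmentMoments) else np.asarray(V)
    th = tau_hat(y, delta, M)
    MV = M @ V
    t = float(np.trace(MV))
    if t <= 0:
        raise ValueError("tr(MV) must be positive")
    r = M @ np.asarray(y, float)
    val = (float(r @ V @ r) - th ** 2 * float(np.trace(MV @ MV))) / t ** 2
    if val < 0:
        warnings.warn("negative variance estimate floored at 0", RuntimeWarning)
        return 0.0
    return val


def conditional_var_hat(y: np.ndarray, delta: np.ndarray, M,
                        cond: ConditionalMoments) -> float:
    """Conditionally unbiased variance estimator given the observed δ′Mδ bin.

    Uses the conditional covariance V_c of the bin containing the realized
    ancillary value:

        v̂_c = (y′MV_cMy − τ̂²·tr(MV_cMV_c)) / ((tr MV_c)² − tr(MV_cMV_c)).

    For symmetrical 1:1 designs this is exactly conditionally unbiased for
    the conditional variance of τ̂.
    """
    M = _M(M)
    a = ancillary(M, delta)
    k = cond.bin_of(a)
    if abs(cond.bins[k] - a) > cond.bin_width:
        warnings.warn(
            f"observed ancillary {a:.3g} far from nearest populated bin "
            f"{cond.bins[k]:.3g}; widening", RuntimeWarning)
    V_c = cond.V_c[k]
    th = tau_hat(y, delta, M)
    MV = M @ V_c
    t = float(np.trace(MV))
    t2 = float(np.trace(MV @ MV))
    denom = t ** 2 - t2
    if denom <= 0:
        raise ValueError("degenerate conditional moments: (tr MV_c)² ≤ tr(MV_cMV_c)")
    r = M @ np.asarray(y, float)
    val = (float(r @ V_c @ r) - th ** 2 * t2) / denom
    if val < 0:
        warnings.warn("negative conditional variance estimate floored at 0",
                      RuntimeWarning)
        return 0.0
    return val


def conditional_bias(p_c: np.ndarray, y0: np.ndarray, M,
                     V_c: np.ndarray | None = None,
                     normalized: bool = False) -> float:
    """First-order conditional bias of τ̂ given a δ′Mδ bin.

    The bias is proportional to the covariance between the conditional
    assignment probabilities p_c and the unit-effect residuals My₀:
    bias ≈ p_c′My₀ / tr(MV_c).  With ``normalized=True`` the bias is divided
    by the conditional standard deviation of τ̂, giving the dimensionless
    relative bias p_c′My₀ / sqrt(y₀′MV_cMy₀).
    """
    M = _M(M)
    r = M @ np.asarray(y0, float)
    num = float(np.asarray(p_c, float) @ r)
    if normalized:
        if V_c is None:
            raise ValueError("normalized bias needs V_c")
        s2 = float(r @ np.asarray(V_c) @ r)
        return num / math.sqrt(s2) if s2 > 0 else 0.0
    if V_c is None:
        raise ValueError("unnormalized bias needs V_c for tr(MV_c)")
    t = float(np.trace(M @ np.asarray(V_c)))
    return num / t


def unconditional_bias(p_vec: np.ndarray, y0: np.ndarray, M,
                       V: np.ndarray | AssignmentMoments) -> float:
    """First-order bias of τ̂ when Eδ = p ≠ p·1: p′My₀ / tr(MV).

    Zero whenever the marginal assignment probabilities are constant,
    because M annihilates constant vectors.
    """
    M = _M(M)
    V = V.V if isinstance(V, AssignmentMoments) else np.asarray(V)
    t = float(np.trace(M @ V))
    return float(np.asarray(p_vec, float) @ M @ np.asarray(y0, float)) / t


def augment_repair(spec: DesignMatrixSpec, p_vec: np.ndarray,
                   data=None, tol: float = 1e-8) -> DesignMatrixSpec:
    """Append the marginal-probability vector p to X to remove the bias.

    If p already lies in the column space of X (e.g. it is constant), the
    spec is returned unchanged with a warning.
    """
    from .projection import build_projection  # local: avoid confusion with arg names
    p_vec = np.asarray(p_vec, dtype=float)
    proj = build_projection(spec, data, n=p_vec.shape[0])
    resid = proj.M @ p_vec
    if float(resid @ resid) <= tol * max(float(p_vec @ p_vec), 1.0):
        warnings.warn("probability vector is collinear with X; no augmentation",
                      RuntimeWarning)
        return spec
    return spec.augmented("assign_prob", p_vec)


def z_test(tau: float, var: float, tau0: float = 0.0,
           alpha: float = 0.05) -> tuple[float, float, tuple[float, float]]:
    """Normal-approximation test and confidence interval for τ.

    Returns (z, two-sided p, (lo, hi)) with z = (τ̂ − τ₀)/sqrt(var).
    """
    if var <= 0:
        raise ZeroDivisionError("variance estimate must be positive")
    se = math.sqrt(var)
    z = (tau - tau0) / se
    p = 2.0 * stats.norm.sf(abs(z))
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    return z, p, (tau - zq * se, tau + zq * se)


# ---------------------------------------------------------------------------
# model / results objects


class RandomizationModel:
    """Randomization-model analysis of a two-arm trial.

    Parameters
    ----------
    y : array
        Observed responses, one per patient in randomization order.
    delta : array of {0,1}
        Realized treatment assignments (1 = experimental).
    design : RandomizationDesign
        The randomization rule actually used; its rerandomization
        distribution supplies Var(δ).
    strata : sequence, optional
        Per-patient stratum labels consumed by the design.
    xspec : DesignMatrixSpec, optional
        Adjustment covariates (default intercept only).
    data : TrialFrame or DataFrame, optional
        Table the covariate terms refer to.
    """

    def __init__(self, y, delta, design: RandomizationDesign,
                 strata: Sequence[Hashable] | None = None,
                 xspec: DesignMatrixSpec | None = None,
                 data: TrialFrame | pd.DataFrame | None = None):
        self.y = np.asarray(y, dtype=float)
        self.delta = np.asarray(delta)
        self.design = design
        self.nobs = self.y.shape[0]
        self.strata = list(strata) if strata is not None else [""] * self.nobs
        self.xspec = xspec or DesignMatrixSpec.intercept_only()
        self.data = data
        if self.delta.shape[0] != self.nobs or len(self.strata) != self.nobs:
            raise ValueError("y, delta and strata must have one entry per patient")

    @classmethod
    def from_trialframe(cls, frame: TrialFrame, design: RandomizationDesign,
                        xspec: DesignMatrixSpec | None = None) -> "RandomizationModel":
        return cls(frame.y, frame.delta, design, strata=frame.strata,
                   xspec=xspec, data=frame)

    def fit(self, method: str = "auto", reps: int = 100_000,
            seed: int | None = None, conditional: bool = False,
            bin_width: float = 0.2, tau0: float = 0.0,
            alpha: float = 0.05, enum_cap: int = 16) -> "RandomizationResults":
        """Estimate τ and its randomization variance.

        ``method`` selects how the moments of δ are computed: ``"exact"``
        (full enumeration), ``"mc"`` (Monte-Carlo rerandomization with
        ``reps`` replicates) or ``"auto"`` (exact when n ≤ ``enum_cap``).
        """
        proj = build_projection(self.xspec, self.data, n=self.nobs)
        if method == "auto":
            method = "exact" if self.nobs <= enum_cap else "mc"
        if method == "exact":
            moments = engine.exact_moments(self.design, self.nobs, self.strata,
                                           cap=max(enum_cap, self.nobs))
        elif method == "mc":
            moments = engine.montecarlo_moments(self.design, self.nobs,
                                                self.strata, reps=reps, rng=seed)
        else:
            raise ValueError(f"unknown method {method!r}")

        th = tau_hat(self.y, self.delta, proj)
        v_rand = var_hat(self.y, self.delta, proj, moments)
        v_lm = _lm_var(self.y, self.delta, proj)

        # diagnostics on the constant-probability condition Eδ = p·1
        p_target = self.design.alloc.p
        p_vec = moments.mean
        if moments.source == "exact":
            bias_flag = bool(np.max(np.abs(p_vec - p_target)) > 0.005)
        else:
            se = np.sqrt(np.maximum(p_vec * (1 - p_vec), 1e-12) / moments.reps)
            bias_flag = bool(np.any(np.abs(p_vec - p_target) > 3 * se + 0.005))

        v_cond = None
        cond_used = None
        if conditional:
            mode = "exact" if moments.source == "exact" else "monte_carlo"
            cond = engine.conditional_moments(
                self.design, self.nobs, proj.M, self.strata,
                bin_width=bin_width, mode=mode, reps=reps,
                rng=None if seed is None else seed + 1,
                cap=max(enum_cap, self.nobs))
            v_cond = conditional_var_hat(self.y, self.delta, proj, cond)
            cond_used = cond.bins[cond.bin_of(proj.ancillary(self.delta))]

        v_use = v_cond if (conditional and v_cond and v_cond > 0) else v_rand
        if v_use > 0:
            z, p, ci = z_test(th, v_use, tau0=tau0, alpha=alpha)
        else:
            z, p, ci = np.nan, np.nan, (np.nan, np.nan)
        return RandomizationResults(
            model=self, projection=proj, moments=moments,
            tau_hat=th, var_rand=v_rand, var_rand_conditional=v_cond,
            var_lm=v_lm, zstat=z, pvalue=p, ci=ci, alpha=alpha, tau0=tau0,
            bias_flag=bias_flag, p_vector=p_vec,
            ancillary=proj.ancillary(self.delta), conditional_bin=cond_used,
        )


def _lm_var(y, delta, proj: Projection) -> float:
    # population-model OLS variance of the treatment coefficient (see lm_compare)
    M, q = proj.M, proj.q
    d = np.asarray(delta, float)
    a = d @ M @ d
    if a <= 1e-12:
        return np.nan
    th = (d @ M @ y) / a
    rss = float(y @ M @ y) - th ** 2 * a
    dof = len(y) - q - 1
    if dof <= 0:
        return np.nan
    return rss / dof / a


@dataclass
class RandomizationResults:
    """Estimates, uncertainties and diagnostics from a randomization fit."""

    model: RandomizationModel
    projection: Projection
    moments: AssignmentMoments
    tau_hat: float
    var_rand: float
    var_lm: float
    zstat: float
    pvalue: float
    ci: tuple[float, float]
    alpha: float
    tau0: float
    bias_flag: bool
    p_vector: np.ndarray
    ancillary: float
    var_rand_conditional: float | None = None
    conditional_bin: float | None = None

    @property
    def bse(self) -> float:
        v = self.var_rand_conditional if self.var_rand_conditional else self.var_rand
        return math.sqrt(v) if v and v > 0 else np.nan

    def conf_int(self, alpha: float | None = None) -> tuple[float, float]:
        if alpha is None or alpha == self.alpha:
            return self.ci
        _, _, ci = z_test(self.tau_hat, self.bse ** 2, tau0=self.tau0, alpha=alpha)
        return ci

    def summary(self) -> str:
        lines = [
            "Randomization-model inference",
            "=" * 46,
            f"n patients            {self.model.nobs:>12d}",
            f"design                {self.model.design.name:>12s}",
            f"allocation            {self.model.design.alloc.r1}:{self.model.design.alloc.r2}".rjust(0),
            f"moments source        {self.moments.source:>12s}"
            + (f" ({self.moments.reps} reps)" if self.moments.reps else ""),
            f"ancillary delta'Mdelta{self.ancillary:>12.4f}",
            "-" * 46,
            f"tau_hat               {self.tau_hat:>12.6g}",
            f"randomization var     {self.var_rand:>12.6g}",
        ]
        if self.var_rand_conditional is not None:
            lines.append(f"conditional var       {self.var_rand_conditional:>12.6g}"
                         f"  (bin {self.conditional_bin:g})")
        lines += [
            f"linear-model var      {self.var_lm:>12.6g}",
            f"z                     {self.zstat:>12.4f}",
            f"two-sided p           {self.pvalue:>12.4g}",
            f"{100 * (1 - self.alpha):.0f}% CI          [{self.ci[0]:.6g}, {self.ci[1]:.6g}]",
            f"E(delta)=p flag       {str(self.bias_flag):>12s}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.model.nobs,
            "design": self.model.design.name,
            "tau_hat": self.tau_hat,
            "var_rand": self.var_rand,
            "var_rand_conditional": self.var_rand_conditional,
            "var_lm": self.var_lm,
            "z": self.zstat,
            "pvalue": self.pvalue,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "ancillary": self.ancillary,
            "bias_flag": self.bias_flag,
        }
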