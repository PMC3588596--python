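"""Synthetic trials, unit-effect generators, and scripted study drivers.

The reference fixture is a 38-patient trial with 2:1 allocation and two
binary stratification factors whose four cells hold 10, 8, 11 and 9
patients; entry order is drawn once from a seeded generator and then held
fixed.  Two randomization methods target it: stratified permuted blocks of
six, and a sequential rule that randomizes 1:1:1 to three arms (stratified
permuted blocks of three) and combines the first two arms into the
experimental group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import engine
from .designs import (AllocationSpec, RandomizationDesign, make_biased_coin_2to1,
                      make_complete, make_efron_coin_1to1,
                      make_marginal_balance_2to1, make_multiarm_permuted_blocks,
                      make_permuted_blocks, make_sequential_combine, make_urn_2to1,
                      sample_assignments)
from .inference import conditional_bias, var_approx, var_hat
from .lm_compare import UnitEffectPattern, lm_var_expectation, lm_var_hat
from .projection import DesignMatrixSpec, build_projection
from .trial import TrialFrame

__all__ = ["Study38Fixture", "make_study38", "gen_unit_effects", "run_study",
           "STUDY_NAMES"]

STUDY_NAMES = ("unbalanced_probs", "conditional_bias_38", "variance_compare",
               "clt_coverage")

_CELLS = {(0, 0): 10, (0, 1): 8, (1, 0): 11, (1, 1): 9}


@dataclass
class Study38Fixture:
    """The 38-patient, two-factor, 2:1 reference trial."""

    frame: TrialFrame
    xspec: DesignMatrixSpec
    pbr: RandomizationDesign          # stratified permuted blocks of 6
    sequential: RandomizationDesign   # 3-arm blocks of 3, first two arms combined

    @property
    def n(self) -> int:
        return self.frame.n


def make_study38(seed: int = 0) -> Study38Fixture:
    """Build the 38-patient fixture with a seeded, then fixed, entry order."""
    labels = [cell for cell, k in _CELLS.items() for _ in range(k)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    df = pd.DataFrame({
        "patient_order": np.arange(1, len(labels) + 1),
        "stratum1": [a for a, _ in labels],
        "stratum2": [b for _, b in labels],
    })
    frame = TrialFrame(df, stratum_cols=("stratum1", "stratum2"))
    xspec = DesignMatrixSpec(["intercept", ("factor", "stratum1"),
                              ("factor", "stratum2")])
    alloc = AllocationSpec(2, 1)
    pbr = make_permuted_blocks(alloc, block_size=6, stratified=True)
    seq = make_sequential_combine(
        make_multiarm_permuted_blocks(3, block_size=3, stratified=True), alloc)
    return Study38Fixture(frame=frame, xspec=xspec, pbr=pbr, sequential=seq)


def gen_unit_effects(pattern: UnitEffectPattern, n: int,
                     rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Fixed unit effects with a stated systematic/noise variance split.

    The systematic component (trend or sinusoid) is scaled so that it
    carries fraction ``r2`` of the total variance ``sigma2`` in expectation;
    the remainder is i.i.d. normal noise.  For ``kind="iid"`` the vector is
    pure noise with variance ``sigma2``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    i = np.arange(n, dtype=float)
    if pattern.kind == "iid":
        return math_sqrt(pattern.sigma2) * rng.standard_normal(n)
    if pattern.kind == "linear_trend":
        g = i - i.mean()
    elif pattern.kind == "low_frequency":
        cycles = pattern.frequency if pattern.frequency is not None else 0.5
        g = np.sin(2.0 * np.pi * cycles * i / max(n - 1, 1))
        g = g - g.mean()
    else:  # high_frequency
        cycles = pattern.frequency if pattern.frequency is not None else n / 2.0
        g = np.where(i % 2 == 0, 1.0, -1.0) if pattern.frequency is None else \
            np.sin(2.0 * np.pi * cycles * i / max(n - 1, 1))
        g = g - g.mean()
    gvar = float(g @ g) / n
    g = g * np.sqrt(pattern.r2 * pattern.sigma2 / gvar)
    noise_sd = np.sqrt((1.0 - pattern.r2) * pattern.sigma2)
    return g + noise_sd * rng.standard_normal(n)


def math_sqrt(x: float) -> float:
    return float(np.sqrt(x))


# ---------------------------------------------------------------------------
# scripted studies


def _plot(fig, outdir: Path, name: str):
    fig.savefig(outdir / f"{name}.png", dpi=120, bbox_inches="tight")


def _study_unbalanced_probs(outdir: Path, seed: int, full: bool) -> dict:
    """Exact P(δᵢ=1) tables for the four dynamic 2:1 rules, plus limits."""
    designs = {
        "biased_coin": make_biased_coin_2to1(),
        "marginal_balance": make_marginal_balance_2to1(),
        "urn_incorrect": make_urn_2to1(add_on_control=2),
        "urn_fixed": make_urn_2to1(add_on_control=4),
    }
    n = 20
    tab = pd.DataFrame({"patient": np.arange(1, n + 1)})
    limits = {}
    for name, d in designs.items():
        tab[name] = engine.marginal_probs(d, n)
        if name.startswith("urn"):  # the coin rules oscillate without a limit
            limits[name] = engine.limiting_prob(d, horizon=500)
    tab.to_csv(outdir / "unbalanced_probs.csv", index=False)
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    for name in designs:
        ax.plot(tab["patient"], tab[name], marker="o", ms=3, label=name)
    ax.axhline(2 / 3, color="k", lw=0.8, ls="--")
    ax.set_xlabel("patient index")
    ax.set_ylabel("P(experimental)")
    ax.legend(fontsize=8)
    _plot(fig, outdir, "unbalanced_probs")
    plt.close(fig)
    return {"limits": limits, "table": "unbalanced_probs.csv"}


def _study_conditional_bias_38(outdir: Path, seed: int, full: bool) -> dict:
    """Conditional assignment probabilities and relative bias for the fixture."""
    reps = 1_000_000 if full else 200_000
    fx = make_study38(seed=seed)
    proj = build_projection(fx.xspec, fx.frame)
    rows, bias_rows = [], []
    rng = np.random.default_rng(seed)
    y0 = gen_unit_effects(UnitEffectPattern("linear_trend", r2=0.5), fx.n, rng)
    proj1 = build_projection(DesignMatrixSpec.intercept_only(), n=fx.n)
    for name, d in (("stratified_pbr", fx.pbr), ("sequential", fx.sequential)):
        cond = engine.conditional_moments(d, fx.n, proj.M, fx.frame.strata,
                                          mode="monte_carlo", reps=reps,
                                          rng=np.random.default_rng(seed + 1))
        for k, c in enumerate(cond.bins):
            if cond.mass[k] * reps < 500:
                continue
            for i in range(fx.n):
                rows.append({"method": name, "bin": round(float(c), 1),
                             "patient": i + 1, "p_c": cond.p_c[k, i],
                             "mass": cond.mass[k]})
            b = conditional_bias(cond.p_c[k], y0, proj1.M, cond.V_c[k],
                                 normalized=True)
            bias_rows.append({"method": name, "bin": round(float(c), 1),
                              "normalized_bias": b, "mass": cond.mass[k]})
    pd.DataFrame(rows).to_csv(outdir / "conditional_p.csv", index=False)
    bias = pd.DataFrame(bias_rows)
    bias.to_csv(outdir / "conditional_bias.csv", index=False)
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, grp in bias.groupby("method"):
        ax.plot(grp["bin"], grp["normalized_bias"], marker="o", ms=3, label=name)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("ancillary bin c")
    ax.set_ylabel("normalized conditional bias")
    ax.legend(fontsize=8)
    _plot(fig, outdir, "conditional_bias")
    plt.close(fig)
    return {"reps": reps, "tables": ["conditional_p.csv", "conditional_bias.csv"]}


def _study_variance_compare(outdir: Path, seed: int, full: bool) -> dict:
    """Linear-model vs randomization variance under three unit-effect patterns."""
    n = 50
    reps = 100_000 if full else 10_000
    proj = build_projection(DesignMatrixSpec.intercept_only(), n=n)
    designs = {"efron_coin_1to1": make_efron_coin_1to1(),
               "pbr_1to1_b4": make_permuted_blocks(AllocationSpec(1, 1), 4)}
    patterns = {"iid": UnitEffectPattern("iid"),
                "low": UnitEffectPattern("low_frequency", r2=0.5),
                "high": UnitEffectPattern("high_frequency", r2=0.5)}
    rows = []
    ss = np.random.SeedSequence(seed)
    for dname, d in designs.items():
        mom = engine.montecarlo_moments(d, n, reps=reps,
                                        rng=np.random.default_rng(ss.spawn(1)[0]))
        D = sample_assignments(d, n=n, reps=reps,
                               rng=np.random.default_rng(ss.spawn(1)[0])).astype(float)
        for pname, pat in patterns.items():
            y0 = gen_unit_effects(pat, n, np.random.default_rng(ss.spawn(1)[0]))
            eq1 = var_approx(y0, proj.M, mom)
            eq5 = lm_var_expectation(y0, 0.0, proj, mom)
            e2 = np.mean([var_hat(y0, D[r], proj.M, mom.V) for r in range(0, reps, max(reps // 2000, 1))])
            e4 = np.mean([lm_var_hat(y0, D[r], proj) for r in range(0, reps, max(reps // 2000, 1))])
            rows.append({"design": dname, "pattern": pname, "var_eq1": eq1,
                         "mean_var_hat": e2, "mean_lm_var": e4, "lm_expect_eq5": eq5})
    tab = pd.DataFrame(rows)
    tab.to_csv(outdir / "variance_compare.csv", index=False)
    return {"reps": reps, "table": "variance_compare.csv"}


def _study_clt_coverage(outdir: Path, seed: int, full: bool) -> dict:
    """Empirical size/coverage of the normal-approximation test at τ = 0."""
    n = 100
    reps = 100_000 if full else 10_000
    rows = []
    ss = np.random.SeedSequence(seed)
    proj = build_projection(DesignMatrixSpec.intercept_only(), n=n)
    for dname, d in (("complete_1to1", make_complete(AllocationSpec(1, 1))),
                     ("efron_coin_1to1", make_efron_coin_1to1())):
        rng = np.random.default_rng(ss.spawn(1)[0])
        y0 = rng.standard_normal(n)
        mom = engine.montecarlo_moments(d, n, reps=max(reps, 50_000), rng=rng)
        D = sample_assignments(d, n=n, reps=reps, rng=rng).astype(float)
        DM = D @ proj.M
        anc = np.einsum("ri,ri->r", DM, D)
        taus = (DM @ y0) / anc
        My0 = proj.M @ y0
        MV = proj.M @ mom.V
        t = np.trace(MV)
        t2 = np.trace(MV @ MV)
        vhat = (float(My0 @ mom.V @ My0) - taus ** 2 * t2) / t ** 2
        z = taus / np.sqrt(np.maximum(vhat, 1e-300))
        size = float(np.mean(np.abs(z) > 1.959963984540054))
        rows.append({"design": dname, "n": n, "reps": reps,
                     "empirical_size": size, "coverage": 1.0 - size})
    tab = pd.DataFrame(rows)
    tab.to_csv(outdir / "clt_coverage.csv", index=False)
    return {"reps": reps, "table": "clt_coverage.csv"}


_STUDIES = {
    "unbalanced_probs": _study_unbalanced_probs,
    "conditional_bias_38": _study_conditional_bias_38,
    "variance_compare": _study_variance_compare,
    "clt_coverage": _study_clt_coverage,
}


def run_study(name: str, outdir: str | Path = "study_out", seed: int = 0,
              full: bool = False) -> dict:
    """Run a scripted study end-to-end, writing tables, plots and a log.

    ``full=True`` restores publication-scale replicate counts; the default
    counts are scaled down to run in minutes on one CPU.
    """
    if name not in _STUDIES:
        raise ValueError(f"unknown study {name!r}; choose from {STUDY_NAMES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    info = _STUDIES[name](outdir, seed, full)
    log = {"study": name, "seed": seed, "full": full, **info}
    (outdir / f"{name}_log.json").write_text(json.dumps(log, indent=2, default=str))
    return log
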