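"""Exact and Monte-Carlo computation of assignment-vector moments.

The exact routines exploit each design's finite state abstraction: a forward
dynamic program over the state distribution yields the marginal assignment
probabilities P(δᵢ = 1), and a depth-first enumeration of assignment
sequences (pruning zero-probability branches) yields the full distribution
of δ for small n, from which any functional — the covariance matrix V,
moments conditional on the ancillary statistic δ′Mδ — follows.  Monte-Carlo
counterparts cover designs or sample sizes where enumeration is infeasible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

from .designs import RandomizationDesign, _as_strata, sample_assignments

__all__ = [
    "AssignmentMoments",
    "ConditionalMoments",
    "EnumerationCapError",
    "marginal_probs",
    "limiting_prob",
    "enumerate_full",
    "exact_moments",
    "montecarlo_moments",
    "conditional_moments",
]


class EnumerationCapError(RuntimeError):
    """Raised when full enumeration would exceed the configured cap."""


@dataclass
class AssignmentMoments:
    """First two moments of the assignment vector δ."""

    mean: np.ndarray          # Eδ, length n
    V: np.ndarray             # Var(δ), n x n
    source: str               # "exact" | "monte_carlo"
    reps: int | None = None

    @property
    def n(self) -> int:
        return self.mean.shape[0]


@dataclass
class ConditionalMoments:
    """Moments of δ conditional on binned values of the ancillary δ′Mδ.

    ``bins[k]`` is the bin center c (δ′Mδ grouped to the nearest
    ``bin_width``); ``p_c[k]`` = E(δ | bin k), ``V_c[k]`` = Var(δ | bin k),
    ``mass[k]`` = P(bin k).
    """

    bins: np.ndarray
    p_c: np.ndarray           # (n_bins, n)
    V_c: np.ndarray           # (n_bins, n, n)
    mass: np.ndarray
    bin_width: float
    source: str
    reps: int | None = None

    def bin_of(self, ancillary_value: float) -> int:
        """Index of the populated bin nearest to an observed δ′Mδ."""
        return int(np.argmin(np.abs(self.bins - ancillary_value)))


def marginal_probs(design: RandomizationDesign, n: int,
                   strata: Sequence[Hashable] | None = None,
                   state_cap: int = 2_000_000) -> np.ndarray:
    """Exact P(δᵢ = 1) for i = 1..n by forward dynamic programming.

    The distribution over design states is propagated patient by patient;
    the marginal probability for patient i is the state-weighted assignment
    probability.  Work is linear in n times the number of reachable states.
    """
    strata = _as_strata(strata, n)
    dist: dict[Hashable, float] = {design.initial_state(): 1.0}
    out = np.empty(len(strata))
    for i, stratum in enumerate(strata):
        p = 0.0
        new: dict[Hashable, float] = {}
        for state, mass in dist.items():
            for d, pr, nxt in design.outcomes(state, stratum):
                if pr <= 0.0:
                    continue
                if d == 1:
                    p += mass * pr
                new[nxt] = new.get(nxt, 0.0) + mass * pr
        out[i] = p
        if len(new) > state_cap:
            raise MemoryError(
                f"state space exceeded cap ({len(new)} > {state_cap}) at patient {i + 1}"
            )
        total = sum(new.values())
        if abs(total - 1.0) > 1e-9:  # pragma: no cover - mass conservation guard
            raise AssertionError(f"state mass drifted to {total}")
        dist = new
    return out


def limiting_prob(design: RandomizationDesign, horizon: int = 500,
                  tol: float = 1e-6) -> float:
    """Terminal value of the exact marginal probability sequence.

    Runs the forward DP to ``horizon`` patients (single stratum) and reports
    the final P(δᵢ = 1); warns if successive values still differ by more
    than ``tol`` at the horizon.
    """
    probs = marginal_probs(design, horizon)
    if horizon >= 2 and abs(probs[-1] - probs[-2]) >= tol:
        warnings.warn(
            f"marginal probabilities not converged within horizon {horizon}: "
            f"last step change {abs(probs[-1] - probs[-2]):.2e}",
            RuntimeWarning,
        )
    return float(probs[-1])


def enumerate_full(design: RandomizationDesign, n: int,
                   strata: Sequence[Hashable] | None = None,
                   cap: int = 20) -> list[tuple[tuple[int, ...], float]]:
    """All assignment sequences with their exact probabilities.

    Zero-probability branches are pruned; paths through different internal
    states that produce the same δ vector (possible with arm-combining
    designs) are merged.  Probabilities sum to one.
    """
    strata = _as_strata(strata, n)
    if len(strata) > cap:
        raise EnumerationCapError(f"n={len(strata)} exceeds enumeration cap {cap}")
    seqs: dict[tuple[int, ...], float] = {}
    stack = [((), design.initial_state(), 1.0)]
    while stack:
        prefix, state, prob = stack.pop()
        i = len(prefix)
        if i == len(strata):
            seqs[prefix] = seqs.get(prefix, 0.0) + prob
            continue
        for d, pr, nxt in design.outcomes(state, strata[i]):
            if pr > 0.0:
                stack.append((prefix + (d,), nxt, prob * pr))
    return sorted(seqs.items())


def exact_moments(design: RandomizationDesign, n: int,
                  strata: Sequence[Hashable] | None = None,
                  cap: int = 20) -> AssignmentMoments:
    """Exact Eδ and Var(δ) from full enumeration (small n)."""
    seqs = enumerate_full(design, n, strata, cap=cap)
    D = np.array([s for s, _ in seqs], dtype=float)
    w = np.array([p for _, p in seqs])
    mean = w @ D
    second = (D * w[:, None]).T @ D
    V = second - np.outer(mean, mean)
    return AssignmentMoments(mean=mean, V=V, source="exact")


def montecarlo_moments(design: RandomizationDesign, n: int,
                       strata: Sequence[Hashable] | None = None,
                       reps: int = 100_000,
                       rng: np.random.Generator | int | None = None) -> AssignmentMoments:
    """Monte-Carlo Eδ and Var(δ) from ``reps`` rerandomizations."""
    if reps < 1000:
        raise ValueError("reps must be at least 1000")
    D = sample_assignments(design, _as_strata(strata, n), reps=reps, rng=rng)
    mean = D.mean(axis=0)
    V = np.cov(D.astype(float), rowvar=False, ddof=1)
    return AssignmentMoments(mean=mean, V=np.atleast_2d(V), source="monte_carlo",
                             reps=reps)


def _bin_accumulate(D: np.ndarray, w: np.ndarray, anc: np.ndarray,
                    bin_width: float) -> tuple[np.ndarray, ...]:
    centers = np.round(anc / bin_width) * bin_width
    uniq = np.unique(np.round(centers, 10))
    n = D.shape[1]
    p_c = np.empty((len(uniq), n))
    V_c = np.empty((len(uniq), n, n))
    mass = np.empty(len(uniq))
    for k, c in enumerate(uniq):
        sel = np.isclose(centers, c)
        wk = w[sel]
        mk = wk.sum()
        Dk = D[sel].astype(float)
        m1 = (wk @ Dk) / mk
        m2 = (Dk * wk[:, None]).T @ Dk / mk
        p_c[k] = m1
        V_c[k] = m2 - np.outer(m1, m1)
        mass[k] = mk
    return uniq, p_c, V_c, mass


def conditional_moments(design: RandomizationDesign, n: int,
                        M: np.ndarray,
                        strata: Sequence[Hashable] | None = None,
                        bin_width: float = 0.2,
                        mode: str = "exact",
                        reps: int = 100_000,
                        rng: np.random.Generator | int | None = None,
                        cap: int = 20) -> ConditionalMoments:
    """Moments of δ conditional on δ′Mδ grouped to the nearest ``bin_width``.

    ``mode="exact"`` enumerates all sequences (small n); ``mode="monte_carlo"``
    bins ``reps`` sampled rerandomizations.
    """
    M = np.asarray(M)
    if mode == "exact":
        seqs = enumerate_full(design, n, strata, cap=cap)
        D = np.array([s for s, _ in seqs], dtype=float)
        w = np.array([p for _, p in seqs])
        source = "exact"
        nreps = None
    elif mode == "monte_carlo":
        if reps < 10_000:
            raise ValueError("monte_carlo mode requires reps >= 10000")
        D = sample_assignments(design, _as_strata(strata, n), reps=reps, rng=rng)
        w = np.full(D.shape[0], 1.0 / D.shape[0])
        source = "monte_carlo"
        nreps = reps
    else:
        raise ValueError(f"unknown mode {mode!r}")
    anc = np.einsum("ri,ij,rj->r", D.astype(float), M, D.astype(float))
    bins, p_c, V_c, mass = _bin_accumulate(D, w, anc, bin_width)
    return ConditionalMoments(bins=bins, p_c=p_c, V_c=V_c, mass=mass,
                              bin_width=bin_width, source=source, reps=nreps)
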