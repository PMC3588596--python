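"""Sequential treatment-assignment rules for two-arm trials.

Every design is expressed through a single contract: a hashable *state*
summarizing the assignment history, and an ``outcomes(state, stratum)``
method returning the possible assignments of the current patient together
with their probabilities and successor states.  This uniform interface is
what the exact dynamic-programming engine, the full enumerator, and the
vectorized Monte-Carlo sampler all consume.

Assignments are coded ``1`` for the experimental arm and ``0`` for control.
The planned allocation is ``r1:r2`` experimental to control, so the target
marginal assignment probability is ``p = r1/(r1 + r2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Hashable, Sequence

import numpy as np

__all__ = [
    "AllocationSpec",
    "RandomizationDesign",
    "MultiArmDesign",
    "make_complete",
    "make_permuted_blocks",
    "make_biased_coin_2to1",
    "make_marginal_balance_2to1",
    "make_urn_2to1",
    "make_sequential_combine",
    "make_pocock_simon_1to1",
    "make_efron_coin_1to1",
    "make_multiarm_complete",
    "make_multiarm_permuted_blocks",
    "assign_sequence",
    "sample_assignments",
]

Outcome = tuple[int, float, Hashable]


@dataclass(frozen=True)
class AllocationSpec:
    """Planned allocation ratio ``r1:r2`` (experimental:control)."""

    r1: int
    r2: int

    def __post_init__(self) -> None:
        if self.r1 < 1 or self.r2 < 1:
            raise ValueError("allocation shares must be positive integers")

    @property
    def p_exact(self) -> Fraction:
        return Fraction(self.r1, self.r1 + self.r2)

    @property
    def p(self) -> float:
        return float(self.p_exact)

    @classmethod
    def parse(cls, text: str) -> "AllocationSpec":
        """Parse a ratio string such as ``"2:1"``."""
        r1, r2 = (int(t) for t in str(text).split(":"))
        return cls(r1, r2)


class RandomizationDesign:
    """Base class for a sequential two-arm randomization rule.

    Subclasses implement :meth:`initial_state` and :meth:`outcomes`.  The
    state must be hashable and must be the minimal sufficient statistic of
    the assignment probability, so the exact engine can aggregate histories.
    """

    name: str = "design"
    alloc: AllocationSpec

    def initial_state(self) -> Hashable:
        raise NotImplementedError

    def outcomes(self, state: Hashable, stratum: Hashable) -> list[Outcome]:
        """Possible assignments ``(delta, probability, next_state)``."""
        raise NotImplementedError

    def prob_experimental(self, state: Hashable, stratum: Hashable) -> float:
        """P(current patient assigned experimental | state, stratum)."""
        return sum(pr for d, pr, _ in self.outcomes(state, stratum) if d == 1)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{type(self).__name__} {self.name} {self.alloc.r1}:{self.alloc.r2}>"


class _TwoOutcomeDesign(RandomizationDesign):
    """Designs whose outcome set is always {experimental, control}."""

    def prob_fn(self, state: Hashable, stratum: Hashable) -> float:
        raise NotImplementedError

    def transition(self, state: Hashable, stratum: Hashable, delta: int) -> Hashable:
        raise NotImplementedError

    def outcomes(self, state, stratum):
        pe = self.prob_fn(state, stratum)
        out: list[Outcome] = []
        if pe > 0.0:
            out.append((1, pe, self.transition(state, stratum, 1)))
        if pe < 1.0:
            out.append((0, 1.0 - pe, self.transition(state, stratum, 0)))
        return out


class CompleteDesign(_TwoOutcomeDesign):
    """Complete randomization: an i.i.d. coin with P(experimental) = p."""

    name = "complete"

    def __init__(self, alloc: AllocationSpec):
        self.alloc = alloc

    def initial_state(self):
        return ()

    def prob_fn(self, state, stratum):
        return self.alloc.p

    def transition(self, state, stratum, delta):
        return ()


class PermutedBlocksDesign(_TwoOutcomeDesign):
    """Permuted-blocks randomization, optionally stratified.

    Within each stratum, assignments are drawn without replacement from a
    block holding ``block_size * r1/(r1+r2)`` experimental slots; a fresh
    block starts once the previous one is exhausted.  A final incomplete
    block is simply truncated at the end of enrollment.
    """

    name = "permuted_blocks"

    def __init__(self, alloc: AllocationSpec, block_size: int, stratified: bool = True):
        total = alloc.r1 + alloc.r2
        if block_size < 1 or block_size % total != 0:
            raise ValueError(
                f"block size {block_size} must be a positive multiple of {total}"
            )
        self.alloc = alloc
        self.block_size = block_size
        self.e_per_block = block_size * alloc.r1 // total
        self.stratified = stratified

    def initial_state(self):
        return ()

    # state: sorted tuple of (stratum_key, (n_used, n_e_used)) for open blocks
    def _counts(self, state, key):
        for k, v in state:
            if k == key:
                return v
        return (0, 0)

    def _key(self, stratum):
        return stratum if self.stratified else "__pooled__"

    def prob_fn(self, state, stratum):
        used, e_used = self._counts(state, self._key(stratum))
        return (self.e_per_block - e_used) / (self.block_size - used)

    def transition(self, state, stratum, delta):
        key = self._key(stratum)
        used, e_used = self._counts(state, key)
        used, e_used = used + 1, e_used + delta
        if used == self.block_size:  # block complete: reset
            used, e_used = 0, 0
        items = {k: v for k, v in state}
        if used == 0:
            items.pop(key, None)
        else:
            items[key] = (used, e_used)
        return tuple(sorted(items.items(), key=lambda kv: repr(kv[0])))


class BiasedCoin2to1Design(_TwoOutcomeDesign):
    """2:1 biased coin triggered by the imbalance n_e/2 − n_c.

    The coin favors the experimental arm with probability ``p_low`` after an
    excess of control assignments (n_e/2 − n_c ≤ −threshold), favors control
    (P(experimental) = ``p_high``) after an excess of experimental
    assignments, and otherwise assigns experimental with probability 2/3.
    The first patient is assigned experimental with probability 2/3.  This
    rule violates the constant-probability condition Eδ = p·1.
    """

    name = "biased_coin_2to1"

    def __init__(self, p_low: float = 0.9, p_high: float = 0.2, threshold: float = 1.0):
        if not (0.0 < p_high < p_low < 1.0):
            raise ValueError("require 0 < p_high < p_low < 1")
        self.alloc = AllocationSpec(2, 1)
        self.p_low = p_low
        self.p_high = p_high
        self.threshold = threshold

    def initial_state(self):
        return (0, 0)

    def prob_fn(self, state, stratum):
        n_e, n_c = state
        d = n_e / 2.0 - n_c
        if d <= -self.threshold:
            return self.p_low
        if d >= self.threshold:
            return self.p_high
        return 2.0 / 3.0

    def transition(self, state, stratum, delta):
        return (state[0] + delta, state[1] + 1 - delta)


class MarginalBalance2to1Design(_TwoOutcomeDesign):
    """2:1 biased coin driven by the normalized marginal-balance metric.

    For a hypothetical assignment of the current patient to each arm,
    compute the relative imbalance |n_e/r1 − n_c/r2| / (n_e/r1 + n_c/r2)
    of the resulting counts; the arm yielding the smaller imbalance is
    favored (experimental with probability ``p_low`` or ``p_high``).  Ties,
    and the first patient, assign experimental with probability 2/3.
    """

    name = "marginal_balance_2to1"

    def __init__(self, p_low: float = 0.9, p_high: float = 0.2):
        if not (0.0 < p_high < p_low < 1.0):
            raise ValueError("require 0 < p_high < p_low < 1")
        self.alloc = AllocationSpec(2, 1)
        self.p_low = p_low
        self.p_high = p_high

    def initial_state(self):
        return (0, 0)

    @staticmethod
    def _imbalance(n_e: int, n_c: int, r1: int, r2: int) -> Fraction:
        a = Fraction(n_e, r1)
        b = Fraction(n_c, r2)
        den = a + b
        if den == 0:
            return Fraction(0)
        return abs(a - b) / den

    def prob_fn(self, state, stratum):
        n_e, n_c = state
        r1, r2 = self.alloc.r1, self.alloc.r2
        if_e = self._imbalance(n_e + 1, n_c, r1, r2)
        if_c = self._imbalance(n_e, n_c + 1, r1, r2)
        if if_e < if_c:
            return self.p_low
        if if_e > if_c:
            return self.p_high
        return 2.0 / 3.0

    def transition(self, state, stratum, delta):
        return (state[0] + delta, state[1] + 1 - delta)


class Urn2to1Design(_TwoOutcomeDesign):
    """Urn randomization for 2:1 allocation.

    The urn starts with ``init_e`` experimental and ``init_c`` control
    balls; the next patient is assigned experimental with probability
    E/(E + C).  A control assignment adds ``add_on_control`` experimental
    balls; an experimental assignment adds ``add_on_experimental`` control
    balls.  With ``add_on_control=2`` the marginal assignment probabilities
    drift to 0.586; ``add_on_control=4`` restores Eδᵢ = 2/3.
    """

    name = "urn_2to1"

    def __init__(
        self,
        add_on_control: int = 2,
        add_on_experimental: int = 1,
        init_e: int = 2,
        init_c: int = 1,
    ):
        if init_e < 1 or init_c < 0 or add_on_control < 0 or add_on_experimental < 0:
            raise ValueError("urn parameters must be nonnegative with init_e >= 1")
        self.alloc = AllocationSpec(2, 1)
        self.add_on_control = add_on_control
        self.add_on_experimental = add_on_experimental
        self.init = (init_e, init_c)

    def initial_state(self):
        return self.init

    def prob_fn(self, state, stratum):
        e, c = state
        if e + c == 0:
            raise ValueError("urn is empty")
        return e / (e + c)

    def transition(self, state, stratum, delta):
        e, c = state
        if delta == 1:
            return (e, c + self.add_on_experimental)
        return (e + self.add_on_control, c)


class MultiArmDesign:
    """Base class for symmetric k-arm randomization rules (inner designs)."""

    k: int

    def initial_state(self) -> Hashable:
        raise NotImplementedError

    def arm_outcomes(self, state: Hashable, stratum: Hashable) -> list[tuple[int, float, Hashable]]:
        """Possible arms ``(arm, probability, next_state)``."""
        raise NotImplementedError


class MultiArmCompleteDesign(MultiArmDesign):
    """Equal-probability i.i.d. assignment to k arms."""

    def __init__(self, k: int):
        if k < 2:
            raise ValueError("need at least two arms")
        self.k = k

    def initial_state(self):
        return ()

    def arm_outcomes(self, state, stratum):
        pr = 1.0 / self.k
        return [(a, pr, ()) for a in range(self.k)]


class MultiArmPermutedBlocksDesign(MultiArmDesign):
    """Balanced permuted blocks over k arms, optionally stratified."""

    def __init__(self, k: int, block_size: int, stratified: bool = True):
        if k < 2:
            raise ValueError("need at least two arms")
        if block_size % k != 0 or block_size < k:
            raise ValueError(f"block size {block_size} must be a positive multiple of {k}")
        self.k = k
        self.block_size = block_size
        self.per_arm = block_size // k
        self.stratified = stratified

    def initial_state(self):
        return ()

    def _key(self, stratum):
        return stratum if self.stratified else "__pooled__"

    def _counts(self, state, key):
        for s, v in state:
            if s == key:
                return v
        return (0,) * self.k

    def arm_outcomes(self, state, stratum):
        key = self._key(stratum)
        counts = self._counts(state, key)
        used = sum(counts)
        remaining = self.block_size - used
        out = []
        for a in range(self.k):
            slots = self.per_arm - counts[a]
            if slots <= 0:
                continue
            new = list(counts)
            new[a] += 1
            if used + 1 == self.block_size:
                nxt = tuple(sorted(
                    ((s, v) for s, v in state if s != key), key=lambda kv: repr(kv[0])
                ))
            else:
                items = {s: v for s, v in state}
                items[key] = tuple(new)
                nxt = tuple(sorted(items.items(), key=lambda kv: repr(kv[0])))
            out.append((a, slots / remaining, nxt))
        return out


class SequentialCombineDesign(RandomizationDesign):
    """Unequal allocation by combining arms of a symmetric inner design.

    Randomize to ``r1 + r2`` arms with a rule that treats the arms
    symmetrically, then assign experimental treatment whenever one of the
    first ``r1`` arms is drawn.  Arm symmetry of the inner rule guarantees
    the constant-probability condition Eδ = p·1.
    """

    name = "sequential_combine"

    def __init__(self, inner: MultiArmDesign, alloc: AllocationSpec):
        if inner.k != alloc.r1 + alloc.r2:
            raise ValueError(
                f"inner design has {inner.k} arms; allocation needs {alloc.r1 + alloc.r2}"
            )
        self.inner = inner
        self.alloc = alloc

    def initial_state(self):
        return self.inner.initial_state()

    def outcomes(self, state, stratum):
        return [
            (1 if arm < self.alloc.r1 else 0, pr, nxt)
            for arm, pr, nxt in self.inner.arm_outcomes(state, stratum)
        ]


class PocockSimon1to1Design(_TwoOutcomeDesign):
    """Covariate-adaptive minimization over stratification-factor margins.

    The stratum label of each patient is a tuple of factor levels.  For a
    hypothetical assignment of the current patient to each arm, the total
    imbalance is the weighted sum over the patient's factor levels of the
    absolute difference in arm counts at that level (the range metric for
    two arms); the arm minimizing the total is chosen with probability
    ``bias_prob``, with ties broken by a fair coin.
    """

    name = "pocock_simon_1to1"

    def __init__(self, n_factors: int, weights: Sequence[float] | None = None,
                 bias_prob: float = 0.75):
        if n_factors < 1:
            raise ValueError("need at least one stratification factor")
        if not (0.5 <= bias_prob <= 1.0):
            raise ValueError("bias_prob must lie in [0.5, 1]")
        self.alloc = AllocationSpec(1, 1)
        self.n_factors = n_factors
        self.weights = tuple(float(w) for w in (weights or [1.0] * n_factors))
        if len(self.weights) != n_factors:
            raise ValueError("one weight per factor required")
        self.bias_prob = bias_prob

    def initial_state(self):
        return ()

    @staticmethod
    def _levels(stratum, n_factors):
        if n_factors == 1 and not isinstance(stratum, tuple):
            return (stratum,)
        return tuple(stratum)

    def prob_fn(self, state, stratum):
        counts = {k: v for k, v in state}
        levels = self._levels(stratum, self.n_factors)
        imb = [0.0, 0.0]  # total imbalance if assigned E (arm 1) or C (arm 0)
        for f, lev in enumerate(levels):
            n_e, n_c = counts.get((f, lev), (0, 0))
            imb[1] += self.weights[f] * abs((n_e + 1) - n_c)
            imb[0] += self.weights[f] * abs(n_e - (n_c + 1))
        if imb[1] < imb[0]:
            return self.bias_prob
        if imb[1] > imb[0]:
            return 1.0 - self.bias_prob
        return 0.5

    def transition(self, state, stratum, delta):
        counts = {k: v for k, v in state}
        for f, lev in enumerate(self._levels(stratum, self.n_factors)):
            n_e, n_c = counts.get((f, lev), (0, 0))
            counts[(f, lev)] = (n_e + delta, n_c + 1 - delta)
        return tuple(sorted(counts.items(), key=lambda kv: repr(kv[0])))


class EfronCoin1to1Design(_TwoOutcomeDesign):
    """Classic 1:1 biased coin: favor the lagging arm with a fixed bias."""

    name = "efron_coin_1to1"

    def __init__(self, bias: float = 2.0 / 3.0):
        if not (0.5 <= bias < 1.0):
            raise ValueError("bias must lie in [0.5, 1)")
        self.alloc = AllocationSpec(1, 1)
        self.bias = bias

    def initial_state(self):
        return (0, 0)

    def prob_fn(self, state, stratum):
        n_e, n_c = state
        if n_e < n_c:
            return self.bias
        if n_e > n_c:
            return 1.0 - self.bias
        return 0.5

    def transition(self, state, stratum, delta):
        return (state[0] + delta, state[1] + 1 - delta)


# ---------------------------------------------------------------------------
# factory functions


def make_complete(alloc: AllocationSpec) -> CompleteDesign:
    """Complete randomization with constant P(experimental) = p."""
    return CompleteDesign(alloc)


def make_permuted_blocks(alloc: AllocationSpec, block_size: int,
                         stratified: bool = True) -> PermutedBlocksDesign:
    """Permuted-blocks randomization in blocks of ``block_size``."""
    return PermutedBlocksDesign(alloc, block_size, stratified)


def make_biased_coin_2to1(p_low: float = 0.9, p_high: float = 0.2,
                          threshold: float = 1.0) -> BiasedCoin2to1Design:
    return BiasedCoin2to1Design(p_low, p_high, threshold)


def make_marginal_balance_2to1(p_low: float = 0.9,
                               p_high: float = 0.2) -> MarginalBalance2to1Design:
    return MarginalBalance2to1Design(p_low, p_high)


def make_urn_2to1(add_on_control: int, add_on_experimental: int = 1,
                  init_e: int = 2, init_c: int = 1) -> Urn2to1Design:
    return Urn2to1Design(add_on_control, add_on_experimental, init_e, init_c)


def make_sequential_combine(inner: MultiArmDesign,
                            alloc: AllocationSpec) -> SequentialCombineDesign:
    return SequentialCombineDesign(inner, alloc)


def make_pocock_simon_1to1(n_factors: int, weights: Sequence[float] | None = None,
                           bias_prob: float = 0.75) -> PocockSimon1to1Design:
    return PocockSimon1to1Design(n_factors, weights, bias_prob)


def make_efron_coin_1to1(bias: float = 2.0 / 3.0) -> EfronCoin1to1Design:
    return EfronCoin1to1Design(bias)


def make_multiarm_complete(k: int) -> MultiArmCompleteDesign:
    return MultiArmCompleteDesign(k)


def make_multiarm_permuted_blocks(k: int, block_size: int,
                                  stratified: bool = True) -> MultiArmPermutedBlocksDesign:
    return MultiArmPermutedBlocksDesign(k, block_size, stratified)


# ---------------------------------------------------------------------------
# sampling


def _as_strata(strata, n=None):
    if strata is None:
        if n is None:
            raise ValueError("need strata or n")
        return [""] * n
    return list(strata)


def assign_sequence(design: RandomizationDesign, strata: Sequence[Hashable] | None = None,
                    rng: np.random.Generator | int | None = None,
                    n: int | None = None) -> np.ndarray:
    """Sample one assignment vector δ for patients enrolled in fixed order."""
    strata = _as_strata(strata, n)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    state = design.initial_state()
    delta = np.empty(len(strata), dtype=np.int8)
    for i, s in enumerate(strata):
        outs = design.outcomes(state, s)
        probs = np.array([pr for _, pr, _ in outs])
        j = rng.choice(len(outs), p=probs / probs.sum())
        delta[i], _, state = outs[j]
    return delta


def sample_assignments(design: RandomizationDesign,
                       strata: Sequence[Hashable] | None = None,
                       reps: int = 10000,
                       rng: np.random.Generator | int | None = None,
                       n: int | None = None) -> np.ndarray:
    """Sample ``reps`` independent assignment vectors, vectorized over reps.

    All replicates advance patient by patient; replicates sharing a design
    state are grouped so per-step work is proportional to the number of
    distinct states, which stays small for all implemented designs.
    """
    strata = _as_strata(strata, n)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    npat = len(strata)
    D = np.empty((reps, npat), dtype=np.int8)
    states: list[Hashable] = [design.initial_state()]
    sidx = np.zeros(reps, dtype=np.int64)
    for i, stratum in enumerate(strata):
        u = rng.random(reps)
        new_states: list[Hashable] = []
        new_index: dict[Hashable, int] = {}
        next_sidx = np.empty(reps, dtype=np.int64)
        for s_id in np.unique(sidx):
            outs = design.outcomes(states[s_id], stratum)
            cum = np.cumsum([pr for _, pr, _ in outs])
            cum[-1] = 1.0  # guard against float round-off
            mask = sidx == s_id
            pick = np.searchsorted(cum, u[mask], side="left")
            deltas = np.fromiter((d for d, _, _ in outs), dtype=np.int8)
            D[mask, i] = deltas[pick]
            out_ids = np.empty(len(outs), dtype=np.int64)
            for j, (_, _, nxt) in enumerate(outs):
                if nxt not in new_index:
                    new_index[nxt] = len(new_states)
                    new_states.append(nxt)
                out_ids[j] = new_index[nxt]
            next_sidx[mask] = out_ids[pick]
        states, sidx = new_states, next_sidx
    return D
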