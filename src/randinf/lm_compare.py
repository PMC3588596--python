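"""Population-based linear-model analysis and its randomization comparison.

The conventional analysis fits y = Xβ + δτ + ε with i.i.d. errors and
estimates Var(τ̂) by s²/(δ′Mδ).  From the randomization perspective both the
numerator and denominator are random; taking expectations separately gives
the approximation implemented in :func:`lm_var_expectation`.  Whether the
linear-model estimate over- or under-states the true randomization variance
depends on the time pattern of the unit-effect residuals: low-frequency
trends inflate it, high-frequency alternation deflates it, and pattern-free
(i.i.d.) unit effects make both estimate σ²/tr(MV).  The exposure of a
design to an unmodeled covariate z is measured by the accidental-bias
quadratic form z′MVMz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import AssignmentMoments
from .projection import Projection

__all__ = ["UnitEffectPattern", "lm_var_hat", "lm_var_expectation",
           "accidental_bias_form"]


@dataclass
class UnitEffectPattern:
    """A stylized time pattern for the fixed unit effects y₀.

    kind:
        ``"iid"`` — pattern-free noise with variance ``sigma2``;
        ``"linear_trend"`` — increasing linear trend plus noise;
        ``"low_frequency"`` — half-cycle sinusoid over the enrollment
        window plus noise (default ``frequency=0.5`` cycles per trial);
        ``"high_frequency"`` — alternating ±1 pattern plus noise.
    r2:
        fraction of the total variance carried by the systematic component
        (ignored for ``"iid"``).
    """

    kind: str = "iid"
    sigma2: float = 1.0
    r2: float = 0.5
    frequency: float | None = None

    def __post_init__(self):
        if self.kind not in ("iid", "linear_trend", "low_frequency", "high_frequency"):
            raise ValueError(f"unknown unit-effect pattern {self.kind!r}")
        if not (0.0 <= self.r2 < 1.0):
            raise ValueError("r2 must lie in [0, 1)")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


def _q(proj_or_q) -> int:
    return proj_or_q.q if isinstance(proj_or_q, Projection) else int(proj_or_q)


def lm_var_hat(y: np.ndarray, delta: np.ndarray, proj: Projection) -> float:
    """OLS variance estimate of the treatment coefficient: s²/(δ′Mδ).

    s² is the residual mean square from the least-squares fit of y on
    [X, δ], with n − q − 1 degrees of freedom.
    """
    M, q = proj.M, proj.q
    y = np.asarray(y, float)
    d = np.asarray(delta, float)
    a = float(d @ M @ d)
    if a <= 1e-12:
        raise ZeroDivisionError("degenerate assignment: δ′Mδ = 0")
    dof = len(y) - q - 1
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    th = float(d @ M @ y) / a
    rss = float(y @ M @ y) - th ** 2 * a
    return max(rss, 0.0) / dof / a


def lm_var_expectation(y0: np.ndarray, tau: float, proj: Projection,
                       V: np.ndarray | AssignmentMoments) -> float:
    """Randomization expectation of the linear-model variance estimate.

    Approximates E_r[s²/(δ′Mδ)] by the ratio of expectations; to first
    order the τ terms cancel and

        E_r[v̂_lm] ≈ (y₀′My₀ − y₀′MVMy₀ / tr MV) / ((n − q − 1)·tr MV).
    """
    M, q = proj.M, proj.q
    V = V.V if isinstance(V, AssignmentMoments) else np.asarray(V)
    r = M @ np.asarray(y0, float)
    t = float(np.trace(M @ V))
    dof = len(r) - q - 1
    if t <= 0 or dof <= 0:
        raise ValueError("need tr(MV) > 0 and residual degrees of freedom")
    return (float(r @ r) - float(r @ V @ r) / t) / (dof * t)


def accidental_bias_form(z: np.ndarray, M: np.ndarray | Projection,
                         V: np.ndarray | AssignmentMoments) -> float:
    """Accidental-bias quadratic form z′MVMz for a unit-length covariate z."""
    M = M.M if isinstance(M, Projection) else np.asarray(M)
    V = V.V if isinstance(V, AssignmentMoments) else np.asarray(V)
    z = np.asarray(z, float)
    if abs(float(z @ z) - 1.0) > 1e-8:
        raise ValueError("z must have unit length")
    r = M @ z
    return float(r @ V @ r)
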