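"""Monte-Carlo randomization tests of the sharp null of no treatment effect.

Under the null, y = y₀ is fixed and the observed τ̂ is one draw from the
distribution induced by rerandomizing treatments to the patients in their
fixed enrollment order.  The test replays the trial's randomization rule,
recomputes τ̂ for each replicate, and reports the add-one p-value
(count + 1)/(reps + 1).  The test can be run conditionally on the observed
bin of the ancillary δ′Mδ, using only replicates with a suitably close
ancillary value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .designs import RandomizationDesign, sample_assignments
from .engine import AssignmentMoments
from .projection import Projection, ancillary

__all__ = ["RandTestResult", "randomization_test", "null_moments"]


@dataclass
class RandTestResult:
    observed_tau_hat: float
    reps: int
    reps_used: int
    p_one_sided: float
    p_two_sided: float
    null_mean: float
    null_var: float
    conditional: bool = False
    bin_center: float | None = None
    bin_width_used: float | None = None
    degenerate_skipped: int = 0


def randomization_test(y: np.ndarray, observed_delta: np.ndarray,
                       design: RandomizationDesign, proj: Projection,
                       strata=None, reps: int = 10_000, sided: str = "two",
                       conditional: bool = False, bin_width: float = 0.2,
                       min_bin_occupancy: int = 200,
                       rng: np.random.Generator | int | None = None) -> RandTestResult:
    """Monte-Carlo randomization test holding y and patient order fixed.

    One-sided p is the fraction of replicate τ̂ values at least as large as
    the observed value (alternative of positive τ); two-sided p compares
    |τ̂ − null mean|.  Replicates with δ′Mδ = 0 cannot produce an estimate
    and are skipped (their count is reported).
    """
    if reps < 1000:
        raise ValueError("reps must be at least 1000")
    y = np.asarray(y, float)
    M = proj.M
    n = len(y)
    strata = strata if strata is not None else [""] * n
    D = sample_assignments(design, strata, reps=reps, rng=rng).astype(float)
    DM = D @ M
    anc = np.einsum("ri,ri->r", DM, D)
    ok = anc > 1e-12
    skipped = int((~ok).sum())
    taus = np.full(reps, np.nan)
    taus[ok] = (DM[ok] @ y) / anc[ok]

    obs_anc = ancillary(M, observed_delta)
    obs_tau = float(np.asarray(observed_delta, float) @ M @ y) / obs_anc

    keep = ok.copy()
    bin_center = bin_width_used = None
    if conditional:
        bw = bin_width
        bin_center = round(obs_anc / bw) * bw
        sel = keep & (np.abs(anc - bin_center) <= bw / 2 + 1e-9)
        if sel.sum() < min_bin_occupancy:
            bw = 2 * bin_width
            center2 = round(obs_anc / bw) * bw
            warnings.warn(
                f"conditional bin at {bin_center:g} under-populated; widening to "
                f"bin width {bw:g}", RuntimeWarning)
            sel = keep & (np.abs(anc - center2) <= bw / 2 + 1e-9)
            bin_center = center2
        keep = sel
        bin_width_used = bw

    t = taus[keep]
    m = int(keep.sum())
    if m == 0:
        raise RuntimeError("no usable replicates for the randomization test")
    null_mean = float(t.mean())
    null_var = float(t.var(ddof=1)) if m > 1 else 0.0
    p_one = (float((t >= obs_tau - 1e-12).sum()) + 1.0) / (m + 1.0)
    p_two = (float((np.abs(t - null_mean) >= abs(obs_tau - null_mean) - 1e-12).sum())
             + 1.0) / (m + 1.0)
    return RandTestResult(
        observed_tau_hat=obs_tau, reps=reps, reps_used=m,
        p_one_sided=p_one, p_two_sided=p_two,
        null_mean=null_mean, null_var=null_var,
        conditional=conditional, bin_center=bin_center,
        bin_width_used=bin_width_used, degenerate_skipped=skipped)


def null_moments(y: np.ndarray, M: np.ndarray | Projection,
                 V: np.ndarray | AssignmentMoments,
                 p_vec: np.ndarray | None = None) -> tuple[float, float]:
    """Approximate moments of τ̂ under the sharp null (y fixed).

    With the constant-probability condition Eδ = p·1 the null distribution
    is centered at zero with variance y′MVMy / (tr MV)²; when the marginal
    probabilities p vary over patients the center shifts to p′My / tr(MV).
    """
    M = M.M if isinstance(M, Projection) else np.asarray(M)
    V = V.V if isinstance(V, AssignmentMoments) else np.asarray(V)
    y = np.asarray(y, float)
    t = float(np.trace(M @ V))
    if t <= 0:
        raise ValueError("tr(MV) must be positive")
    r = M @ y
    var = float(r @ V @ r) / t ** 2
    mean = 0.0
    if p_vec is not None:
        mean = float(np.asarray(p_vec, float) @ r) / t
    return mean, var
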