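"""Covariate matrices, the residual-maker M, and the ancillary δ′Mδ.

The covariate matrix X always contains the constant vector in its column
space and is required to have full column rank q < n.  The residual-maker
M = I − X(X′X)⁻¹X′ projects onto the orthogonal complement of the columns
of X; the quadratic form δ′Mδ of an assignment vector is an ancillary
statistic (in the stratified cases it is a function of per-stratum arm
counts only) and indexes conditional inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .trial import TrialFrame

__all__ = ["DesignMatrixSpec", "Projection", "build_design_matrix",
           "build_projection", "ancillary"]

_RANK_TOL = 1e-10


@dataclass
class DesignMatrixSpec:
    """Ordered covariate terms for the adjustment matrix X.

    Terms are ``"intercept"``, ``("factor", column)`` for a categorical main
    effect (full-rank treatment coding, reference level dropped),
    ``("covariate", column)`` for a continuous covariate taken as-is, or
    ``("values", name, vector)`` for an explicit numeric column (used e.g.
    to augment X with an assignment-probability vector).
    """

    terms: list = field(default_factory=lambda: ["intercept"])

    @classmethod
    def intercept_only(cls) -> "DesignMatrixSpec":
        return cls(["intercept"])

    def augmented(self, name: str, values: np.ndarray) -> "DesignMatrixSpec":
        return DesignMatrixSpec(list(self.terms) + [("values", name, np.asarray(values, float))])


@dataclass
class Projection:
    """The residual-maker M of a full-column-rank covariate matrix X."""

    M: np.ndarray
    X: np.ndarray
    q: int
    column_names: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.M.shape[0]

    def ancillary(self, delta: np.ndarray) -> float:
        return ancillary(self.M, delta)


def _term_columns(term, data: pd.DataFrame | None, n: int):
    if term == "intercept" or term == "1":
        return ["intercept"], np.ones((n, 1))
    if isinstance(term, tuple) and term[0] == "values":
        _, name, vals = term
        v = np.asarray(vals, dtype=float).reshape(n, 1)
        return [name], v
    if isinstance(term, tuple) and term[0] in ("factor", "covariate"):
        kind, col = term
        if data is None:
            raise ValueError(f"term {term!r} needs a trial table")
        x = data[col]
        if kind == "covariate":
            return [col], x.to_numpy(dtype=float).reshape(n, 1)
        levels = sorted(pd.unique(x), key=repr)
        cols, names = [], []
        for lev in levels[1:]:  # drop reference level; intercept carries it
            cols.append((x == lev).to_numpy(dtype=float).reshape(n, 1))
            names.append(f"{col}[{lev}]")
        if not cols:
            return [], np.empty((n, 0))
        return names, np.hstack(cols)
    raise ValueError(f"unrecognized design-matrix term {term!r}")


def build_design_matrix(spec: DesignMatrixSpec,
                        data: TrialFrame | pd.DataFrame | None = None,
                        n: int | None = None) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, TrialFrame):
        data = data.df
    if n is None:
        if data is None:
            raise ValueError("need data or n to size the design matrix")
        n = len(data)
    names: list[str] = []
    blocks = []
    for term in spec.terms:
        tn, tb = _term_columns(term, data, n)
        names.extend(tn)
        blocks.append(tb)
    X = np.hstack(blocks)
    return X, names


def build_projection(spec: DesignMatrixSpec,
                     data: TrialFrame | pd.DataFrame | None = None,
                     n: int | None = None) -> Projection:
    """Build M = I − X(X′X)⁻¹X′ via a rank-revealing QR decomposition."""
    X, names = build_design_matrix(spec, data, n)
    n = X.shape[0]
    Q, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = _RANK_TOL * max(diag[0], 1.0) * max(X.shape)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        dropped = [names[j] for j in piv[rank:]]
        raise ValueError(
            f"covariate matrix is rank deficient; collinear terms: {dropped}"
        )
    M = np.eye(n) - Q @ Q.T
    M = 0.5 * (M + M.T)  # enforce exact symmetry
    return Projection(M=M, X=X, q=rank, column_names=tuple(names))


def ancillary(M: np.ndarray | Projection, delta: np.ndarray) -> float:
    """The ancillary quadratic form δ′Mδ of an assignment vector."""
    if isinstance(M, Projection):
        M = M.M
    d = np.asarray(delta, dtype=float)
    if d.shape[0] != M.shape[0]:
        raise ValueError("assignment vector and M have incompatible shapes")
    val = float(d @ M @ d)
    return max(val, 0.0)
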