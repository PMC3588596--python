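"""Trial tables: patients in fixed randomization order.

A :class:`TrialFrame` wraps a pandas DataFrame with one row per patient in
order of entry, carrying stratum labels, optional continuous covariates, an
optional observed response ``y`` and an optional realized assignment
``delta``.  In the randomization model everything in this table is fixed;
only the treatment assignment is random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TrialFrame"]


@dataclass
class TrialFrame:
    df: pd.DataFrame
    stratum_cols: tuple[str, ...] = ()
    y_col: str = "y"
    delta_col: str = "delta"

    def __post_init__(self):
        self.stratum_cols = tuple(self.stratum_cols)
        for c in self.stratum_cols:
            if c not in self.df.columns:
                raise KeyError(f"stratum column {c!r} not in trial table")
        if "patient_order" in self.df.columns:
            self.df = self.df.sort_values("patient_order").reset_index(drop=True)

    @classmethod
    def from_csv(cls, path, stratum_cols: Sequence[str] = (), **kwargs) -> "TrialFrame":
        return cls(pd.read_csv(path), stratum_cols=tuple(stratum_cols), **kwargs)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def strata(self) -> list:
        """Per-patient stratum label (a tuple when several factors)."""
        if not self.stratum_cols:
            return [""] * self.n
        if len(self.stratum_cols) == 1:
            return list(self.df[self.stratum_cols[0]])
        return list(map(tuple, self.df[list(self.stratum_cols)].itertuples(index=False)))

    @property
    def y(self) -> np.ndarray:
        if self.y_col not in self.df.columns:
            raise KeyError(f"no response column {self.y_col!r}")
        return self.df[self.y_col].to_numpy(dtype=float)

    @property
    def delta(self) -> np.ndarray:
        if self.delta_col not in self.df.columns:
            raise KeyError(f"no assignment column {self.delta_col!r}")
        d = self.df[self.delta_col].to_numpy()
        if not np.isin(d, [0, 1]).all():
            raise ValueError("assignments must be coded 0/1")
        return d.astype(np.int8)

    def with_assignment(self, delta: np.ndarray) -> "TrialFrame":
        df = self.df.copy()
        df[self.delta_col] = np.asarray(delta, dtype=int)
        return TrialFrame(df, self.stratum_cols, self.y_col, self.delta_col)

    def with_response(self, y: np.ndarray) -> "TrialFrame":
        df = self.df.copy()
        df[self.y_col] = np.asarray(y, dtype=float)
        return TrialFrame(df, self.stratum_cols, self.y_col, self.delta_col)
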