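"""Cross-correlation of experimental parameters with molecular descriptors.

Builds the matrix of squared Pearson correlations (determination
coefficients R^2) between per-compound experimental quantities (log k_w, S,
phi0 per modifier; dH, dG) and arbitrary numeric descriptor columns
(polarizability, calculated log P, BBB score, docking / DFT binding
energies, topological indices). Cells are pairwise-complete: each uses only
compounds with both values present, and its n is reported; nothing is
imputed. Raw R^2 only — no multiple-testing correction is applied, matching
common screening practice; interpret large matrices accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SchemaError

__all__ = ["CorrelationMatrix", "cross_correlate", "pairwise_r2"]

MIN_SHARED = 3


@dataclass
class CorrelationMatrix:
    """r2 per (parameter, descriptor) cell with per-cell n.

    Cells with fewer than 3 shared compounds are NaN ('undefined'), with n
    still recorded.
    """

    r2: pd.DataFrame
    n: pd.DataFrame
    method: str = "pearson"

    def cell(self, parameter: str, descriptor: str) -> tuple[float, int]:
        return float(self.r2.loc[parameter, descriptor]), int(self.n.loc[parameter, descriptor])

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "r2": {p: {d: _none_if_nan(self.r2.loc[p, d]) for d in self.r2.columns} for p in self.r2.index},
            "n": {p: {d: int(self.n.loc[p, d]) for d in self.n.columns} for p in self.n.index},
            "note": "raw bivariate R^2; no multiple-testing correction applied",
        }

    def summary(self) -> str:
        return (
            f"Cross-correlation matrix ({self.method} R^2; pairwise-complete)\n\n"
            + self.r2.to_string(float_format=lambda v: f"{v:.4f}")
        )


def _none_if_nan(v):
    return None if pd.isna(v) else float(v)


def pairwise_r2(x, y, method: str = "pearson") -> tuple[float, int]:
    """Squared correlation of two vectors over their pairwise-complete subset."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < MIN_SHARED:
        return float("nan"), n
    xv, yv = x[ok], y[ok]
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return float("nan"), n
    if method == "pearson":
        r = stats.pearsonr(xv, yv).statistic
    elif method == "spearman":
        r = stats.spearmanr(xv, yv).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r * r), n


def cross_correlate(
    params: pd.DataFrame, descriptors: pd.DataFrame, method: str = "pearson"
) -> CorrelationMatrix:
    """Correlate every experimental parameter with every descriptor.

    Both frames are indexed by compound_id; rows are aligned on the index
    intersection, cells on their pairwise-complete subsets.
    """
    if descriptors.shape[1] == 0:
        raise SchemaError("descriptor table has no descriptor columns")
    empty = [c for c in descriptors.columns if descriptors[c].isna().all()]
    if empty:
        raise SchemaError(f"descriptor column(s) entirely missing: {empty}")
    shared = params.index.intersection(descriptors.index)
    p = params.loc[shared]
    d = descriptors.loc[shared]
    r2 = pd.DataFrame(index=p.columns, columns=d.columns, dtype=float)
    n = pd.DataFrame(index=p.columns, columns=d.columns, dtype=int)
    for pc in p.columns:
        for dc in d.columns:
            r2.loc[pc, dc], n.loc[pc, dc] = pairwise_r2(p[pc], d[dc], method=method)
    return CorrelationMatrix(r2=r2, n=n.astype(int), method=method)
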