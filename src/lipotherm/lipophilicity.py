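"""Soczewinski-Wachtmeister lipophilicity indices from isocratic retention data.

Under reversed-phase conditions retention falls log-linearly with the organic
modifier volume fraction phi::

    log10 k = log10 k_w + S * phi

with S < 0. The intercept log k_w extrapolates retention to pure water (a
chromatographic lipophilicity index), and phi0 = -log k_w / S is the modifier
fraction at which k = 1 — an interpolated index generally more reproducible
than the extrapolated log k_w.

Sign convention: ``S`` is stored as the raw fitted slope d(log10 k)/dphi and
is therefore *negative* in reversed-phase systems; literature that writes the
model as log k = -S phi + log k_w reports the same negative numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AmbiguousSeriesError, InsufficientDataError, PairingError
from .io import RetentionMeasurement, measurements_to_frame
from .linreg import LinearFit, fit_ols

__all__ = [
    "LipophilicityIndices",
    "SoczewinskiModel",
    "LipophilicityResults",
    "fit_soczewinski",
    "similarity_regression",
    "cross_system_regression",
]


@dataclass(frozen=True)
class LipophilicityIndices:
    """Per-(compound, modifier) lipophilicity indices with their fit.

    ``range_warning`` flags that log k_w is an extrapolation beyond the
    measured phi range (phi = 0 is never measured), and that phi0 may also
    fall outside it.
    """

    compound_id: str
    modifier: str
    S: float
    log_kw: float
    phi0: float
    fit: LinearFit
    range_warning: bool = True

    def to_dict(self) -> dict:
        d = {
            "compound_id": self.compound_id,
            "modifier": self.modifier,
            "S": self.S,
            "log_kw": self.log_kw,
            "phi0": self.phi0,
            "range_warning": self.range_warning,
        }
        d.update({f"fit_{k}": v for k, v in self.fit.to_dict().items()})
        return d


def fit_soczewinski(measurements) -> LipophilicityIndices:
    """Fit log10 k vs phi for one compound and modifier at fixed temperature.

    Requires >= 3 distinct phi levels and a single temperature.
    phi0 satisfies log_kw + S * phi0 = 0 exactly.
    """
    df = _one_series_frame(measurements)
    if df["temperature"].nunique() > 1:
        raise AmbiguousSeriesError(
            f"mixed temperatures {sorted(df['temperature'].unique())} in an "
            "isocratic lipophilicity series"
        )
    if df["phi"].nunique() < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct phi levels, got {df['phi'].nunique()}"
        )
    fit = fit_ols(df["phi"].to_numpy(), np.log10(df["k"].to_numpy()))
    S = fit.slope
    log_kw = fit.intercept
    phi0 = -log_kw / S
    lo, hi = df["phi"].min(), df["phi"].max()
    warn = not (lo <= phi0 <= hi) or lo > 0.0  # log_kw always extrapolated
    return LipophilicityIndices(
        compound_id=str(df["compound_id"].iloc[0]),
        modifier=str(df["modifier"].iloc[0]),
        S=S,
        log_kw=log_kw,
        phi0=phi0,
        fit=fit,
        range_warning=bool(warn),
    )


def _one_series_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        df = measurements
    else:
        df = measurements_to_frame(measurements)
    if df.empty:
        raise InsufficientDataError("empty measurement series")
    if df["compound_id"].nunique() > 1 or df["modifier"].nunique() > 1:
        raise AmbiguousSeriesError(
            "series must contain exactly one compound and one modifier; got "
            f"{sorted(df['compound_id'].unique())} x {sorted(df['modifier'].unique())}"
        )
    return df


def similarity_regression(indices, modifier: str) -> LinearFit:
    """OLS of log k_w on S across compounds of one eluent system.

    For a congeneric series retained by the same intermolecular forces, S and
    log k_w are strongly collinear; the R^2 of this regression is the
    structural-similarity diagnostic.
    """
    sel = [ix for ix in indices if ix.modifier == modifier]
    others = {ix.modifier for ix in indices} - {modifier}
    if any(ix.modifier != modifier for ix in indices) and not sel:
        raise PairingError(f"no indices for modifier {modifier!r}; found {sorted(others)}")
    if len(sel) < 3:
        raise InsufficientDataError(
            f"need >= 3 compounds with indices for {modifier}, got {len(sel)}"
        )
    S = np.array([ix.S for ix in sel])
    log_kw = np.array([ix.log_kw for ix in sel])
    return fit_ols(S, log_kw)


def cross_system_regression(indices_a, indices_b, parameter: str) -> LinearFit:
    """OLS of a lipophilicity parameter in system A on the same parameter in B.

    ``parameter`` is one of 'log_kw', 'S', 'phi0'. Both index collections must
    cover the same compound set (pairing is by compound_id).
    """
    if parameter not in ("log_kw", "S", "phi0"):
        raise ValueError(f"parameter must be log_kw, S or phi0, got {parameter!r}")
    a = {ix.compound_id: getattr(ix, parameter) for ix in indices_a}
    b = {ix.compound_id: getattr(ix, parameter) for ix in indices_b}
    if set(a) != set(b):
        diff = sorted(set(a) ^ set(b))
        raise PairingError(f"compound sets differ between systems: {diff}")
    ids = sorted(a)
    return fit_ols(
        np.array([b[c] for c in ids]), np.array([a[c] for c in ids])
    )


class SoczewinskiModel:
    """Lipophilicity model for a whole cohort of isocratic retention series.

    Parameters
    ----------
    measurements
        RetentionMeasurement collection (or canonical DataFrame) holding, per
        compound and modifier, >= 3 phi levels at one temperature.

    ``fit()`` returns :class:`LipophilicityResults` with one
    :class:`LipophilicityIndices` per (compound, modifier) series.
    """

    def __init__(self, measurements):
        if isinstance(measurements, pd.DataFrame):
            self.data = measurements.copy()
        else:
            self.data = measurements_to_frame(measurements)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SoczewinskiModel":
        return cls(df)

    def fit(self) -> "LipophilicityResults":
        out = []
        for (_, _), grp in self.data.groupby(["compound_id", "modifier"], sort=True):
            out.append(fit_soczewinski(grp))
        return LipophilicityResults(out)


class LipophilicityResults:
    """Fitted lipophilicity indices for a cohort, with similarity and
    cross-system regressions as methods."""

    def __init__(self, indices: list[LipophilicityIndices]):
        self.indices = list(indices)

    def for_modifier(self, modifier: str) -> list[LipophilicityIndices]:
        return [ix for ix in self.indices if ix.modifier == modifier]

    def get(self, compound_id: str, modifier: str) -> LipophilicityIndices:
        for ix in self.indices:
            if ix.compound_id == compound_id and ix.modifier == modifier:
                return ix
        raise KeyError((compound_id, modifier))

    def similarity_regression(self, modifier: str) -> LinearFit:
        return similarity_regression(self.indices, modifier)

    def cross_system_regression(
        self, parameter: str, modifier_a: str = "MeOH", modifier_b: str = "ACN"
    ) -> LinearFit:
        return cross_system_regression(
            self.for_modifier(modifier_a), self.for_modifier(modifier_b), parameter
        )

    def to_frame(self) -> pd.DataFrame:
        """Table-shaped output: compound, modifier, S, log_kw, phi0 + diagnostics."""
        return pd.DataFrame([ix.to_dict() for ix in self.indices])

    def summary(self) -> str:
        lines = ["Soczewinski-Wachtmeister lipophilicity indices", ""]
        df = self.to_frame()
        cols = ["compound_id", "modifier", "S", "log_kw", "phi0", "fit_r2", "fit_s_e"]
        lines.append(df[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        for mod in sorted(df["modifier"].unique()):
            n = (df["modifier"] == mod).sum()
            if n >= 3:
                sim = self.similarity_regression(mod)
                lines.append("")
                lines.append(f"log k_w vs S ({mod}): {sim.summary().splitlines()[0]}")
                lines.append(f"  n = {sim.n}, R^2 = {sim.r2:.4f}")
        return "\n".join(lines)
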