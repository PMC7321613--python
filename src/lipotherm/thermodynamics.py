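"""Van't Hoff analysis of retention temperature series.

For an isocratic series at fixed modifier fraction phi, retention follows::

    ln k = -dH / (R T) + dS / R + ln PhaseRatio

A linear fit of ln k on 1/T gives dH = -R * slope. The intercept entropy is
biased by the unknown phase ratio (the stationary/mobile volume ratio of the
column): what R * intercept estimates is dS* = dS + R ln PhaseRatio. dS* is
always labelled "biased"; pairwise entropy *differences* between compounds
cancel the bias exactly. The Gibbs energy dG = dH - T dS* inherits the same
constant bias and is comparable across compounds on one column.

A linearity gate (R^2 > 0.9 by default) marks series whose van't Hoff plots
are trustworthy; curvature usually signals a phase-ratio or stationary-phase
change with temperature, and the derived parameters are then flagged rather
than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .exceptions import AmbiguousSeriesError, InsufficientDataError, LipothermError
from .lipophilicity import _one_series_frame
from .linreg import LinearFit, fit_ols

__all__ = [
    "GAS_CONSTANT",
    "VantHoffResult",
    "GibbsResult",
    "fit_vant_hoff",
    "gibbs_free_energy",
    "VantHoffModel",
    "ThermodynamicResults",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1

DEFAULT_T_REF = 293.15  # K; 20 degC column thermostat
LINEARITY_GATE = 0.9


@dataclass(frozen=True)
class VantHoffResult:
    """dH (J/mol) and phase-ratio-biased dS* (J/mol/K) for one series."""

    compound_id: str
    modifier: str
    phi: float
    dH: float
    dS_star: float
    fit: LinearFit
    linear_ok: bool

    def to_dict(self) -> dict:
        d = {
            "compound_id": self.compound_id,
            "modifier": self.modifier,
            "phi": self.phi,
            "dH_J_mol": self.dH,
            "dS_star_J_mol_K": self.dS_star,
            "linear_ok": self.linear_ok,
        }
        d.update({f"fit_{k}": v for k, v in self.fit.to_dict().items()})
        return d


@dataclass(frozen=True)
class GibbsResult:
    """dG = dH - t_ref * dS* (J/mol) at a stated reference temperature."""

    compound_id: str
    modifier: str
    t_ref: float
    dG: float

    def to_dict(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "modifier": self.modifier,
            "t_ref_K": self.t_ref,
            "dG_J_mol": self.dG,
        }


def fit_vant_hoff(
    measurements, r2_gate: float = LINEARITY_GATE, min_span: float = 20.0
) -> VantHoffResult:
    """OLS of ln k on 1/T for one compound+modifier at fixed phi.

    Requires >= 4 temperatures spanning at least ``min_span`` kelvin.
    """
    df = _one_series_frame(measurements)
    if df["phi"].nunique() > 1:
        raise AmbiguousSeriesError(
            f"mixed phi levels {sorted(df['phi'].unique())} in a van't Hoff series"
        )
    temps = df["temperature"].to_numpy(dtype=float)
    if df["temperature"].nunique() < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct temperatures, got {df['temperature'].nunique()}"
        )
    if temps.max() - temps.min() < min_span:
        raise InsufficientDataError(
            f"temperature span {temps.max() - temps.min():.1f} K below {min_span} K"
        )
    fit = fit_ols(1.0 / temps, np.log(df["k"].to_numpy(dtype=float)))
    return VantHoffResult(
        compound_id=str(df["compound_id"].iloc[0]),
        modifier=str(df["modifier"].iloc[0]),
        phi=float(df["phi"].iloc[0]),
        dH=-GAS_CONSTANT * fit.slope,
        dS_star=GAS_CONSTANT * fit.intercept,
        fit=fit,
        linear_ok=bool(fit.r2 > r2_gate),
    )


def gibbs_free_energy(
    vh: VantHoffResult, t_ref: float = DEFAULT_T_REF, allow_nonlinear: bool = False
) -> GibbsResult:
    """Gibbs-Helmholtz combination dG = dH - t_ref * dS*.

    Refuses series failing the linearity gate unless ``allow_nonlinear``
    (then a warning is emitted instead).
    """
    if t_ref < 0:
        raise LipothermError(f"t_ref={t_ref} K must be >= 0")
    if not vh.linear_ok:
        if not allow_nonlinear:
            raise LipothermError(
                f"van't Hoff fit for {vh.compound_id}/{vh.modifier} failed the "
                f"linearity gate (R^2 = {vh.fit.r2:.3f}); pass allow_nonlinear=True "
                "to override"
            )
        warnings.warn(
            f"computing dG from a non-linear van't Hoff fit "
            f"({vh.compound_id}/{vh.modifier}, R^2 = {vh.fit.r2:.3f})",
            stacklevel=2,
        )
    return GibbsResult(
        compound_id=vh.compound_id,
        modifier=vh.modifier,
        t_ref=float(t_ref),
        dG=vh.dH - t_ref * vh.dS_star,
    )


class VantHoffModel:
    """Van't Hoff model over a cohort of temperature series.

    Groups the measurements by (compound, modifier) — each group must sit at a
    single phi — and fits every series. ``fit()`` returns
    :class:`ThermodynamicResults`.
    """

    def __init__(self, measurements, r2_gate: float = LINEARITY_GATE):
        from .io import measurements_to_frame

        if isinstance(measurements, pd.DataFrame):
            self.data = measurements.copy()
        else:
            self.data = measurements_to_frame(measurements)
        self.r2_gate = r2_gate

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, r2_gate: float = LINEARITY_GATE):
        return cls(df, r2_gate=r2_gate)

    def fit(self) -> "ThermodynamicResults":
        results = [
            fit_vant_hoff(grp, r2_gate=self.r2_gate)
            for _, grp in self.data.groupby(["compound_id", "modifier"], sort=True)
        ]
        return ThermodynamicResults(results)


class ThermodynamicResults:
    """Fitted van't Hoff parameters for a cohort; dG on demand."""

    def __init__(self, results: list[VantHoffResult]):
        self.results = list(results)

    def get(self, compound_id: str, modifier: str) -> VantHoffResult:
        for r in self.results:
            if r.compound_id == compound_id and r.modifier == modifier:
                return r
        raise KeyError((compound_id, modifier))

    def gibbs(
        self, t_ref: float = DEFAULT_T_REF, allow_nonlinear: bool = False
    ) -> list[GibbsResult]:
        return [
            gibbs_free_energy(r, t_ref=t_ref, allow_nonlinear=allow_nonlinear)
            for r in self.results
            if r.linear_ok or allow_nonlinear
        ]

    def to_frame(self, t_ref: float = DEFAULT_T_REF) -> pd.DataFrame:
        """Table-shaped output in kJ/mol (dH, dG) and J/mol/K (dS*)."""
        rows = []
        for r in self.results:
            rows.append(
                {
                    "compound_id": r.compound_id,
                    "modifier": r.modifier,
                    "phi": r.phi,
                    "dH_kJ_mol": r.dH / 1e3,
                    "dS_star_J_mol_K": r.dS_star,
                    "dG_kJ_mol": (r.dH - t_ref * r.dS_star) / 1e3,
                    "r2": r.fit.r2,
                    "linear_ok": r.linear_ok,
                }
            )
        return pd.DataFrame(rows)

    def summary(self, t_ref: float = DEFAULT_T_REF) -> str:
        df = self.to_frame(t_ref)
        head = (
            f"van't Hoff thermodynamic parameters (t_ref = {t_ref} K; "
            "dS* biased by R ln PhaseRatio)"
        )
        return head + "\n\n" + df.to_string(index=False, float_format=lambda v: f"{v:.3f}")
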