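"""Molecular-difference selectivity analysis (Chester-Coym differencing).

For two structurally similar solutes measured on the same column, phase and
temperature grid, the selectivity alpha = k_high / k_low obeys::

    d ln(alpha) / d(1/T) = -dHd / R

where dHd is the partial molar transfer enthalpy of the *molecular
difference* between the pair (a heteroatom swap, a methylene linker, ...).
Because the phase ratio divides out of alpha, dHd is free of the phase-ratio
bias that afflicts single-compound van't Hoff intercepts. On a shared
temperature grid, dHd equals the difference of the two individually fitted
van't Hoff enthalpies exactly (OLS is linear in the response).

A stricter linearity gate (R^2 > 0.97 by default) marks pairs whose members
plausibly access the same stationary-phase volume.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .exceptions import PairingError
from .linreg import LinearFit, fit_ols
from .thermodynamics import GAS_CONSTANT, GibbsResult

__all__ = [
    "CompoundPair",
    "SelectivityResult",
    "selectivity_series",
    "delta_delta_g",
    "SelectivityModel",
    "SelectivityResults",
]

SELECTIVITY_GATE = 0.97


@dataclass(frozen=True)
class CompoundPair:
    """Ordered pair: ``id_low`` less retained, ``id_high`` more retained."""

    id_low: str
    id_high: str
    difference_label: str = ""

    def __post_init__(self):
        if self.id_low == self.id_high:
            raise PairingError(f"pair members must differ, got {self.id_low!r} twice")


@dataclass(frozen=True)
class SelectivityResult:
    """Transfer enthalpy of a molecular difference, with its ln alpha fit."""

    pair: CompoundPair
    modifier: str
    phi: float
    dHd: float  # J/mol
    fit: LinearFit
    linear_ok: bool

    def to_dict(self) -> dict:
        return {
            "id_low": self.pair.id_low,
            "id_high": self.pair.id_high,
            "difference_label": self.pair.difference_label,
            "modifier": self.modifier,
            "phi": self.phi,
            "dHd_kJ_mol": self.dHd / 1e3,
            "r2": self.fit.r2,
            "linear_ok": self.linear_ok,
        }


def selectivity_series(
    measurements, pair: CompoundPair, r2_gate: float = SELECTIVITY_GATE
) -> SelectivityResult:
    """Fit ln alpha vs 1/T for a declared pair on their shared grid.

    Members must share modifier and phi and >= 4 temperatures. The more
    retained member (higher mean ln k over the shared grid) is placed in the
    numerator so alpha >= 1 on average; dHd = -R * slope.
    """
    from .io import measurements_to_frame

    df = measurements if isinstance(measurements, pd.DataFrame) else measurements_to_frame(measurements)
    sub = df[df["compound_id"].isin([pair.id_low, pair.id_high])]
    mods = sorted(sub["modifier"].unique())
    if len(mods) != 1:
        raise PairingError(f"pair members measured in different modifiers: {mods}")
    phis = sorted(sub["phi"].unique())
    if len(phis) != 1:
        raise PairingError(f"pair members measured at different phi: {phis}")
    piv = sub.pivot_table(index="temperature", columns="compound_id", values="k")
    piv = piv.dropna()
    if piv.shape[1] != 2 or len(piv) < 4:
        raise PairingError(
            f"pair {pair.id_low}/{pair.id_high} shares only {len(piv)} "
            "temperatures (need >= 4 on a common grid)"
        )
    lnk = np.log(piv.to_numpy(dtype=float))
    means = dict(zip(piv.columns, lnk.mean(axis=0)))
    lo, hi = pair.id_low, pair.id_high
    if means[lo] > means[hi]:
        lo, hi = hi, lo
    elif means[lo] == means[hi]:
        lo, hi = sorted((lo, hi))
        warnings.warn(
            f"pair {pair.id_low}/{pair.id_high} has equal mean ln k; "
            "ordered lexicographically",
            stacklevel=2,
        )
    ordered = CompoundPair(id_low=lo, id_high=hi, difference_label=pair.difference_label)
    ln_alpha = np.log(piv[hi].to_numpy(dtype=float)) - np.log(piv[lo].to_numpy(dtype=float))
    fit = fit_ols(1.0 / piv.index.to_numpy(dtype=float), ln_alpha)
    return SelectivityResult(
        pair=ordered,
        modifier=mods[0],
        phi=phis[0],
        dHd=-GAS_CONSTANT * fit.slope,
        fit=fit,
        linear_ok=bool(fit.r2 > r2_gate),
    )


def delta_delta_g(g1: GibbsResult, g2: GibbsResult) -> float:
    """Pairwise |dG1 - dG2| in kJ/mol — a phase-ratio-independent selectivity
    measure; requires matching modifier and reference temperature."""
    if g1.modifier != g2.modifier:
        raise PairingError(f"modifiers differ: {g1.modifier} vs {g2.modifier}")
    if g1.t_ref != g2.t_ref:
        raise PairingError(f"reference temperatures differ: {g1.t_ref} vs {g2.t_ref}")
    return abs(g1.dG - g2.dG) / 1e3


class SelectivityModel:
    """Selectivity analysis over a declared pair list.

    Pairs are user-declared (structural-difference detection is out of scope);
    non-linear pairs are reported with ``linear_ok = False`` rather than
    dropped, so diagnostic plots remain possible.
    """

    def __init__(self, measurements, pairs: list[CompoundPair], r2_gate: float = SELECTIVITY_GATE):
        from .io import measurements_to_frame

        self.data = (
            measurements.copy()
            if isinstance(measurements, pd.DataFrame)
            else measurements_to_frame(measurements)
        )
        self.pairs = list(pairs)
        self.r2_gate = r2_gate

    def fit(self) -> "SelectivityResults":
        out = []
        for pair in self.pairs:
            for mod, grp in self.data[
                self.data["compound_id"].isin([pair.id_low, pair.id_high])
            ].groupby("modifier"):
                out.append(selectivity_series(grp, pair, r2_gate=self.r2_gate))
        return SelectivityResults(out)


class SelectivityResults:
    def __init__(self, results: list[SelectivityResult]):
        self.results = list(results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])

    def summary(self) -> str:
        head = "Molecular-difference transfer enthalpies (ln alpha vs 1/T)"
        return head + "\n\n" + self.to_frame().to_string(
            index=False, float_format=lambda v: f"{v:.3f}"
        )
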