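"""Synthetic retention / descriptor / activity cohorts with exported ground truth.

The generator emulates the statistical structure that the downstream analysis
assumes for a congeneric solute series on a glycopeptide (teicoplanin-type)
reversed-phase column:

* per compound and modifier, log10 k is linear in the modifier volume
  fraction phi (slope S < 0, intercept log k_w), with the S / log k_w pairs
  drawn collinearly (R^2 about 0.90 for methanol, 0.99 for acetonitrile) and
  the two systems' slopes strongly related, as observed for such series;
* per compound and modifier, ln k is linear in 1/T (van't Hoff), with the
  entropy intercept anchored so that the temperature series and the
  isocratic series agree at the reference point (phi_ref, t_ref) — this
  makes dG at t_ref equal to -R t_ref ln k(phi_ref, t_ref), landing the
  methanol-system dG range near -8..-5 kJ/mol;
* declared structural pairs (heteroatom swap with/without a methylene
  linker, methylene homologues) carry fixed transfer-enthalpy offsets of a
  few kJ/mol, more negative in methanol than acetonitrile;
* descriptors are affine in the methanol-system dG with noise solved to hit
  a target R^2 in expectation;
* ED50 is a two-component lognormal mixture (modes near 110 and 620 mg/kg,
  either side of the 350 mg/kg boundary) whose class is tied to phi0(MeOH)
  through a logistic link.

Measurement noise is applied to log10 k (multiplicative on k), total
sd 0.01 by default, consistent with near-unity R^2 of well-behaved isocratic
fits. It is decomposed into a systematic component shared by all compounds
measured under the same (modifier, phi, T) condition — eluent-batch, flow
and thermostat drifts dominate retention error in practice — and a small
independent injection-to-injection component (10% of the total sd). The
systematic part cancels in selectivity ratios alpha = k2/k1, which is why
well-matched pairs show the near-perfect ln alpha linearity the selectivity
gate expects even though single-series residuals are an order of magnitude
larger. Retention, descriptor and activity draws come from independently
spawned streams of the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .selectivity import CompoundPair
from .thermodynamics import GAS_CONSTANT

__all__ = [
    "SyntheticTruth",
    "generate_cohort",
    "generate_descriptors",
    "generate_activity",
    "DEFAULT_PHI_GRIDS",
    "DEFAULT_T_GRID",
]

LN10 = np.log(10.0)

DEFAULT_PHI_GRIDS = {
    "MeOH": (0.15, 0.20, 0.25, 0.30, 0.35, 0.40),
    "ACN": (0.05, 0.10, 0.15, 0.20, 0.25, 0.30),
}
DEFAULT_T_GRID = tuple(273.15 + t for t in (5, 10, 15, 20, 25, 30, 35, 40, 45))
DEFAULT_T_REF = 293.15
DEFAULT_PHI_REF = 0.15
DEFAULT_NOISE_SD = 0.01
INDEPENDENT_NOISE_FRACTION = 0.1  # share of the total sd that is per-injection
# Congeneric pair members move *along* the S / log k_w similarity line: the
# member carrying the extra methylene / heavier heteroatom is drawn with a
# lower S (ACN scale, decrement given per pair below, jitter sd 0.05) and
# shares its partner's deviations from the calibration maps. The decrement
# sets the pair's Gibbs-energy selectivity ddG at the reference point
# (~1.17 kJ/mol per unit decrement in the methanol system), putting
# heteroatom pairs near 1.3 kJ/mol and methylene pairs near 0.65 kJ/mol.
PAIR_DELTA_S_JITTER = 0.05

# S/log_kw calibration per system: S mean/sd and the log_kw = a*S + b map
# with the residual sd that yields the target collinearity.
_S_ACN_MEAN, _S_ACN_SD = -3.816, 0.55
_CROSS_S = (0.7682, 0.08605, 0.162)  # S_MeOH = a*S_ACN + b + N(0, sd)
_LOGKW_MAP = {
    "MeOH": (-0.4205, 0.4540, 0.063),
    "ACN": (-0.3359, 0.3145, 0.0203),
}
# Retention-linked enthalpy baseline, kJ/mol per unit log10 k_ref.
_DH_BASE = {"MeOH": (-5.0, -8.0, 0.8), "ACN": (-4.0, -5.0, 0.8)}  # (c0, c1, sd) kJ/mol

# Declared structural pairs: (label, low index, high index, dH offset J/mol
# per modifier, S decrement on the ACN scale). Offsets are the transfer
# enthalpies of the molecular difference.
_PAIR_SPECS = (
    ("heteroatom O->S", 0, 1, {"MeOH": -3770.0, "ACN": -2800.0}, 1.15),
    ("heteroatom O->S, methylene-linked", 2, 3, {"MeOH": -5460.0, "ACN": -3290.0}, 1.18),
    ("methylene linker", 4, 5, {"MeOH": -1710.0, "ACN": -930.0}, 0.56),
    ("methylene linker", 6, 7, {"MeOH": -3280.0, "ACN": -2260.0}, 0.56),
)

DEFAULT_DESCRIPTOR_R2 = {
    "polarizability": 0.86,
    "dft_binding_energy": 0.86,
    "docking_energy": 0.30,
    "ac_logp": 0.50,
    "bbb_score": 0.10,
}

DEFAULT_MIXTURE = {
    "active": {"median": 110.0, "sigma": 0.30},
    "inactive": {"median": 620.0, "sigma": 0.25},
}


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort; regenerating from it is byte-identical."""

    table: pd.DataFrame  # per-compound true parameters
    pairs: list  # CompoundPair declarations
    phi_grids: dict
    t_grid: tuple
    t_ref: float
    phi_ref: float
    noise_sd: float
    master_seed: int
    descriptor_r2: dict = field(default_factory=dict)
    mixture: dict = field(default_factory=dict)
    link_scale: float = 60.0

    def param(self, compound_id: str, name: str) -> float:
        return float(self.table.loc[compound_id, name])

    def to_dict(self) -> dict:
        return {
            "table": self.table.reset_index().to_dict(orient="records"),
            "pairs": [
                {"id_low": p.id_low, "id_high": p.id_high, "label": p.difference_label}
                for p in self.pairs
            ],
            "phi_grids": {k: list(v) for k, v in self.phi_grids.items()},
            "t_grid": list(self.t_grid),
            "t_ref": self.t_ref,
            "phi_ref": self.phi_ref,
            "noise_sd": self.noise_sd,
            "master_seed": self.master_seed,
            "descriptor_r2": self.descriptor_r2,
            "mixture": self.mixture,
            "link_scale": self.link_scale,
        }


def _spawn(seed: int, n: int = 3):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(
    n_compounds: int = 14,
    phi_grids: dict | None = None,
    t_grid=DEFAULT_T_GRID,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    t_ref: float = DEFAULT_T_REF,
    phi_ref: float = DEFAULT_PHI_REF,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a retention table plus its ground truth.

    The table holds, per compound and modifier, an isocratic series over the
    phi grid at ``t_ref`` and a temperature series over ``t_grid`` at
    ``phi_ref`` (the reference point itself comes from the isocratic series,
    so the (compound, modifier, phi, T) key stays unique). Noise sd applies
    to log10 k.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    phi_grids = dict(phi_grids or DEFAULT_PHI_GRIDS)
    for mod, grid in phi_grids.items():
        if len(set(grid)) < 3:
            raise ValueError(f"phi grid for {mod} must have >= 3 distinct levels")
    if len(set(t_grid)) < 4:
        raise ValueError("temperature grid must have >= 4 distinct levels")
    rng = _spawn(seed)[0]
    ids = [f"C{i + 1:02d}" for i in range(n_compounds)]

    pair_idx = [(lo, hi) for _, lo, hi, _, _ in _PAIR_SPECS if hi < n_compounds]
    pair_ds = [ds for _, lo, hi, _, ds in _PAIR_SPECS if hi < n_compounds]

    s_acn = _S_ACN_MEAN + _S_ACN_SD * rng.standard_normal(n_compounds)
    jitter = PAIR_DELTA_S_JITTER * rng.standard_normal(len(pair_idx))
    for (lo, hi), ds, j in zip(pair_idx, pair_ds, jitter):
        base = s_acn[lo]  # split the decrement symmetrically: cohort mean kept
        d = ds + j
        s_acn[lo] = base + d / 2.0
        s_acn[hi] = base - d / 2.0
    a, b, sd = _CROSS_S
    e_cross = sd * rng.standard_normal(n_compounds)
    for lo, hi in pair_idx:
        e_cross[hi] = e_cross[lo]  # congeners deviate from the map alike
    s_meoh = a * s_acn + b + e_cross
    S = {"MeOH": s_meoh, "ACN": s_acn}
    truth_rows = {cid: {"compound_id": cid} for cid in ids}

    for mod in ("MeOH", "ACN"):
        am, bm, sm = _LOGKW_MAP[mod]
        e_kw = sm * rng.standard_normal(n_compounds)
        for lo, hi in pair_idx:
            e_kw[hi] = e_kw[lo]
        log_kw = am * S[mod] + bm + e_kw
        # Because am + phi_ref < 0 in both systems, the lower-S pair member is
        # strictly more retained at the reference composition.
        log_k_ref = log_kw + S[mod] * phi_ref
        c0, c1, dh_sd = _DH_BASE[mod]
        dh = (c0 + c1 * log_k_ref + dh_sd * rng.standard_normal(n_compounds)) * 1e3
        for label, lo, hi, offsets, _ in _PAIR_SPECS:
            if hi < n_compounds:
                dh[hi] = dh[lo] + offsets[mod]
        ln_k_ref = LN10 * log_k_ref
        ds_star = GAS_CONSTANT * ln_k_ref + dh / t_ref  # anchors the vH line
        dg = dh - t_ref * ds_star
        for i, cid in enumerate(ids):
            truth_rows[cid].update(
                {
                    f"S_{mod}": S[mod][i],
                    f"log_kw_{mod}": log_kw[i],
                    f"phi0_{mod}": -log_kw[i] / S[mod][i],
                    f"dH_{mod}": dh[i],
                    f"dS_star_{mod}": ds_star[i],
                    f"dG_{mod}": dg[i],
                }
            )

    truth_table = pd.DataFrame([truth_rows[c] for c in ids]).set_index("compound_id")
    pairs = [
        CompoundPair(id_low=ids[lo], id_high=ids[hi], difference_label=label)
        for label, lo, hi, _, _ in _PAIR_SPECS
        if hi < n_compounds
    ]

    # Noise decomposition: a systematic offset per measurement condition
    # (shared by all compounds run under it) plus an independent
    # injection-level term; total variance = noise_sd^2.
    ind_sd = INDEPENDENT_NOISE_FRACTION * noise_sd
    sys_sd = float(np.sqrt(max(noise_sd**2 - ind_sd**2, 0.0)))
    conditions = []
    for mod in ("MeOH", "ACN"):
        conditions += [(mod, float(phi), t_ref) for phi in phi_grids[mod]]
        conditions += [
            (mod, float(phi_ref), float(T)) for T in t_grid if T != t_ref
        ]
    sys_noise = dict(zip(conditions, sys_sd * rng.standard_normal(len(conditions))))

    rows = []
    for cid in ids:
        for mod in ("MeOH", "ACN"):
            s = truth_table.loc[cid, f"S_{mod}"]
            lkw = truth_table.loc[cid, f"log_kw_{mod}"]
            dh = truth_table.loc[cid, f"dH_{mod}"]
            dss = truth_table.loc[cid, f"dS_star_{mod}"]
            for phi in phi_grids[mod]:
                eps = sys_noise[(mod, float(phi), t_ref)] + ind_sd * rng.standard_normal()
                log_k = lkw + s * phi + eps
                rows.append((cid, mod, float(phi), t_ref, 10.0 ** log_k))
            for T in t_grid:
                if T == t_ref:
                    continue  # reference point supplied by the isocratic series
                eps = sys_noise[(mod, float(phi_ref), float(T))] + ind_sd * rng.standard_normal()
                ln_k = -dh / (GAS_CONSTANT * T) + dss / GAS_CONSTANT + LN10 * eps
                rows.append((cid, mod, float(phi_ref), float(T), float(np.exp(ln_k))))
    measurements = pd.DataFrame(
        rows, columns=["compound_id", "modifier", "phi", "temperature", "k"]
    )
    assert (measurements["k"] > 0).all()

    truth = SyntheticTruth(
        table=truth_table,
        pairs=pairs,
        phi_grids=phi_grids,
        t_grid=tuple(t_grid),
        t_ref=t_ref,
        phi_ref=phi_ref,
        noise_sd=noise_sd,
        master_seed=int(seed),
        descriptor_r2=dict(DEFAULT_DESCRIPTOR_R2),
        mixture={k: dict(v) for k, v in DEFAULT_MIXTURE.items()},
    )
    return measurements, truth


# Affine maps descriptor = a + b * dG_MeOH(kJ/mol) + noise; magnitudes chosen
# to resemble the physical quantities (polarizability in A^3, energies in
# kJ/mol, log P and BBB unitless).
_DESCRIPTOR_MAPS = {
    "polarizability": (20.0, -2.0),
    "dft_binding_energy": (10.0, 2.5),
    "docking_energy": (-2.0, 0.5),
    "ac_logp": (-1.0, -0.6),
    "bbb_score": (0.5, -0.05),
}


def generate_descriptors(
    truth: SyntheticTruth, target_r2: dict | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Per-compound descriptor table correlated with the MeOH-system dG.

    Each descriptor is ``a + b * dG + noise`` with the noise variance solved
    so the squared correlation with dG equals ``target_r2`` in expectation
    (r2 = 1 -> exact affine map; r2 = 0 -> independent draws).
    """
    target_r2 = dict(truth.descriptor_r2 if target_r2 is None else target_r2)
    seed = truth.master_seed + 1 if seed is None else seed
    rng = np.random.default_rng(seed)
    dg = truth.table["dG_MeOH"].to_numpy() / 1e3  # kJ/mol
    sd_dg = float(np.std(dg, ddof=1)) if dg.size > 1 else 0.0
    out = {}
    for name, r2 in target_r2.items():
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"target r2 for {name} must be in [0, 1], got {r2}")
        a, b = _DESCRIPTOR_MAPS.get(name, (0.0, 1.0))
        if r2 == 0.0:
            out[name] = a + abs(b) * sd_dg * rng.standard_normal(dg.size)
            continue
        noise_sd = abs(b) * sd_dg * np.sqrt((1.0 - r2) / r2)
        out[name] = a + b * dg + noise_sd * rng.standard_normal(dg.size)
    df = pd.DataFrame(out, index=truth.table.index)
    df.index.name = "compound_id"
    return df


def generate_activity(
    truth: SyntheticTruth,
    mixture: dict | None = None,
    link_scale: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-compound ED50 records from a phi0(MeOH)-linked lognormal mixture.

    The active class (low dose) is drawn with probability
    ``sigmoid(link_scale * (phi0 - cohort median phi0))``; each class's ED50
    comes from its lognormal component. With the default components the
    350 mg/kg boundary lies between the modes.
    """
    mixture = {k: dict(v) for k, v in (mixture or truth.mixture or DEFAULT_MIXTURE).items()}
    link_scale = truth.link_scale if link_scale is None else link_scale
    seed = truth.master_seed + 2 if seed is None else seed
    rng = np.random.default_rng(seed)
    phi0 = truth.table["phi0_MeOH"].to_numpy()
    center = float(np.median(phi0))
    p_active = 1.0 / (1.0 + np.exp(-link_scale * (phi0 - center)))
    active = rng.random(phi0.size) < p_active
    ed50 = np.empty(phi0.size)
    for cls, mask in (("active", active), ("inactive", ~active)):
        comp = mixture[cls]
        ed50[mask] = comp["median"] * np.exp(
            comp["sigma"] * rng.standard_normal(int(mask.sum()))
        )
    df = pd.DataFrame(
        {
            "ed50": ed50,
            "class_label": np.where(active, "active", "inactive"),
        },
        index=truth.table.index,
    )
    df.index.name = "compound_id"
    return df
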