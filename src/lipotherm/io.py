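"""Tabular I/O for retention, descriptor and activity tables.

The canonical on-disk format is a long CSV, one retention measurement per row,
with columns ``compound_id, modifier, phi, temperature, k``. Arbitrary input
headers are mapped to these names through a dialect configuration (a plain
dict, typically loaded from YAML by the CLI), which also declares whether
temperatures are in degrees Celsius or kelvin and whether the modifier
fraction is a volume fraction or a percentage. Internally everything is
kelvin and volume fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = [
    "RetentionMeasurement",
    "retention_factor",
    "read_retention_table",
    "write_retention_table",
    "measurements_to_frame",
    "frame_to_measurements",
    "read_descriptor_table",
    "read_activity_table",
    "CELSIUS_OFFSET",
]

CELSIUS_OFFSET = 273.15

MODIFIERS = ("MeOH", "ACN")

RETENTION_COLUMNS = ("compound_id", "modifier", "phi", "temperature", "k")


@dataclass(frozen=True)
class RetentionMeasurement:
    """One (compound, modifier, phi, T, k) observation.

    ``phi`` is the organic-modifier volume fraction in [0, 1], ``temperature``
    is in kelvin, and ``k`` is the dimensionless retention factor
    (t_r - t_0) / t_0, strictly positive.
    """

    compound_id: str
    modifier: str
    phi: float
    temperature: float
    k: float

    def __post_init__(self):
        if self.modifier not in MODIFIERS:
            raise ValidationError(
                f"unknown modifier {self.modifier!r}; expected one of {MODIFIERS}"
            )
        if not 0.0 <= self.phi <= 1.0:
            raise ValidationError(f"phi={self.phi} outside [0, 1]")
        if self.temperature <= 0:
            raise ValidationError(f"temperature={self.temperature} K must be > 0")
        if not self.k > 0:
            raise ValidationError(f"k={self.k} must be > 0")


def retention_factor(t_r: float, t_0: float) -> float:
    """Retention factor k = (t_r - t_0) / t_0 from retention and hold-up times.

    Raises
    ------
    ValidationError
        If ``t_0 <= 0`` or ``t_r <= t_0`` (non-retained solute or
        mis-specified hold-up time).
    """
    if t_0 <= 0:
        raise ValidationError(f"hold-up time t_0={t_0} must be > 0")
    if t_r <= t_0:
        raise ValidationError(
            f"t_r={t_r} <= t_0={t_0}: solute not retained or hold-up mis-specified"
        )
    return (t_r - t_0) / t_0


def _apply_dialect(df: pd.DataFrame, dialect: dict | None) -> pd.DataFrame:
    dialect = dialect or {}
    mapping = dialect.get("columns", {})
    if mapping:
        df = df.rename(columns={v: k for k, v in mapping.items()})
    missing = [c for c in RETENTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"retention table is missing column(s): {', '.join(missing)}")
    df = df.loc[:, list(RETENTION_COLUMNS)].copy()
    unit = str(dialect.get("temperature_unit", "C")).upper()
    if unit in ("C", "CELSIUS", "°C"):
        df["temperature"] = df["temperature"].astype(float) + CELSIUS_OFFSET
    elif unit in ("K", "KELVIN"):
        df["temperature"] = df["temperature"].astype(float)
    else:
        raise SchemaError(f"unknown temperature unit {unit!r}; use 'C' or 'K'")
    if dialect.get("phi_as_percent", False):
        df["phi"] = df["phi"].astype(float) / 100.0
    return df


def frame_to_measurements(df: pd.DataFrame) -> list[RetentionMeasurement]:
    """Validate a canonical frame row by row into RetentionMeasurement records."""
    records: list[RetentionMeasurement] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            records.append(
                RetentionMeasurement(
                    compound_id=str(row["compound_id"]),
                    modifier=str(row["modifier"]),
                    phi=float(row["phi"]),
                    temperature=float(row["temperature"]),
                    k=float(row["k"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValidationError("invalid retention rows:\n" + "\n".join(errors))
    key = df[["compound_id", "modifier", "phi", "temperature"]]
    dup = key.duplicated()
    if dup.any():
        rows = list(df.index[dup])
        raise ValidationError(
            f"duplicated (compound, modifier, phi, T) at rows {rows}; "
            "replicates must be resolved by the caller"
        )
    return records


def read_retention_table(path, dialect: dict | None = None) -> list[RetentionMeasurement]:
    """Read a long-format retention CSV and validate it.

    ``dialect`` maps arbitrary headers to the canonical columns
    (``{"columns": {"compound_id": "Compound", ...}}``), declares
    ``temperature_unit`` ('C' by default, matching typical 5-45 degC column
    programs) and ``phi_as_percent``.
    """
    df = pd.read_csv(path)
    df = _apply_dialect(df, dialect)
    return frame_to_measurements(df)


def measurements_to_frame(measurements: Iterable[RetentionMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": m.compound_id,
                "modifier": m.modifier,
                "phi": m.phi,
                "temperature": m.temperature,
                "k": m.k,
            }
            for m in measurements
        ],
        columns=list(RETENTION_COLUMNS),
    )


def write_retention_table(measurements: Iterable[RetentionMeasurement], path) -> None:
    """Write measurements as canonical CSV (kelvin, volume fraction)."""
    measurements_to_frame(measurements).to_csv(path, index=False)


def read_descriptor_table(path) -> pd.DataFrame:
    """Read a per-compound descriptor table (polarizability, AC log P, BBB,
    docking / DFT binding energies, topological indices ... as numeric columns).

    One row per compound, indexed by ``compound_id``; missing cells stay NaN,
    never silently zero.
    """
    df = pd.read_csv(path)
    if "compound_id" not in df.columns:
        raise SchemaError("descriptor table is missing column: compound_id")
    if df["compound_id"].duplicated().any():
        raise ValidationError("descriptor table has duplicated compound_id rows")
    df = df.set_index("compound_id")
    if df.columns.duplicated().any():
        raise ValidationError("descriptor table has duplicated descriptor names")
    return df.astype(float)


def read_activity_table(path, threshold: float | None = None) -> pd.DataFrame:
    """Read per-compound ED50 activity records (mg/kg, > 0).

    If a ``class_label`` column is present and ``threshold`` is given, labels
    are checked for consistency with the ED50 < threshold -> 'active'
    convention.
    """
    df = pd.read_csv(path)
    for col in ("compound_id", "ed50"):
        if col not in df.columns:
            raise SchemaError(f"activity table is missing column: {col}")
    if (df["ed50"] <= 0).any():
        bad = list(df.index[df["ed50"] <= 0])
        raise ValidationError(f"non-positive ED50 at rows {bad}")
    if threshold is not None and "class_label" in df.columns:
        expected = np.where(df["ed50"] < threshold, "active", "inactive")
        mism = df["class_label"].notna() & (df["class_label"] != expected)
        if mism.any():
            raise ValidationError(
                f"class_label inconsistent with threshold {threshold} at rows "
                f"{list(df.index[mism])}"
            )
    return df.set_index("compound_id")
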