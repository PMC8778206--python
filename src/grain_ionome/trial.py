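"""Replicate-level trial table: validation, CSV I/O and aggregation.

One row per field plot: genotype, germplasm group, year, replicate, the
agronomic traits (days to heading, grain yield g/m², thousand-kernel
weight g, protein %) and the 15 grain element concentrations in µg/g dry
weight.  The analysis unit downstream is the genotype×year mean over
replicates, produced by :func:`aggregate_genotype_year_means`.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import ElementRegistry, default_registry

logger = logging.getLogger(__name__)

__all__ = [
    "KEY_COLUMNS",
    "AGRONOMIC_TRAITS",
    "GROUPS",
    "SchemaError",
    "TrialValidationError",
    "read_phenotype_table",
    "write_phenotype_table",
    "validate_records",
    "aggregate_genotype_year_means",
    "trait_columns",
]

KEY_COLUMNS = ["genotype", "group", "year", "rep"]
AGRONOMIC_TRAITS = ["dh", "yield", "tkw", "protein"]

GROUPS = (
    "CIMMYT_synthetic",
    "Japan_synthetic",
    "USA",
    "KASIB_early",
    "KASIB_intermediate",
    "KASIB_late",
    "check",
)


class SchemaError(ValueError):
    """A required column is missing or unrecognised."""


class TrialValidationError(ValueError):
    """A cell value or key violates the trial-table contract."""


def trait_columns(registry: ElementRegistry | None = None) -> list[str]:
    """Agronomic traits followed by the element codes — the full trait set."""
    registry = registry or default_registry()
    return AGRONOMIC_TRAITS + registry.codes


def _normalize_header(name: str, registry: ElementRegistry) -> str:
    """Map a raw CSV header to a canonical column name.

    Unit suffixes in parentheses are stripped; element codes match
    case-insensitively.
    """
    base = re.sub(r"\s*\(.*\)\s*$", "", name).strip()
    lowered = base.lower()
    for canonical in KEY_COLUMNS + AGRONOMIC_TRAITS:
        if lowered == canonical:
            return canonical
    for code in registry.codes:
        if lowered == code.lower():
            return code
    return base


def validate_records(
    df: pd.DataFrame,
    registry: ElementRegistry | None = None,
    strict: bool = True,
    allow_negative: bool = False,
) -> pd.DataFrame:
    """Validate a replicate-level table and return it with canonical dtypes.

    Parameters
    ----------
    df : DataFrame
        One row per plot with the required columns.
    registry : ElementRegistry, optional
        Element schema; defaults to the 15-element registry.
    strict : bool
        In strict mode missing cells are an error.  In permissive mode
        incomplete (genotype, year) units are dropped with a warning.
    allow_negative : bool
        Accept negative trait values.  Raw concentrations are
        nonnegative, but covariate-adjusted values (mean + residual)
        may dip below zero, so tables of adjusted data are read with
        this enabled.
    """
    registry = registry or default_registry()
    required = KEY_COLUMNS + trait_columns(registry)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")

    df = df[required].copy()
    df["year"] = df["year"].astype(int)
    df["rep"] = df["rep"].astype(int)
    df["genotype"] = df["genotype"].astype(str)
    df["group"] = df["group"].astype(str)

    bad_groups = sorted(set(df["group"]) - set(GROUPS))
    if bad_groups:
        raise TrialValidationError(f"unknown germplasm group(s): {bad_groups}")

    numeric = trait_columns(registry)
    for col in numeric:
        values = pd.to_numeric(df[col], errors="coerce")
        coerced_na = values.isna() & df[col].notna()
        if coerced_na.any():
            row = int(df.index[coerced_na][0])
            raise TrialValidationError(
                f"non-numeric value in column {col!r} at row {row}"
            )
        df[col] = values.astype(float)

    incomplete = df[numeric].isna().any(axis=1)
    if incomplete.any():
        if strict:
            row = int(df.index[incomplete][0])
            raise TrialValidationError(f"missing value at row {row} (strict mode)")
        bad_units = df.loc[incomplete, ["genotype", "year"]].drop_duplicates()
        logger.warning(
            "dropping %d incomplete (genotype, year) unit(s)", len(bad_units)
        )
        drop_keys = set(map(tuple, bad_units.to_numpy()))
        keep = ~df.set_index(["genotype", "year"]).index.map(
            lambda k: k in drop_keys
        )
        df = df[keep.to_numpy()]

    if not allow_negative:
        for col in numeric:
            neg = df[col] < 0
            if neg.any():
                row = int(df.index[neg][0])
                raise TrialValidationError(
                    f"negative value in column {col!r} at row {row}"
                )
    nonfinite = ~np.isfinite(df[numeric].to_numpy()).all(axis=1)
    if nonfinite.any():
        row = int(df.index[nonfinite][0])
        raise TrialValidationError(f"non-finite value at row {row}")
    bad_protein = (df["protein"] <= 0) | (df["protein"] >= 100)
    if bad_protein.any():
        row = int(df.index[bad_protein][0])
        raise TrialValidationError(f"protein outside (0, 100) at row {row}")

    dup = df.duplicated(subset=["genotype", "year", "rep"])
    if dup.any():
        key = df.loc[df.index[dup][0], ["genotype", "year", "rep"]].tolist()
        raise TrialValidationError(
            f"duplicate (genotype, year, rep) key: {tuple(key)}"
        )
    return df.reset_index(drop=True)


def read_phenotype_table(
    path: str | Path,
    registry: ElementRegistry | None = None,
    strict: bool = True,
    allow_negative: bool = False,
) -> pd.DataFrame:
    """Read and validate a replicate-level phenotype CSV.

    Headers are matched case-insensitively for element codes and may carry
    unit annotations in parentheses (stripped on read).  Values are taken
    as-is: concentrations in µg/g dry weight, yield in g/m², TKW in g,
    protein in percent.
    """
    registry = registry or default_registry()
    raw = pd.read_csv(path)
    raw.columns = [_normalize_header(c, registry) for c in raw.columns]
    return validate_records(
        raw, registry, strict=strict, allow_negative=allow_negative
    )


def write_phenotype_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a replicate-level table as RFC-4180 CSV ('.' decimal, UTF-8)."""
    df.to_csv(path, index=False)


def aggregate_genotype_year_means(
    records: pd.DataFrame, registry: ElementRegistry | None = None
) -> pd.DataFrame:
    """Collapse replicates to genotype×year arithmetic means.

    Returns one row per (genotype, year) carrying the group label and the
    mean of every trait over the available replicates.  Balanced and
    unbalanced inputs are both accepted here; balance is enforced where
    the ANOVA requires it.
    """
    registry = registry or default_registry()
    traits = [c for c in trait_columns(registry) if c in records.columns]
    if records.empty:
        return pd.DataFrame(columns=["genotype", "group", "year"] + traits)
    grouped = records.groupby(
        ["genotype", "group", "year"], as_index=False, sort=True
    )[traits].mean()
    return grouped
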