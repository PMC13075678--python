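"""Plot-level trial data model and I/O.

Observations from a two-sowing-date wheat trial are kept in long format:
one row per (genotype, condition, year, replicate, trait) with a numeric
value. ``condition`` is ``normal`` (fall sowing) or ``stress`` (late/spring
sowing imposing terminal heat). Yields are standardized to g/m² by dividing
plot mass by the harvested area (0.40 m² in the reference design, i.e. ×2.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("normal", "stress")
#: accepted aliases for the two sowing-date conditions
CONDITION_ALIASES = {
    "normal": "normal",
    "fall": "normal",
    "autumn": "normal",
    "nc": "normal",
    "stress": "stress",
    "spring": "stress",
    "hs": "stress",
}

LONG_COLUMNS = ["genotype", "condition", "year", "rep", "block", "trait", "value"]

#: trait codes used throughout, with units
STANDARD_TRAITS = {
    "DB": "days", "DF": "days", "DA": "days", "DM": "days",
    "PH": "cm", "PL": "cm", "SL": "cm",
    "TKW": "g", "TW": "kg/hL",
    "GY": "g/m2", "BY": "g/m2", "HI": "%",
    "PGP": "%", "ZSV": "mL", "GH": "%",
}


class TrialSchemaError(ValueError):
    """Input table does not conform to the long-format trial schema."""


class DuplicateKeyError(ValueError):
    """Two rows share (genotype, condition, year, rep, trait)."""


@dataclass
class TraitName:
    code: str
    units: str = ""


@dataclass
class TrialDataset:
    """Long-format plot-level observations plus inferred design counts.

    ``records`` has columns genotype, condition, year, rep, block, trait,
    value; one row per plot per trait, value possibly NaN for missing cells.
    """

    records: pd.DataFrame
    traits: list[TraitName] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in LONG_COLUMNS if c not in self.records.columns]
        if missing:
            raise TrialSchemaError(f"records missing columns: {missing}")
        if not self.traits:
            self.traits = [
                TraitName(t, STANDARD_TRAITS.get(t, ""))
                for t in self.records["trait"].unique()
            ]

    # -- design -----------------------------------------------------------
    @property
    def genotypes(self) -> list:
        return sorted(self.records["genotype"].unique())

    @property
    def design(self) -> dict:
        r = self.records
        return {
            "n_genotypes": r["genotype"].nunique(),
            "n_conditions": r["condition"].nunique(),
            "n_years": r["year"].nunique(),
            "n_reps": r["rep"].nunique(),
        }

    def trait_codes(self) -> list[str]:
        return [t.code for t in self.traits]

    def trait_table(self, trait: str, dropna: bool = True) -> pd.DataFrame:
        """Rows of one trait with genotype/condition/year/rep and value."""
        if trait not in set(self.records["trait"]):
            raise KeyError(f"trait {trait!r} not in dataset")
        out = self.records.loc[self.records["trait"] == trait,
                               ["genotype", "condition", "year", "rep", "value"]]
        return out.dropna(subset=["value"]) if dropna else out

    def is_balanced(self, trait: str) -> bool:
        """Every genotype × condition × year × rep cell present exactly once."""
        t = self.trait_table(trait)
        d = self.design
        expected = d["n_genotypes"] * d["n_conditions"] * d["n_years"] * d["n_reps"]
        if len(t) != expected:
            return False
        return not t.duplicated(["genotype", "condition", "year", "rep"]).any()


# -- unit standardization and derived traits ------------------------------

def standardize_yield(raw_mass, harvested_area: float):
    """Convert harvested plot mass (g) to areal yield (g/m²).

    The reference trial harvests the central 1.0 m of two 0.20 m-spaced rows,
    a 0.40 m² area, so masses are multiplied by 2.5.
    """
    if np.any(np.asarray(harvested_area) <= 0):
        raise ValueError("harvested_area must be positive")
    return np.asarray(raw_mass) / harvested_area if np.ndim(raw_mass) else raw_mass / harvested_area


def harvest_index(gy, by):
    """HI (%) = 100·GY/BY, per plot.

    Computed plot-wise and then averaged; the ratio of condition means is a
    different (Jensen-gapped) quantity and deliberately not used.
    """
    gy = np.asarray(gy, dtype=float)
    by = np.asarray(by, dtype=float)
    if np.any(by == 0):
        raise ValueError("biological yield must be positive")
    if np.any(gy > by):
        warnings.warn("grain yield exceeds biological yield for some plots "
                      "(biologically implausible)", stacklevel=2)
    out = 100.0 * gy / by
    return float(out) if out.ndim == 0 else out


def mean_reduction(mean_normal: float, mean_stress: float) -> float:
    """Percent decline of a trait mean under stress relative to normal."""
    if mean_normal == 0:
        raise ValueError("normal-condition mean must be nonzero")
    return 100.0 * (mean_normal - mean_stress) / mean_normal


def genotype_condition_means(ds: TrialDataset, trait: str) -> pd.DataFrame:
    """Per-genotype condition means (YP, YS) and panel means (XP, XS).

    YP/YS are unweighted arithmetic means over year × rep cells; XP/XS are
    unweighted means of the genotype means (under balance these equal the
    grand means of the raw plots). Genotypes missing an entire condition are
    excluded and listed in the returned frame's ``attrs['excluded']``.
    """
    t = ds.trait_table(trait)
    wide = (t.groupby(["genotype", "condition"])["value"].mean()
              .unstack("condition"))
    for c in CONDITIONS:
        if c not in wide.columns:
            wide[c] = np.nan
    excluded = wide.index[wide[list(CONDITIONS)].isna().any(axis=1)].tolist()
    kept = wide.drop(index=excluded)
    out = pd.DataFrame({
        "genotype": kept.index,
        "YP": kept["normal"].to_numpy(),
        "YS": kept["stress"].to_numpy(),
    }).reset_index(drop=True)
    out["XP"] = out["YP"].mean()
    out["XS"] = out["YS"].mean()
    out.attrs["excluded"] = excluded
    out.attrs["trait"] = trait
    return out


# -- I/O -------------------------------------------------------------------

_REQUIRED = ("genotype", "condition", "year", "rep")


def read_trial_csv(path, column_map: dict | None = None, sep: str = ",") -> TrialDataset:
    """Read a long-format trial CSV into a :class:`TrialDataset`.

    The header must name genotype, condition, year, rep and either a
    trait/value pair (canonical long form) or one column per trait (wide
    form, detected automatically). ``column_map`` renames non-canonical
    headers, e.g. ``{"sowing": "condition"}``.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise TrialSchemaError(f"missing required column(s): {missing}")
    df["condition"] = df["condition"].map(
        lambda c: CONDITION_ALIASES.get(str(c).strip().lower()))
    if df["condition"].isna().any():
        raise TrialSchemaError("unrecognized condition labels "
                               "(expect normal/stress or fall/spring)")
    if "block" not in df.columns:
        df["block"] = np.nan

    if "trait" in df.columns and "value" in df.columns:
        long = df[LONG_COLUMNS].copy()
    else:
        trait_cols = [c for c in df.columns if c not in _REQUIRED + ("block",)]
        if not trait_cols:
            raise TrialSchemaError("no trait columns found")
        long = df.melt(id_vars=list(_REQUIRED) + ["block"],
                       value_vars=trait_cols, var_name="trait",
                       value_name="value")[LONG_COLUMNS]

    bad = pd.to_numeric(long["value"], errors="coerce").isna() & long["value"].notna()
    if bad.any():
        rows = long.index[bad].tolist()[:5]
        raise TrialSchemaError(f"non-numeric trait value(s) at row(s) {rows}")
    long["value"] = pd.to_numeric(long["value"])

    dup = long.duplicated(["genotype", "condition", "year", "rep", "trait"])
    if dup.any():
        key = long.loc[dup.idxmax(), ["genotype", "condition", "year", "rep", "trait"]]
        raise DuplicateKeyError(f"duplicate observation for {key.to_dict()}")
    return TrialDataset(long.reset_index(drop=True))


def write_trial_csv(ds: TrialDataset, path, sep: str = ",") -> None:
    """Write the canonical long-format CSV; full float precision preserved."""
    ds.records.to_csv(path, sep=sep, index=False)


def round_half_away(x, ndigits: int = 0):
    """Round half away from zero (the convention of printed trial tables)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** ndigits
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out
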