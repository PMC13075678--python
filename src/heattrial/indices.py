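"""Yield-based stress tolerance and sensitivity indices.

From each genotype's mean grain yield under normal (YP) and heat-stress (YS)
sowing, and the panel means XP and XS, ten indices are computed:

    HSI = (1 − YS/YP) / (1 − XS/XP)      heat susceptibility index
    YSI = YS/YP                          yield stability index
    STI = YP·YS / XP²                    stress tolerance index
    TOL = YP − YS                        tolerance (absolute loss)
    MP  = (YP + YS)/2                    mean productivity
    GMP = √(YP·YS)                       geometric mean productivity
    YI  = YS/XS                          yield index
    HM  = 2·YP·YS/(YP + YS)              harmonic mean
    MRP = YS/XS + YP/XP                  mean relative performance
    PYR = 100·(YP − YS)/YP               percent yield reduction

Low HSI means tolerant; the productivity means satisfy HM ≤ GMP ≤ MP with
equality iff YP = YS. HSI is an affine function of YSI, so across any panel
corr(YSI, HSI) = −1 and corr(HSI, PYR) = +1 exactly. GMP is the geometric
mean proper; the raw product YP·YS (= STI·XP²) is exposed as ``gmp_raw``
for users replicating tables that print the unrooted form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INDEX_NAMES = ("TOL", "MP", "GMP", "HM", "HSI", "YSI", "STI", "YI", "MRP", "PYR")

#: selection direction per index: is a low value desirable?
LOW_IS_GOOD = {"HSI": True, "TOL": True, "PYR": True,
               "MP": False, "GMP": False, "HM": False, "STI": False,
               "YSI": False, "YI": False, "MRP": False,
               "YP": False, "YS": False}

CLASS_LABELS = ("tolerant", "semi_tolerant", "susceptible")


@dataclass
class HsiThresholds:
    """HSI class boundaries (both inclusive on the lower class)."""
    tolerant_max: float = 0.8
    susceptible_min: float = 1.3

    def __post_init__(self) -> None:
        if not self.tolerant_max < self.susceptible_min:
            raise ValueError("tolerant_max must be < susceptible_min")


def compute_indices(summaries: pd.DataFrame, xp: float | None = None,
                    xs: float | None = None) -> pd.DataFrame:
    """Build the full index table from per-genotype YP/YS summaries.

    ``summaries`` needs columns genotype, YP, YS. Panel means default to the
    table's own XP/XS columns, else the unweighted means of YP and YS; pass
    ``xp``/``xs`` explicitly when indexing a subset against full-panel means.
    """
    t = summaries[["genotype", "YP", "YS"]].copy().reset_index(drop=True)
    if xp is None:
        xp = float(summaries["XP"].iloc[0]) if "XP" in summaries else float(t["YP"].mean())
    if xs is None:
        xs = float(summaries["XS"].iloc[0]) if "XS" in summaries else float(t["YS"].mean())
    if xp <= 0 or xs <= 0:
        raise ValueError("panel means must be positive")
    if xp == xs:
        raise ValueError("XP == XS: HSI denominator (1 - XS/XP) is zero")

    yp = t["YP"].to_numpy(float)
    ys = t["YS"].to_numpy(float)
    if np.any(yp < 0) or np.any(ys < 0):
        raise ValueError("yields must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ysi = np.where(yp > 0, ys / yp, np.nan)
        t["TOL"] = yp - ys
        t["MP"] = (yp + ys) / 2.0
        t["GMP"] = np.sqrt(yp * ys)
        t["gmp_raw"] = yp * ys
        t["HM"] = np.where(yp + ys > 0, 2.0 * yp * ys / (yp + ys), 0.0)
        t["YSI"] = ysi
        t["HSI"] = (1.0 - ysi) / (1.0 - xs / xp)
        t["STI"] = yp * ys / xp ** 2
        t["YI"] = ys / xs
        t["MRP"] = ys / xs + yp / xp
        t["PYR"] = 100.0 * (1.0 - ysi)
    t["XP"], t["XS"] = xp, xs
    t.attrs["XP"], t.attrs["XS"] = xp, xs
    return t


def classify_by_hsi(table: pd.DataFrame,
                    thresholds: HsiThresholds | None = None) -> pd.DataFrame:
    """Label genotypes tolerant / semi_tolerant / susceptible by HSI.

    Boundaries are inclusive downward: HSI ≤ tolerant_max is tolerant,
    tolerant_max < HSI ≤ susceptible_min is semi-tolerant, above is
    susceptible. Genotypes with undefined HSI are labeled ``unclassified``.
    """
    thr = thresholds or HsiThresholds()
    out = table.copy()
    hsi = out["HSI"].to_numpy(float)
    out["class"] = np.select(
        [np.isnan(hsi), hsi <= thr.tolerant_max, hsi <= thr.susceptible_min],
        ["unclassified", "tolerant", "semi_tolerant"], "susceptible")
    return out


def composite_rank(table: pd.DataFrame,
                   indices: tuple[str, ...] = ("HSI", "MP", "STI"),
                   directions: dict | None = None) -> pd.DataFrame:
    """Mean-rank selection: low HSI prioritized jointly with high MP and STI.

    Each index is ranked (1 = best in its direction, ties averaged); the
    mean rank orders the output ascending, ties broken by lower HSI then
    genotype id.
    """
    dirs = dict(LOW_IS_GOOD)
    if directions:
        dirs.update(directions)
    unknown = [i for i in indices if i not in table.columns]
    if unknown:
        raise KeyError(f"unknown index column(s): {unknown}")
    out = table.copy()
    for idx in indices:
        out[f"rank_{idx}"] = out[idx].rank(ascending=dirs.get(idx, False),
                                           method="average")
    out["mean_rank"] = out[[f"rank_{i}" for i in indices]].mean(axis=1)
    sort_cols = ["mean_rank"] + (["HSI"] if "HSI" in out.columns else []) + ["genotype"]
    out = out.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    out["overall_rank"] = np.arange(1, len(out) + 1)
    return out


def hsi_mp_selection(table: pd.DataFrame) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Regress HSI on MP; select above-mean-MP genotypes lying below the line.

    Genotypes whose HSI falls below the fitted value at above-average MP
    combine high productivity with better-than-expected tolerance. Returns
    (selected rows, (slope, intercept)).
    """
    ok = table.dropna(subset=["HSI", "MP"])
    if len(ok) < 3:
        raise ValueError("need >=3 genotypes with defined HSI and MP")
    mp = ok["MP"].to_numpy(float)
    hsi = ok["HSI"].to_numpy(float)
    if np.ptp(mp) == 0:
        raise ValueError("MP has no variance; regression is degenerate")
    slope, intercept = np.polyfit(mp, hsi, 1)
    resid = hsi - (slope * mp + intercept)
    tol = 1e-9 * (np.abs(hsi).max() + 1.0)     # exact-line points are not "below"
    mask = (mp > mp.mean()) & (resid < -tol)
    sel = ok.loc[mask].copy()
    sel["hsi_residual"] = resid[mask]
    return sel, (float(slope), float(intercept))


def top_k_table(ranked: pd.DataFrame, k: int = 10, ndigits: int = 2) -> pd.DataFrame:
    """Printed-style top-k summary: Rank, Genotype, YP, YS, HSI, MP, STI."""
    from .dataset import round_half_away
    head = ranked.head(k)
    return pd.DataFrame({
        "Rank": np.arange(1, len(head) + 1),
        "Genotype": head["genotype"].to_numpy(),
        "YP": round_half_away(head["YP"].to_numpy(), 0),
        "YS": round_half_away(head["YS"].to_numpy(), 0),
        "HSI": round_half_away(head["HSI"].to_numpy(), ndigits),
        "MP": round_half_away(head["MP"].to_numpy(), 0),
        "STI": round_half_away(head["STI"].to_numpy(), ndigits),
    })
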