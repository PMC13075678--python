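"""Balanced combined ANOVA for two-sowing-date, multi-year RCBD trials.

The lattice trial is analyzed as an RCBD (inter-block effects negligible).
Sums of squares come from the exact mean decomposition of the balanced
layout, so the engine is closed-form: no design-matrix fitting. Sources for
the across-environment analysis are Y, SD, SD×Y, Rep(SD×Y), G, G×SD, G×Y,
G×SD×Y and Residual; per-condition analyses use Y, Rep(Y), G, G×Y, Residual.

F-test denominators follow the mixed-model logic with genotype and sowing
date fixed and year/replicate random: each fixed effect is tested against
its interaction with random year, random interactions against the residual.
The assignment is overridable per source.

Variance components are method-of-moments solutions of the expected mean
squares for the balanced per-condition design:

    sigma2_e  = MS_res
    sigma2_GY = (MS_GxY − MS_res) / r
    sigma2_G  = (MS_G − MS_GxY) / (r·y)

and broad-sense heritability on a genotype-mean basis is

    h2b = sigma2_G / (sigma2_G + sigma2_GY/y + sigma2_e/(r·y)),

reported as the sentinel "np" (non-predictive) when sigma2_G truncates to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import TrialDataset

NP_SENTINEL = "np"

COMBINED_ERROR_TERMS = {
    "Y": "SD*Y",
    "SD": "SD*Y",
    "SD*Y": "Residual",
    "Rep(SD*Y)": "Residual",
    "G": "G*Y",
    "G*SD": "G*SD*Y",
    "G*Y": "Residual",
    "G*SD*Y": "Residual",
}

PER_CONDITION_ERROR_TERMS = {
    "Y": "Rep(Y)",
    "Rep(Y)": "Residual",
    "G": "G*Y",
    "G*Y": "Residual",
}


class UnbalancedDataError(ValueError):
    """The requested ANOVA needs a fully balanced layout."""


@dataclass
class AnovaTable:
    table: pd.DataFrame          # source, df, SS, MS, F, p, error_term
    grand_mean: float
    r2: float
    cv_percent: float
    trait: str = ""
    condition: str | None = None

    def row(self, source: str) -> pd.Series:
        hit = self.table[self.table["source"] == source]
        if hit.empty:
            raise KeyError(f"no ANOVA source {source!r}")
        return hit.iloc[0]

    def ms(self, source: str) -> float:
        return float(self.row(source)["MS"])

    def formatted(self) -> pd.DataFrame:
        """Printed-table layout: MS with significance stars at 0.05/0.01."""
        out = self.table[["source", "df", "MS"]].copy()
        stars = []
        for _, r in self.table.iterrows():
            p = r["p"]
            if not np.isfinite(p):
                stars.append("")
            elif p < 0.01:
                stars.append("**")
            elif p < 0.05:
                stars.append("*")
            else:
                stars.append("ns")
        out["sig"] = stars
        return out


@dataclass
class VarianceComponents:
    sigma2_G: float
    sigma2_GxY: float
    sigma2_e: float
    raw: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


@dataclass
class HeritabilityEstimate:
    trait: str
    condition: str | None
    h2b: float | str            # in [0,1] or the "np" sentinel
    sigma2_P: float
    components: VarianceComponents


def _pivot(ds: TrialDataset, trait: str, condition: str | None = None) -> np.ndarray:
    t = ds.trait_table(trait)
    if condition is not None:
        t = t[t["condition"] == condition]
        if t.empty:
            raise KeyError(f"no data for condition {condition!r}")
    dims = [("genotype", sorted(t["genotype"].unique())),
            ("condition", sorted(t["condition"].unique())),
            ("year", sorted(t["year"].unique())),
            ("rep", sorted(t["rep"].unique()))]
    shape = tuple(len(v) for _, v in dims)
    if len(t) != int(np.prod(shape)) or t.duplicated(
            ["genotype", "condition", "year", "rep"]).any():
        raise UnbalancedDataError(
            f"trait {trait!r} is not balanced over genotype×condition×year×rep; "
            "see the exclusion report from genotype_condition_means")
    idx = {name: {v: i for i, v in enumerate(vals)} for name, vals in dims}
    arr = np.full(shape, np.nan)
    arr[tuple(t[name].map(idx[name]).to_numpy() for name, _ in dims)] = t["value"].to_numpy()
    return arr


def _finish(rows: list, y: np.ndarray, error_terms: dict, trait: str,
            condition: str | None) -> AnovaTable:
    df_tab = pd.DataFrame(rows, columns=["source", "df", "SS"])
    ss_total = float(np.sum((y - y.mean()) ** 2))
    df_total = y.size - 1
    resid_ss = ss_total - df_tab["SS"].sum()
    resid_df = df_total - df_tab["df"].sum()
    df_tab.loc[len(df_tab)] = ["Residual", resid_df, max(resid_ss, 0.0)]
    df_tab["MS"] = np.where(df_tab["df"] > 0, df_tab["SS"] / df_tab["df"].replace(0, 1), np.nan)

    ms = dict(zip(df_tab["source"], df_tab["MS"]))
    dfs = dict(zip(df_tab["source"], df_tab["df"]))
    F, p, err = [], [], []
    for src in df_tab["source"]:
        denom = error_terms.get(src)
        if denom is None or src == "Residual":
            F.append(np.nan), p.append(np.nan), err.append("")
            continue
        ms_d, df_d = ms[denom], dfs[denom]
        if ms_d == 0:
            f = np.inf if ms[src] > 0 else np.nan
        else:
            f = ms[src] / ms_d
        F.append(f)
        p.append(stats.f.sf(f, dfs[src], df_d) if np.isfinite(f) else
                 (0.0 if f == np.inf else np.nan))
        err.append(denom)
    df_tab["F"], df_tab["p"], df_tab["error_term"] = F, p, err

    gm = float(y.mean())
    ms_res = ms["Residual"]
    cv = 100.0 * np.sqrt(ms_res) / gm if gm != 0 else np.nan
    r2 = 1.0 - max(resid_ss, 0.0) / ss_total if ss_total > 0 else np.nan
    # conservation invariants, asserted on every run
    assert int(df_tab["df"].sum()) == df_total
    assert np.isclose(df_tab["SS"].sum(), ss_total, rtol=1e-9, atol=1e-8)
    return AnovaTable(df_tab, gm, r2, cv, trait=trait, condition=condition)


def combined_anova(ds: TrialDataset, trait: str,
                   error_terms: dict | None = None) -> AnovaTable:
    """Across-environment ANOVA over genotype × sowing date × year × rep."""
    y = _pivot(ds, trait)
    g, s, ny, r = y.shape
    if min(s, ny, r) < 2:
        raise UnbalancedDataError("need >=2 levels of condition, year and rep")
    gm = y.mean()
    m_i = y.mean(axis=(1, 2, 3)); m_j = y.mean(axis=(0, 2, 3))
    m_k = y.mean(axis=(0, 1, 3))
    m_ij = y.mean(axis=(2, 3)); m_ik = y.mean(axis=(1, 3)); m_jk = y.mean(axis=(0, 3))
    m_ijk = y.mean(axis=3); m_jkl = y.mean(axis=0)

    rows = [
        ("Y", ny - 1, g * s * r * np.sum((m_k - gm) ** 2)),
        ("SD", s - 1, g * ny * r * np.sum((m_j - gm) ** 2)),
        ("SD*Y", (s - 1) * (ny - 1),
         g * r * np.sum((m_jk - m_j[:, None] - m_k[None, :] + gm) ** 2)),
        ("Rep(SD*Y)", s * ny * (r - 1),
         g * np.sum((m_jkl - m_jk[:, :, None]) ** 2)),
        ("G", g - 1, s * ny * r * np.sum((m_i - gm) ** 2)),
        ("G*SD", (g - 1) * (s - 1),
         ny * r * np.sum((m_ij - m_i[:, None] - m_j[None, :] + gm) ** 2)),
        ("G*Y", (g - 1) * (ny - 1),
         s * r * np.sum((m_ik - m_i[:, None] - m_k[None, :] + gm) ** 2)),
        ("G*SD*Y", (g - 1) * (s - 1) * (ny - 1),
         r * np.sum((m_ijk - m_ij[:, :, None] - m_ik[:, None, :] - m_jk[None, :, :]
                     + m_i[:, None, None] + m_j[None, :, None] + m_k[None, None, :]
                     - gm) ** 2)),
    ]
    return _finish([(s_, d, float(ss)) for s_, d, ss in rows], y,
                   error_terms or COMBINED_ERROR_TERMS, trait, None)


def per_condition_anova(ds: TrialDataset, trait: str, condition: str,
                        error_terms: dict | None = None) -> AnovaTable:
    """Single-condition ANOVA: Y, Rep(Y), G, G×Y, Residual."""
    y = _pivot(ds, trait, condition)[:, 0, :, :]   # genotype × year × rep
    g, ny, r = y.shape
    gm = y.mean()
    m_i = y.mean(axis=(1, 2)); m_k = y.mean(axis=(0, 2))
    m_ik = y.mean(axis=2); m_kl = y.mean(axis=0)
    rows = [
        ("Y", ny - 1, g * r * np.sum((m_k - gm) ** 2)),
        ("Rep(Y)", ny * (r - 1), g * np.sum((m_kl - m_k[:, None]) ** 2)),
        ("G", g - 1, ny * r * np.sum((m_i - gm) ** 2)),
        ("G*Y", (g - 1) * (ny - 1),
         r * np.sum((m_ik - m_i[:, None] - m_k[None, :] + gm) ** 2)),
    ]
    return _finish([(s_, d, float(ss)) for s_, d, ss in rows], y,
                   error_terms or PER_CONDITION_ERROR_TERMS, trait, condition)


def variance_components(table: AnovaTable, n_years: int, n_reps: int) -> VarianceComponents:
    """EMS solution for a per-condition table (sources G, G*Y, Residual)."""
    for src in ("G", "G*Y", "Residual"):
        table.row(src)     # raises if missing
    ms_res = table.ms("Residual")
    raw = {
        "sigma2_e": ms_res,
        "sigma2_GxY": (table.ms("G*Y") - ms_res) / n_reps,
        "sigma2_G": (table.ms("G") - table.ms("G*Y")) / (n_reps * n_years),
    }
    flags = {k: ("ok" if v >= 0 else "truncated") for k, v in raw.items()}
    trunc = {k: max(v, 0.0) for k, v in raw.items()}
    return VarianceComponents(trunc["sigma2_G"], trunc["sigma2_GxY"],
                              trunc["sigma2_e"], raw=raw, flags=flags)


def broad_sense_heritability(vc: VarianceComponents, n_years: int, n_reps: int,
                             trait: str = "", condition: str | None = None
                             ) -> HeritabilityEstimate:
    """h2b on a genotype-mean basis; "np" when genotypic variance truncates."""
    sigma2_P = vc.sigma2_G + vc.sigma2_GxY / n_years + vc.sigma2_e / (n_reps * n_years)
    if vc.flags.get("sigma2_G") == "truncated" or vc.sigma2_G == 0:
        h2b: float | str = NP_SENTINEL
    elif sigma2_P == 0:
        h2b = NP_SENTINEL
    else:
        h2b = vc.sigma2_G / sigma2_P
    return HeritabilityEstimate(trait, condition, h2b, sigma2_P, vc)


def lsd(ms_error: float, df_error: int, n_per_mean: int, alpha: float = 0.05) -> float:
    """Fisher's least significant difference for pairwise mean comparison."""
    if ms_error < 0:
        raise ValueError("ms_error must be >= 0")
    if df_error < 1 or n_per_mean < 1:
        raise ValueError("df_error and n_per_mean must be >= 1")
    t = stats.t.ppf(1 - alpha / 2, df_error)
    return float(t * np.sqrt(2.0 * ms_error / n_per_mean))


def screen_outliers(ds: TrialDataset, trait: str, threshold: float = 3.0) -> pd.DataFrame:
    """Flag plots with |externally studentized residual| > threshold.

    A preliminary RCBD fit (genotype + replicate) is made within each
    condition × year; flagged rows are returned for inspection — nothing is
    removed, since removal is an explicit scientific decision.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.outliers_influence import OLSInfluence

    t = ds.trait_table(trait).copy()
    flagged = []
    for (cond, yr), grp in t.groupby(["condition", "year"]):
        if grp["genotype"].nunique() < 2 or grp["rep"].nunique() < 2:
            continue
        fit = smf.ols("value ~ C(genotype) + C(rep)", data=grp).fit()
        scale = max(grp["value"].var(ddof=0), 1.0)
        if fit.mse_resid < 1e-10 * scale:      # perfect fit: nothing to flag
            continue
        rstud = OLSInfluence(fit).resid_studentized_external
        hits = grp.loc[np.abs(rstud) > threshold].copy()
        hits["rstudent"] = rstud[np.abs(rstud) > threshold]
        flagged.append(hits)
    if not flagged:
        return pd.DataFrame(columns=list(t.columns) + ["rstudent"])
    return pd.concat(flagged).sort_values("rstudent", key=np.abs, ascending=False)
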