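"""Pearson correlation matrices with significance stars, and PCA biplot inputs.

Correlations among traits are computed on genotype means within a condition
(one value per genotype, matching how multi-environment trial tables report
a single r per trait pair per condition); index correlations run across the
whole panel. PCA standardizes complete cases to z-scores and
eigen-decomposes the correlation matrix, with a deterministic sign
convention so loadings are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame      # "ns", "*", "**" (or "" on the diagonal/undefined)

    def star_annotated(self, ndigits: int = 2) -> pd.DataFrame:
        txt = self.r.round(ndigits).astype(str)
        return txt + self.stars.where(self.stars.isin(["*", "**"]), "")


@dataclass
class PcaResult:
    loadings: pd.DataFrame       # variables × components, orthonormal columns
    scores: pd.DataFrame         # observations × components
    explained_variance: np.ndarray
    explained_ratio: np.ndarray


def pearson_matrix(table: pd.DataFrame, variables: list[str] | None = None
                   ) -> CorrelationMatrix:
    """Pairwise Pearson r on complete cases, two-sided p from the t transform.

    Zero-variance variables get NaN correlations (flagged by empty stars),
    not an error, so one degenerate column cannot sink a whole report.
    """
    cols = variables or [c for c in table.columns
                         if pd.api.types.is_numeric_dtype(table[c])]
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    for a in range(k):
        n[a, a] = table[cols[a]].notna().sum()
        for b in range(a + 1, k):
            pair = table[[cols[a], cols[b]]].dropna()
            n[a, b] = n[b, a] = len(pair)
            if len(pair) < 3 or pair[cols[a]].nunique() < 2 or pair[cols[b]].nunique() < 2:
                r[a, b] = r[b, a] = np.nan
                p[a, b] = p[b, a] = np.nan
                continue
            rr, pp = stats.pearsonr(pair[cols[a]], pair[cols[b]])
            r[a, b] = r[b, a] = rr
            p[a, b] = p[b, a] = pp
    star = np.full((k, k), "ns", dtype=object)
    star[p < 0.05] = "*"
    star[p < 0.01] = "**"
    star[np.isnan(p)] = ""
    np.fill_diagonal(star, "")
    wrap = lambda m: pd.DataFrame(m, index=cols, columns=cols)
    return CorrelationMatrix(cols, wrap(r), wrap(p), wrap(n), wrap(star))


def pca(table: pd.DataFrame, variables: list[str] | None = None,
        standardize: bool = True, n_components: int | None = None) -> PcaResult:
    """PCA of genotype-mean data via eigen-decomposition.

    Standardized mode (default) decomposes the correlation matrix of
    complete cases; otherwise the covariance matrix. Within each component
    the sign is fixed so the largest-magnitude loading is positive.
    """
    cols = variables or [c for c in table.columns
                         if pd.api.types.is_numeric_dtype(table[c])]
    if len(cols) < 2:
        raise ValueError("PCA needs at least two variables")
    data = table[cols].dropna()
    X = data.to_numpy(float)
    mu = X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        constant = [c for c, s in zip(cols, sd) if s == 0]
        if constant:
            raise ValueError(f"constant column(s) under standardization: {constant}")
        Z = (X - mu) / sd
        C = np.corrcoef(Z, rowvar=False)
    else:
        Z = X - mu
        C = np.cov(Z, rowvar=False)

    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(evecs.shape[1]):
        pivot = np.argmax(np.abs(evecs[:, j]))
        if evecs[pivot, j] < 0:
            evecs[:, j] = -evecs[:, j]

    if n_components is not None:
        evals, evecs = evals[:n_components], evecs[:, :n_components]
    comp_names = [f"PC{i + 1}" for i in range(evecs.shape[1])]
    scores = Z @ evecs
    total = np.trace(C)
    return PcaResult(
        loadings=pd.DataFrame(evecs, index=cols, columns=comp_names),
        scores=pd.DataFrame(scores, index=data.index, columns=comp_names),
        explained_variance=evals,
        explained_ratio=evals / total if total > 0 else evals,
    )


def biplot_coordinates(res: PcaResult, components: tuple[int, int] = (1, 2),
                       loading_scale: float | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scores and scaled loadings for the chosen component pair, ready to plot."""
    names = [f"PC{c}" for c in components]
    sc = res.scores[names]
    if loading_scale is None:
        span = sc.abs().to_numpy().max()
        lmax = res.loadings[names].abs().to_numpy().max()
        loading_scale = 0.8 * span / lmax if lmax > 0 else 1.0
    return sc, res.loadings[names] * loading_scale
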