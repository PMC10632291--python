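"""Unweighted and weighted multiple linear regression of line means on
marker designs, per-triple aaa effects, and variance-explained accounting.

The unweighted estimate is the ordinary least-squares solution

    alpha_u = (G'G)^{-1} G'y

and the weighted estimate uses the diagonal matrix of per-line replicate
variances w_ii (empirically estimated from the phenotype replicates):

    alpha_w = (G' W^{-1} G)^{-1} G' W^{-1} y ,   W = diag(w_ii).

The coefficient vector alpha = (mu, beta, gamma, delta) carries the grand
mean, additive effects a_l, pairwise epistasis aa and three-way epistasis
aaa coefficients. The total three-way effect of a trait is the plain sum of
its per-triple aaa coefficients (by default restricted to triples
significant at p < 0.001, matching how significant triples are counted).

Coefficient covariances are the classical sigma2 * (G'W^{-1}G)^{-1} with
sigma2 the (weighted) residual mean square: the empirical w_ii are treated
as relative, not absolute, variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import ModelDesign, Term

TRIPLE_ALPHA = 0.001  # significance level for counting/reporting triples


@dataclass
class ModelFit:
    """A fitted (possibly weighted) linear model on a marker design."""

    design: ModelDesign
    coef: np.ndarray
    cov: np.ndarray
    resid: np.ndarray
    sigma2: float
    df_resid: int
    weights: np.ndarray        # regression weights (1/w_ii), unit if unweighted
    rss: float
    tss: float                 # (weighted) total SS about the (weighted) mean
    r2: float
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def terms(self) -> list[Term]:
        return self.design.terms

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def coef_of(self, term: Term) -> float:
        return float(self.coef[self.terms.index(term)])

    def coefficient_tests(self) -> pd.DataFrame:
        """Two-sided t tests per coefficient: t = estimate / SE."""
        if self.df_resid < 1:
            raise ValueError("no residual degrees of freedom")
        se = self.se
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, self.coef / se, np.where(self.coef == 0, 0.0, np.inf))
        p = 2.0 * stats.t.sf(np.abs(t), self.df_resid)
        p[self.coef == 0.0] = 1.0
        return pd.DataFrame({"term": self.terms, "estimate": self.coef,
                             "se": se, "t": t, "p": p})


def _fit(y: np.ndarray, design: ModelDesign, weights: np.ndarray) -> ModelFit:
    G = design.G
    n, k = G.shape
    if n <= k:
        raise ValueError(f"need n > number of columns ({n} <= {k})")
    rank = np.linalg.matrix_rank(G)
    if rank < k:
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {k} columns); "
            "run check_full_rank / drop_aliased first"
        )
    model = sm.WLS(y, G, weights=weights)
    res = model.fit()
    w = weights
    fitted = res.fittedvalues
    resid = y - fitted
    rss = float(w @ resid ** 2)
    wmean = float(w @ y / w.sum())
    tss = float(w @ (y - wmean) ** 2)
    return ModelFit(
        design=design,
        coef=np.asarray(res.params, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        resid=resid,
        sigma2=float(res.scale),
        df_resid=int(res.df_resid),
        weights=w,
        rss=rss,
        tss=tss,
        r2=1.0 - rss / tss if tss > 0 else 0.0,
        fitted=fitted,
    )


def fit_unweighted(y, design: ModelDesign) -> ModelFit:
    """Ordinary least squares: alpha = (G'G)^{-1} G'y."""
    y = np.asarray(y, dtype=float)
    return _fit(y, design, np.ones(y.size))


def fit_weighted(y, design: ModelDesign, line_variances) -> ModelFit:
    """Weighted least squares with weights 1/w_ii from per-line variances."""
    y = np.asarray(y, dtype=float)
    w_ii = np.asarray(line_variances, dtype=float)
    if w_ii.shape != y.shape:
        raise ValueError("line_variances must match y in length")
    if (w_ii <= 0).any() or np.isnan(w_ii).any():
        raise ValueError("all line variances must be strictly positive")
    return _fit(y, design, 1.0 / w_ii)


def total_aaa(fit: ModelFit, which: str = "significant_only",
              alpha: float = TRIPLE_ALPHA):
    """Total three-way epistasis: the sum over triple coefficients.

    ``which``: 'significant_only' (default; triples with p < alpha, the
    convention used when counting significant triples) or 'all_retained'.
    Returns ``(total, min, max, count)``; (0, nan, nan, 0) with no triples.
    """
    idx = fit.design.columns_of("triple")
    if which == "significant_only" and idx:
        tests = fit.coefficient_tests()
        idx = [j for j in idx if tests["p"].iloc[j] < alpha]
    elif which not in ("significant_only", "all_retained"):
        raise ValueError("which must be 'significant_only' or 'all_retained'")
    if not idx:
        return 0.0, float("nan"), float("nan"), 0
    eff = fit.coef[idx]
    return float(eff.sum()), float(eff.min()), float(eff.max()), len(idx)


def triple_variance_explained(y, design: ModelDesign, fit: ModelFit,
                              triple: Term) -> float:
    """Percent of phenotypic variance attributable to one triple.

    100 * (RSS without the triple column - RSS of the full model) / TSS,
    all in the fit's weighting (weighted TSS about the weighted mean).
    """
    y = np.asarray(y, dtype=float)
    if triple not in fit.terms:
        raise KeyError(f"{triple} not in the fitted model")
    j = fit.terms.index(triple)
    reduced = design.subset([i for i in range(len(fit.terms)) if i != j])
    red_fit = _fit(y, reduced, fit.weights)
    pct = 100.0 * (red_fit.rss - fit.rss) / fit.tss if fit.tss > 0 else 0.0
    return max(pct, 0.0)


def coefficient_tests(fit: ModelFit) -> pd.DataFrame:
    return fit.coefficient_tests()
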