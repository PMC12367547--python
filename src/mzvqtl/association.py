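"""Per-SNP variance-QTL association statistics.

Two estimators are implemented:

* the MZ-differences regression: the prepared absolute within-pair difference
  is regressed on the shared pair genotype (optionally with the within-pair
  phenotype mean as a covariate, model 2);
* the population-based deviation regression model (DRM): absolute deviations
  of the phenotype from its genotype-group median are regressed on genotype.

Both use ordinary least squares with a t reference on n - k degrees of
freedom.  A sign test compares effect directions between two result tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AssocResult", "mz_diff_test", "drm_test", "sign_concordance_test"]


@dataclass(frozen=True)
class AssocResult:
    """Slope, standard error and two-sided p-value for one variant."""

    snp_id: str
    beta: float
    se: float
    p: float
    n: int
    testable: bool = True


def _ols_last(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int]:
    """OLS of y on X; slope/SE/p of the LAST column, t reference on n-k df."""
    n, k = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    coef = XtX_inv @ (X.T @ y)
    resid = y - X @ coef
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    se = float(np.sqrt(sigma2 * XtX_inv[-1, -1]))
    beta = float(coef[-1])
    p = float(2.0 * stats.t.sf(abs(beta / se), dof)) if se > 0 else np.nan
    return beta, se, p, dof


def _slope_p(g: np.ndarray, d: np.ndarray) -> tuple[float, float, float]:
    """Fast simple regression of d on (1, g); returns slope, SE, p."""
    n = g.size
    gc = g - g.mean()
    sxx = float(gc @ gc)
    beta = float(gc @ d) / sxx
    resid = d - d.mean() - beta * gc
    se = float(np.sqrt(float(resid @ resid) / (n - 2) / sxx))
    p = float(2.0 * stats.t.sf(abs(beta / se), n - 2))
    return beta, se, p


def mz_diff_test(
    prepared: np.ndarray,
    G: np.ndarray,
    model: int = 1,
    pair_mean: Optional[np.ndarray] = None,
    snp_id: str = "snp",
) -> AssocResult:
    """Regress the prepared MZ-differences score on the pair genotype.

    ``G`` may be hard calls in {0, 1, 2} or imputed dosage in [0, 2].  Model 2
    adds ``pair_mean`` as a covariate; models 1 and 3 differ only in how the
    phenotype was prepared, not in the regression.
    """
    d = np.asarray(prepared, dtype=float)
    g = np.asarray(G, dtype=float)
    if d.shape != g.shape:
        raise ValueError("prepared score and genotype vectors must have equal length")
    if model == 2:
        if pair_mean is None:
            raise ValueError("model 2 requires the within-pair phenotype mean")
    elif pair_mean is not None:
        raise ValueError("pair_mean is only used by model 2")
    n = g.size
    if np.ptp(g) == 0.0:
        return AssocResult(snp_id, np.nan, np.nan, np.nan, n, testable=False)
    if model == 2:
        X = np.column_stack([np.ones(n), np.asarray(pair_mean, dtype=float), g])
        beta, se, p, _ = _ols_last(X, d)
    else:
        beta, se, p = _slope_p(g, d)
    return AssocResult(snp_id, beta, se, p, n)


def drm_test(
    y: np.ndarray,
    G: np.ndarray,
    min_group_size: int = 10,
    center: str = "median",
    snp_id: str = "snp",
) -> AssocResult:
    """Deviation regression model: |y - center_g| regressed on genotype.

    Genotype groups are the hard calls rounded from ``G`` (dosages are
    rounded for grouping; the regression uses the rounded calls).  Groups
    smaller than ``min_group_size`` are excluded; if fewer than two groups
    remain the variant is flagged untestable.
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    y = np.asarray(y, dtype=float)
    g = np.rint(np.asarray(G, dtype=float)).astype(np.int64)
    if y.shape != g.shape:
        raise ValueError("y and G must have equal length")
    gmin = g.min()
    g0 = g - gmin
    counts = np.bincount(g0)
    vals = np.nonzero(counts >= min_group_size)[0]
    if len(vals) < 2:
        return AssocResult(snp_id, np.nan, np.nan, np.nan, int(counts[vals].sum()), testable=False)
    centre_of = np.full(counts.size, np.nan)
    for v in vals:
        grp = y[g0 == v]
        centre_of[v] = np.median(grp) if center == "median" else grp.mean()
    if len(vals) == counts.size:  # every group usable: no row filtering needed
        d = np.abs(y - centre_of[g0])
        beta, se, p = _slope_p(g.astype(float), d)
        return AssocResult(snp_id, beta, se, p, y.size)
    kept = counts[g0] >= min_group_size
    d = np.abs(y[kept] - centre_of[g0[kept]])
    beta, se, p = _slope_p(g[kept].astype(float), d)
    return AssocResult(snp_id, beta, se, p, int(kept.sum()))


def sign_concordance_test(
    results_a: pd.DataFrame, results_b: pd.DataFrame
) -> dict[str, float]:
    """Cross-model concordance of effect signs over the shared SNPs.

    Expects tables with ``snp`` (or ``snp_id``), ``beta`` and ``p`` columns.
    Reports the fraction of shared SNPs with matching sign, an exact binomial
    p-value against 0.5, and Spearman correlations of beta and -log10(p).
    """
    def _norm(df: pd.DataFrame) -> pd.DataFrame:
        key = "snp" if "snp" in df.columns else "snp_id"
        return df.set_index(key)[["beta", "p"]]

    a = _norm(results_a)
    b = _norm(results_b)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("the two result tables share no SNPs")
    a, b = a.loc[shared], b.loc[shared]
    match = np.sign(a["beta"].to_numpy()) == np.sign(b["beta"].to_numpy())
    k = int(match.sum())
    n = len(shared)
    binom_p = stats.binomtest(k, n, 0.5).pvalue
    rho_beta = stats.spearmanr(a["beta"], b["beta"]).statistic
    rho_logp = stats.spearmanr(-np.log10(a["p"]), -np.log10(b["p"])).statistic
    return {
        "n_shared": n,
        "concordance": k / n,
        "binomial_p": float(binom_p),
        "spearman_beta": float(rho_beta),
        "spearman_logp": float(rho_logp),
    }
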