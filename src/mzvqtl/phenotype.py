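"""Preparation of the MZ-differences phenotype.

The analysis-ready score is built in a fixed order: the absolute within-pair
difference |yA - yB| is residualized on covariates (age, sex, ten genetic
principal components and any study-specific columns), then standardized and
rank-based inverse-normal transformed.  Three preparation variants are
supported:

* model 1 (primary): residualize on all covariates;
* model 2: as model 1, and the within-pair phenotype mean (yA + yB)/2 is
  carried along for use as a regression covariate in the association test;
* model 3: residualize on age and sex only (no principal components).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import TwinCohort

__all__ = [
    "absolute_pair_difference",
    "residualize",
    "inverse_normal_transform",
    "prepare_phenotype",
]

log = logging.getLogger(__name__)

BLOM_OFFSET = 0.375


def absolute_pair_difference(cohort: TwinCohort) -> pd.Series:
    """|yA - yB| per pair, indexed by pair_id; incomplete pairs are dropped."""
    yA = np.asarray(cohort.yA, dtype=float)
    yB = np.asarray(cohort.yB, dtype=float)
    complete = np.isfinite(yA) & np.isfinite(yB)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropping %d pairs with a missing phenotype for either twin", n_dropped)
    return pd.Series(
        np.abs(yA[complete] - yB[complete]),
        index=pd.Index(np.asarray(cohort.pair_id)[complete], name="pair_id"),
        name="raw_diff",
    )


def residualize(values: pd.Series | np.ndarray, covariates: Optional[pd.DataFrame]) -> pd.Series:
    """OLS residuals of ``values`` on an intercept plus all covariate columns.

    Rows with a missing covariate are excluded (and logged).  A rank-deficient
    design raises with the offending columns named.
    """
    values = pd.Series(values) if not isinstance(values, pd.Series) else values
    if covariates is None or covariates.shape[1] == 0:
        return values - values.mean()
    covariates = covariates.loc[values.index] if covariates.index.equals(values.index) else (
        covariates.set_axis(values.index) if len(covariates) == len(values) else None
    )
    if covariates is None:
        raise ValueError("covariate table does not align with the phenotype vector")
    complete = covariates.notna().all(axis=1) & values.notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropping %d rows with missing covariates", n_dropped)
    y = values[complete]
    X = covariates.loc[complete].astype(float)
    Xd = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        # identify columns that do not increase the rank when added in order
        bad = []
        cols: list[str] = []
        for c in Xd.columns:
            trial = Xd[cols + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(c)
            else:
                cols.append(c)
        raise ValueError(f"covariate matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(y.to_numpy(), Xd.to_numpy()).fit()
    return pd.Series(fit.resid, index=y.index, name=values.name)


def inverse_normal_transform(
    values: pd.Series | np.ndarray, offset: float = BLOM_OFFSET
) -> pd.Series | np.ndarray:
    """Standardize, then map ranks to normal quantiles.

    Each value is replaced by ``Phi^{-1}((rank - c) / (n - 2c + 1))`` with the
    Blom offset c = 3/8 by default; ties receive the average rank.  The
    transform is monotone and invariant to affine rescaling of the input.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("at least two values are required")
    sd = arr.std()
    if sd == 0.0:
        raise ValueError("all values are identical; ranks carry no information")
    z = (arr - arr.mean()) / sd
    ranks = stats.rankdata(z, method="average")
    quantiles = (ranks - offset) / (arr.size - 2.0 * offset + 1.0)
    out = stats.norm.ppf(quantiles)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


_MODEL3_COLS = ("age", "sex")


def prepare_phenotype(
    cohort: TwinCohort,
    model: int = 1,
    extra_covariates: Optional[Iterable[str]] = None,
    int_offset: float = BLOM_OFFSET,
) -> pd.DataFrame:
    """Analysis-ready MZ-differences score for one cohort.

    Returns a table with ``pair_id``, ``raw_diff``, ``prepared`` and
    ``model_tag`` columns; model 2 adds ``pair_mean`` = (yA + yB)/2.
    """
    if model not in (1, 2, 3):
        raise ValueError(f"model must be 1, 2 or 3, got {model}")
    raw = absolute_pair_difference(cohort)
    if cohort.covariates is None:
        if model in (1, 2):
            raise ValueError(f"model {model} requires a covariate table")
        cov = None
    else:
        cov_all = cohort.covariates.set_axis(pd.Index(cohort.pair_id, name="pair_id"))
        if model == 3:
            missing = [c for c in _MODEL3_COLS if c not in cov_all.columns]
            if missing:
                raise ValueError(f"model 3 requires columns {missing}")
            cov = cov_all[list(_MODEL3_COLS)]
        else:
            cov = cov_all
        if extra_covariates is not None:
            extra = [c for c in extra_covariates if c not in (cov.columns if cov is not None else [])]
            cov = pd.concat([cov, cov_all[extra]], axis=1) if cov is not None else cov_all[extra]
        cov = cov.loc[raw.index]
    resid = residualize(raw, cov)
    prepared = inverse_normal_transform(resid, offset=int_offset)
    out = pd.DataFrame(
        {
            "pair_id": prepared.index.to_numpy(),
            "raw_diff": raw.loc[prepared.index].to_numpy(),
            "prepared": prepared.to_numpy(),
            "model_tag": model,
        }
    )
    if model == 2:
        mean = pd.Series(
            (np.asarray(cohort.yA, dtype=float) + np.asarray(cohort.yB, dtype=float)) / 2.0,
            index=pd.Index(np.asarray(cohort.pair_id), name="pair_id"),
        )
        out["pair_mean"] = mean.loc[out["pair_id"]].to_numpy()
    return out
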