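"""Two-sample summary-data Mendelian randomization of liability on variance.

Instruments are variants robustly associated with the exposure (the mean-level
trait, e.g. genetic liability to depression); the outcome is the
MZ-differences (variance) GWAS of the same phenotype.  After allele
harmonization, the causal effect is the inverse-variance-weighted (IVW)
estimate,

    beta_IVW = sum_j (b_xj * b_yj / s_yj^2) / sum_j (b_xj^2 / s_yj^2),

which equals weighted least squares of outcome on exposure effects through
the origin with weights 1/s_yj^2.  Heterogeneity across instruments is
summarised by Cochran's Q.  A z-test compares IVW estimates between two
independent groups (e.g. child vs adult outcome GWASs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MRResult", "GroupDifference", "harmonize", "ivw_estimate", "group_difference_test"]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

MRINPUT_COLUMNS = ["snp", "A1", "A2", "beta_exp", "se_exp", "beta_out", "se_out"]


@dataclass(frozen=True)
class MRResult:
    """IVW causal estimate with heterogeneity statistics."""

    beta: float
    se: float
    p: float
    n_snps: int
    Q: float
    Q_df: int
    Q_p: float
    method: str = "IVW-FE"


class GroupDifference(NamedTuple):
    difference: float
    se: float
    p: float


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_eaf_margin: float = 0.08,
) -> pd.DataFrame:
    """Join exposure and outcome tables on position and align effect alleles.

    Both tables need ``chr, pos, A1, A2, beta, se`` (``eaf`` is used to
    orient palindromic variants when present in both; otherwise palindromic
    variants are dropped).  When the outcome's allele labels are swapped
    relative to the exposure, the outcome beta is negated; strand flips are
    resolved through base complements; allele-set mismatches are dropped.
    """
    for name, df in (("exposure", exposure), ("outcome", outcome)):
        missing = [c for c in ("chr", "pos", "A1", "A2", "beta", "se") if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table is missing columns: {missing}")

    exp = exposure.copy()
    out = outcome.copy()
    for df in (exp, out):
        df["A1"] = df["A1"].astype(str).str.upper()
        df["A2"] = df["A2"].astype(str).str.upper()

    merged = exp.merge(out, on=["chr", "pos"], suffixes=("_exp", "_out"))
    if merged.empty:
        raise ValueError("exposure and outcome tables share no variants")

    a1o, a2o = merged["A1_out"], merged["A2_out"]
    c1o = a1o.map(_COMPLEMENT.get)
    c2o = a2o.map(_COMPLEMENT.get)
    a1e, a2e = merged["A1_exp"], merged["A2_exp"]
    pal = a1e.map(_COMPLEMENT.get) == a2e

    same = (a1o == a1e) & (a2o == a2e)
    swapped = (a1o == a2e) & (a2o == a1e)
    comp_same = (c1o == a1e) & (c2o == a2e)
    comp_swapped = (c1o == a2e) & (c2o == a1e)

    if "eaf_exp" in merged.columns and "eaf_out" in merged.columns:
        decisive = ((merged["eaf_exp"] - 0.5).abs() > palindromic_eaf_margin) & (
            (merged["eaf_out"] - 0.5).abs() > palindromic_eaf_margin
        )
        pal_keep = pal & (same | swapped) & decisive
        pal_flip = pal_keep & ((merged["eaf_exp"] - 0.5) * (merged["eaf_out"] - 0.5) < 0)
    else:
        pal_keep = pd.Series(False, index=merged.index)
        pal_flip = pal_keep

    keep = (~pal & (same | swapped | comp_same | comp_swapped)) | pal_keep
    flip = (~pal & (swapped | comp_swapped)) | pal_flip
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d variants with mismatching or ambiguous alleles", n_dropped)

    merged = merged[keep].copy()
    flip = flip[keep]
    merged.loc[flip, "beta_out"] = -merged.loc[flip, "beta_out"]

    snp_col = "snp_exp" if "snp_exp" in merged.columns else (
        "snp" if "snp" in merged.columns else None
    )
    snp = merged[snp_col] if snp_col else (
        merged["chr"].astype(str) + ":" + merged["pos"].astype(str)
    )
    result = pd.DataFrame(
        {
            "snp": snp.to_numpy(),
            "A1": a1e[keep].to_numpy(),
            "A2": a2e[keep].to_numpy(),
            "beta_exp": merged["beta_exp"].to_numpy(),
            "se_exp": merged["se_exp"].to_numpy(),
            "beta_out": merged["beta_out"].to_numpy(),
            "se_out": merged["se_out"].to_numpy(),
        }
    )
    if result["snp"].duplicated().any():
        raise ValueError("duplicate instruments after harmonization")
    return result


def ivw_estimate(data: pd.DataFrame, random_effects: bool = False) -> MRResult:
    """Inverse-variance-weighted causal estimate from a harmonized table.

    With a single instrument the Wald ratio beta_out/beta_exp is returned
    (se = se_out/|beta_exp|).  ``random_effects=True`` inflates the fixed-
    effect standard error by sqrt(Q/df) when Q exceeds its degrees of
    freedom (multiplicative random-effects model).
    """
    missing = [c for c in ("beta_exp", "beta_out", "se_out") if c not in data.columns]
    if missing:
        raise ValueError(f"harmonized table is missing columns: {missing}")
    bx = data["beta_exp"].to_numpy(dtype=float)
    by = data["beta_out"].to_numpy(dtype=float)
    sy = data["se_out"].to_numpy(dtype=float)
    if np.any(sy <= 0):
        raise ValueError("outcome standard errors must be positive")
    nonzero = bx != 0.0
    if not np.all(nonzero):
        log.warning("dropping %d instruments with a zero exposure effect", int((~nonzero).sum()))
        bx, by, sy = bx[nonzero], by[nonzero], sy[nonzero]
    n = bx.size
    if n == 0:
        raise ValueError("no usable instruments")
    if n == 1:
        beta = float(by[0] / bx[0])
        se = float(sy[0] / abs(bx[0]))
        p = 2.0 * stats.norm.sf(abs(beta / se))
        return MRResult(beta, se, p, 1, np.nan, 0, np.nan, method="Wald")
    w = bx**2 / sy**2
    beta = float(np.sum(by * bx / sy**2) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum((by - beta * bx) ** 2 / sy**2))
    q_df = n - 1
    q_p = float(stats.chi2.sf(q, q_df))
    method = "IVW-FE"
    if random_effects:
        se = se * max(1.0, np.sqrt(q / q_df))
        method = "IVW-mRE"
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return MRResult(beta, se, float(p), n, q, q_df, q_p, method=method)


def group_difference_test(res_child: MRResult, res_adult: MRResult) -> GroupDifference:
    """z-test for a difference between two independent IVW estimates."""
    diff = res_adult.beta - res_child.beta
    se = float(np.hypot(res_adult.se, res_child.se))
    p = 2.0 * stats.norm.sf(abs(diff / se)) if se > 0 else (1.0 if diff == 0 else 0.0)
    return GroupDifference(float(diff), se, float(p))
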