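"""Summary-statistic quality control and fixed-effect meta-analysis.

The QC step mirrors common GWAS-consortium practice: drop rows with missing
estimates, minor-allele frequency or imputation-quality failures, indels and
monomorphic variants; harmonize alleles to a reference panel (swapping the
effect allele flips the sign of beta and complements the frequency; ambiguous
palindromic variants are resolved by frequency or dropped); and de-duplicate
positions keeping the largest sample.  Meta-analysis is inverse-variance-
weighted and fixed-effect, with a per-study direction string ("+", "-", "?")
and Cochran's Q reported per variant.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SUMSTAT_COLUMNS",
    "REFERENCE_COLUMNS",
    "read_sumstats",
    "write_sumstats",
    "qc_summary_stats",
    "lambda_median",
    "ivw_meta",
    "availability_filter",
    "genome_wide_hits",
]

log = logging.getLogger(__name__)

SUMSTAT_COLUMNS = ["snp", "chr", "pos", "A1", "A2", "eaf", "beta", "se", "p", "n", "info"]
REFERENCE_COLUMNS = ["chr", "pos", "ref_A1", "ref_A2", "ref_eaf"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_BASES = frozenset("ACGT")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated summary-statistic table (gzip-transparent)."""
    return pd.read_csv(path, sep="\t", dtype={"chr": str, "A1": str, "A2": str})


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _cptid(df: pd.DataFrame) -> pd.Series:
    return (
        df["chr"].astype(str)
        + ":"
        + df["pos"].astype(int).astype(str)
        + ":"
        + df["A1"]
        + ":"
        + df["A2"]
    )


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a1.map(_COMPLEMENT.get) == a2


def qc_summary_stats(
    stats_table: pd.DataFrame,
    reference: pd.DataFrame,
    maf_min: float = 0.01,
    info_min: float = 0.5,
    palindromic_eaf_margin: float = 0.08,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter and harmonize one study's summary statistics against a reference.

    Returns the cleaned table (with cptid identifiers rebuilt from the
    harmonized alleles) and an ordered report of row counts removed per rule.
    """
    missing_cols = [c for c in SUMSTAT_COLUMNS if c not in stats_table.columns]
    if missing_cols:
        raise ValueError(f"summary-statistic table is missing columns: {missing_cols}")
    missing_ref = [c for c in REFERENCE_COLUMNS if c not in reference.columns]
    if missing_ref:
        raise ValueError(f"reference table is missing columns: {missing_ref}")

    df = stats_table.copy()
    df["A1"] = df["A1"].astype(str).str.upper()
    df["A2"] = df["A2"].astype(str).str.upper()
    report: dict[str, int] = {"input": len(df)}

    ok = df[["beta", "se", "p", "info"]].notna().all(axis=1)
    report["missing_values"] = int((~ok).sum())
    df = df[ok]

    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    ok = maf >= maf_min
    report["low_maf"] = int((~ok).sum())
    df = df[ok]

    ok = df["info"] >= info_min
    report["low_info"] = int((~ok).sum())
    df = df[ok]

    ok = df["A1"].isin(_BASES) & df["A2"].isin(_BASES)
    report["indels"] = int((~ok).sum())
    df = df[ok]

    ok = (df["A1"] != df["A2"]) & (df["eaf"] > 0.0) & (df["eaf"] < 1.0)
    report["monomorphic"] = int((~ok).sum())
    df = df[ok]

    ref = reference.copy()
    ref["ref_A1"] = ref["ref_A1"].astype(str).str.upper()
    ref["ref_A2"] = ref["ref_A2"].astype(str).str.upper()
    merged = df.merge(ref, on=["chr", "pos"], how="left")
    in_ref = merged["ref_A1"].notna()
    report["not_in_reference"] = int((~in_ref).sum())
    merged = merged[in_ref]

    a1, a2 = merged["A1"], merged["A2"]
    c1 = a1.map(_COMPLEMENT.get)
    c2 = a2.map(_COMPLEMENT.get)
    r1, r2 = merged["ref_A1"], merged["ref_A2"]
    pal = _is_palindromic(a1, a2)

    same = (a1 == r1) & (a2 == r2)
    swapped = (a1 == r2) & (a2 == r1)
    comp_same = (c1 == r1) & (c2 == r2)
    comp_swapped = (c1 == r2) & (c2 == r1)

    # Palindromic variants: orientation cannot be read from the allele labels;
    # resolve by comparing frequencies when both are decisive, otherwise drop.
    decisive = (
        ((merged["eaf"] - 0.5).abs() > palindromic_eaf_margin)
        & ((merged["ref_eaf"] - 0.5).abs() > palindromic_eaf_margin)
    )
    pal_keep = pal & (same | swapped) & decisive
    pal_flip_freq = pal_keep & (
        (merged["eaf"] - 0.5) * (merged["ref_eaf"] - 0.5) < 0
    )

    flip = (~pal & swapped) | (~pal & comp_swapped) | pal_flip_freq
    keep = (~pal & (same | swapped | comp_same | comp_swapped)) | pal_keep
    report["allele_mismatch_or_ambiguous"] = int((~keep).sum())
    merged = merged[keep].copy()
    flip = flip[keep]

    merged.loc[flip, "beta"] = -merged.loc[flip, "beta"]
    merged.loc[flip, "eaf"] = 1.0 - merged.loc[flip, "eaf"]
    merged["A1"] = merged["ref_A1"]
    merged["A2"] = merged["ref_A2"]
    merged["snp"] = _cptid(merged)

    merged = merged.sort_values("n", ascending=False, kind="stable")
    dup = merged.duplicated(subset=["chr", "pos"], keep="first")
    report["duplicate_position"] = int(dup.sum())
    merged = merged[~dup].sort_values(["chr", "pos"], kind="stable")

    out = merged[SUMSTAT_COLUMNS].reset_index(drop=True)
    report["output"] = len(out)
    return out, report


def lambda_median(p_values: np.ndarray | pd.Series) -> float:
    """Genomic inflation factor: median association chi-square / null median."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def ivw_meta(
    studies: Sequence[pd.DataFrame], labels: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effect meta-analysis across studies.

    All inputs must be QC'd and harmonized to the same reference so that a
    given cptid carries the same effect allele everywhere; variants with
    conflicting allele pairs across studies are dropped and logged.  Returns
    one row per variant with the pooled estimate, a per-study direction
    string in input order, and Cochran's Q heterogeneity statistics.
    """
    if len(studies) == 0:
        raise ValueError("at least one study is required")
    k = len(studies)
    labels = [f"study{i + 1}" for i in range(k)] if labels is None else list(labels)

    frames = []
    for i, df in enumerate(studies):
        sub = df[["snp", "A1", "A2", "eaf", "beta", "se", "n"]].copy()
        sub["study"] = i
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)

    alleles = long.groupby("snp")[["A1", "A2"]].nunique()
    conflicted = alleles[(alleles["A1"] > 1) | (alleles["A2"] > 1)].index
    if len(conflicted):
        log.warning("dropping %d variants with conflicting alleles across studies", len(conflicted))
        long = long[~long["snp"].isin(conflicted)]
    if long.empty:
        raise ValueError("no variants remain after allele-conflict filtering")

    def _pivot(col: str) -> pd.DataFrame:
        return long.pivot_table(index="snp", columns="study", values=col, aggfunc="first")

    beta = _pivot("beta").reindex(columns=range(k))
    se = _pivot("se").reindex(columns=range(k))
    n = _pivot("n").reindex(columns=range(k))
    eaf = _pivot("eaf").reindex(columns=range(k))

    w = 1.0 / se**2
    sw = w.sum(axis=1)
    beta_meta = (w * beta).sum(axis=1) / sw
    se_meta = np.sqrt(1.0 / sw)
    z = beta_meta / se_meta
    p = 2.0 * stats.norm.sf(np.abs(z))
    n_total = n.sum(axis=1)
    n_studies = beta.notna().sum(axis=1)
    eaf_avg = (n * eaf).sum(axis=1) / n.sum(axis=1)

    q = (w * (beta.sub(beta_meta, axis=0)) ** 2).sum(axis=1)
    q_df = (n_studies - 1).clip(lower=0)
    q_p = np.where(q_df > 0, stats.chi2.sf(q, np.maximum(q_df, 1)), np.nan)

    sign = np.where(beta.isna(), "?", np.where(beta >= 0, "+", "-"))
    direction = ["".join(row) for row in sign]

    allele_map = long.groupby("snp")[["A1", "A2"]].first()

    out = pd.DataFrame(
        {
            "snp": beta.index,
            "A1": allele_map.loc[beta.index, "A1"].to_numpy(),
            "A2": allele_map.loc[beta.index, "A2"].to_numpy(),
            "eaf_avg": eaf_avg.to_numpy(),
            "beta": beta_meta.to_numpy(),
            "se": se_meta.to_numpy(),
            "z": z.to_numpy(),
            "p": p,
            "n_total": n_total.to_numpy(),
            "n_studies": n_studies.to_numpy(),
            "direction": direction,
            "Q": q.to_numpy(),
            "Q_df": q_df.to_numpy(),
            "Q_p": q_p,
        }
    ).reset_index(drop=True)
    out.attrs["study_labels"] = labels
    return out


def availability_filter(meta: pd.DataFrame, min_prop: float = 0.5) -> pd.DataFrame:
    """Keep variants observed (non-"?") in at least ``min_prop`` of studies."""
    direction = meta["direction"].astype(str)
    n_present = direction.str.len() - direction.str.count(r"\?")
    frac = n_present / direction.str.len()
    return meta[frac >= min_prop].reset_index(drop=True)


def genome_wide_hits(meta: pd.DataFrame, threshold: float = 5e-8) -> pd.DataFrame:
    """Rows with p below the genome-wide threshold, sorted by p."""
    return meta[meta["p"] < threshold].sort_values("p", kind="stable").reset_index(drop=True)
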