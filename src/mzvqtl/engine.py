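"""Genome-wide application of a vQTL test over a genotype source.

Genotypes come from a VCF (DS dosage field when present, otherwise GT hard
calls) or a plain tab-separated matrix (variant metadata columns followed by
one column per sample).  The engine intersects samples with the prepared
phenotype table, applies variant-level filters (call rate, MAF, imputation
info), runs the chosen test per variant and emits a study-level
summary-statistic table in the dialect consumed by the QC/meta module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .association import drm_test, mz_diff_test
from .qcmeta import SUMSTAT_COLUMNS

__all__ = ["GenotypeSource", "run_gwas"]

log = logging.getLogger(__name__)

_META_COLS = ["id", "chr", "pos", "A1", "A2", "info"]


@dataclass
class GenotypeSource:
    """Variant metadata plus a (variants x samples) dosage matrix.

    ``variants`` has columns id, chr, pos, A1, A2, info; ``dosages`` holds
    values in [0, 2] with NaN for missing calls; ``samples`` are identifiers
    matched against the phenotype table's pair ids.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table is missing columns: {missing}")
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        self.samples = [str(s) for s in self.samples]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeSource":
        """Read genotypes from a VCF; prefers the DS FORMAT field over GT."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        meta, rows = [], []
        for var in vcf:
            try:
                raw = var.format("DS")
            except KeyError:
                raw = None
            if raw is not None:
                ds = np.asarray(raw, dtype=float).reshape(-1)
            else:
                gt = np.asarray(var.genotypes, dtype=float)[:, :2]
                ds = np.where((gt < 0).any(axis=1), np.nan, gt.clip(0).sum(axis=1))
            info_score = var.INFO.get("INFO", 1.0)
            meta.append(
                {
                    "id": var.ID or f"{var.CHROM}:{var.POS}",
                    "chr": str(var.CHROM),
                    "pos": int(var.POS),
                    "A1": var.ALT[0] if var.ALT else ".",
                    "A2": var.REF,
                    "info": float(info_score),
                }
            )
            rows.append(ds)
        vcf.close()
        return cls(pd.DataFrame(meta), np.vstack(rows), samples)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeSource":
        df = pd.read_csv(path, sep="\t", dtype={"chr": str})
        missing = [c for c in _META_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"genotype matrix is missing columns: {missing}")
        sample_cols = [c for c in df.columns if c not in _META_COLS]
        return cls(
            df[_META_COLS].copy(),
            df[sample_cols].to_numpy(dtype=float),
            [str(c) for c in sample_cols],
        )

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat(
            [
                self.variants.reset_index(drop=True),
                pd.DataFrame(self.dosages, columns=self.samples),
            ],
            axis=1,
        )
        out.to_csv(path, sep="\t", index=False)

    def to_vcf(self, path: str | Path) -> None:
        """Write an uncompressed VCF with GT and DS fields.

        The effect allele (A1) is written as ALT and A2 as REF, so dosage
        counts the effect allele.
        """
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
            fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n')
            chroms = self.variants["chr"].astype(str).unique()
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            order = self.variants.reset_index(drop=True).sort_values(["chr", "pos"]).index
            for i in order:
                row = self.variants.iloc[i]
                ds = self.dosages[i]
                fields = []
                for d in ds:
                    if np.isnan(d):
                        fields.append("./.:.")
                    else:
                        hard = int(round(d))
                        gt = ["0/0", "0/1", "1/1"][min(max(hard, 0), 2)]
                        fields.append(f"{gt}:{d:g}")
                fh.write(
                    f"{row['chr']}\t{int(row['pos'])}\t{row['id']}\t{row['A2']}\t{row['A1']}"
                    f"\t.\t.\tINFO={row['info']:g}\tGT:DS\t" + "\t".join(fields) + "\n"
                )


def run_gwas(
    source: GenotypeSource,
    prepared: pd.DataFrame,
    test: str = "mz_diff",
    model: int = 1,
    maf_min: float = 0.01,
    info_min: float = 0.0,
    callrate_min: float = 0.95,
    phenotype_col: Optional[str] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the selected vQTL test for every variant passing the filters.

    ``prepared`` is the table produced by ``prepare_phenotype`` (keyed by
    pair_id) for the MZ test, or any table with an ``id`` equivalent column
    plus a phenotype column for the DRM.  Returns the summary-statistic
    table and an ordered log of variants removed per filter; output rows
    plus logged removals always add up to the input variant count.
    """
    if test not in ("mz_diff", "drm"):
        raise ValueError("test must be 'mz_diff' or 'drm'")
    key = "pair_id" if "pair_id" in prepared.columns else "id"
    if phenotype_col is None:
        phenotype_col = "prepared" if "prepared" in prepared.columns else "y"
    pheno = prepared.set_index(prepared[key].astype(str))

    sample_index = {s: i for i, s in enumerate(source.samples)}
    shared = [s for s in pheno.index if s in sample_index]
    if not shared:
        raise ValueError(
            f"no overlap between {len(pheno)} phenotype ids and "
            f"{len(source.samples)} genotype samples"
        )
    if len(shared) < len(pheno):
        log.info(
            "phenotype/genotype overlap: %d of %d phenotype rows", len(shared), len(pheno)
        )
    cols = np.array([sample_index[s] for s in shared])
    y = pheno.loc[shared, phenotype_col].to_numpy(dtype=float)
    pair_mean = (
        pheno.loc[shared, "pair_mean"].to_numpy(dtype=float)
        if model == 2 and "pair_mean" in pheno.columns
        else None
    )
    if model == 2 and pair_mean is None:
        raise ValueError("model 2 requires a pair_mean column in the phenotype table")

    filter_log = {"call_rate": 0, "low_maf": 0, "low_info": 0, "untestable": 0}
    records = []
    for i in range(source.n_variants):
        meta = source.variants.iloc[i]
        if meta["info"] < info_min:
            filter_log["low_info"] += 1
            continue
        dos = source.dosages[i, cols]
        called = np.isfinite(dos)
        callrate = called.mean()
        if callrate < callrate_min:
            filter_log["call_rate"] += 1
            continue
        g = dos[called]
        yv = y[called]
        eaf = g.mean() / 2.0
        if min(eaf, 1.0 - eaf) < maf_min:
            filter_log["low_maf"] += 1
            continue
        if test == "mz_diff":
            pm = pair_mean[called] if pair_mean is not None else None
            res = mz_diff_test(yv, g, model=model, pair_mean=pm, snp_id=str(meta["id"]))
        else:
            res = drm_test(yv, g, snp_id=str(meta["id"]))
        if not res.testable:
            filter_log["untestable"] += 1
            continue
        records.append(
            {
                "snp": f"{meta['chr']}:{int(meta['pos'])}:{meta['A1']}:{meta['A2']}",
                "chr": str(meta["chr"]),
                "pos": int(meta["pos"]),
                "A1": meta["A1"],
                "A2": meta["A2"],
                "eaf": eaf,
                "beta": res.beta,
                "se": res.se,
                "p": res.p,
                "n": res.n,
                "info": float(meta["info"]),
            }
        )
    if not records:
        raise ValueError("no variants passed the filters")
    out = pd.DataFrame(records, columns=SUMSTAT_COLUMNS)
    return out, filter_log
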