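"""End-to-end pipeline: simulate studies -> prep -> GWAS -> QC -> meta -> hits.

Driven by a YAML configuration; every run writes the resolved configuration,
a log and a manifest of artifacts with content hashes next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .engine import GenotypeSource, run_gwas
from .phenotype import prepare_phenotype
from .qcmeta import (
    genome_wide_hits,
    ivw_meta,
    lambda_median,
    qc_summary_stats,
    read_sumstats,
    write_sumstats,
)
from .simulate import SimulationParams, TwinCohort, simulate_twin_cohort

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "n_studies": 2,
        "n_pairs": 2000,
        "n_variants": 200,
        "p_causal": 0.3,
        "beta1": 0.0,
        "beta2": 0.0,
        "h2": 0.5,
        "causal_index": 0,
    },
    "prep": {"model": 1},
    "gwas": {
        "test": "mz_diff",
        "maf_min": 0.01,
        "info_min": 0.0,
        "callrate_min": 0.95,
    },
    "qc": {"maf_min": 0.01, "info_min": 0.5},
    "hits": {"threshold": 5e-8},
}


def validate_config(config: Optional[dict[str, Any]]) -> dict[str, Any]:
    """Merge a user configuration over the defaults, rejecting unknown keys."""
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if config is None:
        return merged
    for key, value in config.items():
        if key not in merged:
            raise ValueError(f"unknown configuration key: {key!r}")
        if isinstance(merged[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"configuration section {key!r} must be a mapping")
            for sub, sval in value.items():
                if sub not in merged[key]:
                    raise ValueError(f"unknown configuration key: {key}.{sub}")
                merged[key][sub] = sval
        else:
            merged[key] = value
    return merged


_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


def _simulate_study(
    cfg: dict[str, Any], study: int, rng: np.random.Generator
) -> tuple[GenotypeSource, pd.DataFrame, pd.DataFrame]:
    """One study: genotype source, cohort frame and truth/reference table."""
    sim = cfg["simulate"]
    n_pairs = sim["n_pairs"]
    n_var = sim["n_variants"]
    causal = sim["causal_index"]

    params = SimulationParams(
        p=sim["p_causal"],
        beta1=sim["beta1"],
        beta2=sim["beta2"],
        sigma2_g=sim["h2"],
        n_pairs=n_pairs,
    )
    cohort = simulate_twin_cohort(params, rng=rng, covariates=True)
    samples = [f"s{study}_p{i}" for i in range(n_pairs)]
    cohort.pair_id = np.array(samples)

    freqs = rng.uniform(0.05, 0.5, n_var)
    dosages = np.empty((n_var, n_pairs), dtype=float)
    meta_rows = []
    for j in range(n_var):
        a1, a2 = _NONPALINDROMIC_PAIRS[j % len(_NONPALINDROMIC_PAIRS)]
        if causal is not None and j == causal:
            freqs[j] = params.p
            dosages[j] = cohort.G
        else:
            dosages[j] = rng.binomial(2, freqs[j], n_pairs)
        meta_rows.append(
            {
                "id": f"var{j}",
                "chr": "1",
                "pos": 10_000 + 1_000 * j,
                "A1": a1,
                "A2": a2,
                "info": 1.0,
            }
        )
    variants = pd.DataFrame(meta_rows)
    reference = pd.DataFrame(
        {
            "chr": variants["chr"],
            "pos": variants["pos"],
            "ref_A1": variants["A1"],
            "ref_A2": variants["A2"],
            "ref_eaf": freqs,
        }
    )
    return GenotypeSource(variants, dosages, samples), cohort.to_frame(), reference


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Optional[dict[str, Any]], out_dir: str | Path) -> dict[str, str]:
    """Execute the configured stage sequence; returns the artifact manifest.

    Stage outputs are TSV tables under ``out_dir``; a failing stage writes a
    FAILED marker naming the stage and re-raises.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mzvqtl")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)

    stage = "simulate"
    try:
        ss = np.random.SeedSequence(cfg["seed"])
        n_studies = cfg["simulate"]["n_studies"]
        children = ss.spawn(n_studies)

        study_stats = []
        summary: dict[str, Any] = {"studies": []}
        for s in range(n_studies):
            stage = f"simulate/study{s + 1}"
            rng = np.random.default_rng(children[s])
            source, cohort_frame, reference = _simulate_study(cfg, s + 1, rng)
            vcf_path = out / f"study{s + 1}.genotypes.vcf"
            source.to_vcf(vcf_path)
            cohort_frame.to_csv(out / f"study{s + 1}.cohort.tsv", sep="\t", index=False)
            reference.to_csv(out / f"study{s + 1}.reference.tsv", sep="\t", index=False)

            stage = f"prep/study{s + 1}"
            cohort = TwinCohort.from_tsv(out / f"study{s + 1}.cohort.tsv")
            prepared = prepare_phenotype(cohort, model=cfg["prep"]["model"])
            prepared.to_csv(out / f"study{s + 1}.prepared.tsv", sep="\t", index=False)

            stage = f"gwas/study{s + 1}"
            source_rt = GenotypeSource.from_vcf(vcf_path)
            stats, filter_log = run_gwas(
                source_rt,
                prepared,
                test=cfg["gwas"]["test"],
                model=cfg["prep"]["model"],
                maf_min=cfg["gwas"]["maf_min"],
                info_min=cfg["gwas"]["info_min"],
                callrate_min=cfg["gwas"]["callrate_min"],
            )
            write_sumstats(stats, out / f"study{s + 1}.sumstats.tsv")
            log.info("study %d GWAS filter log: %s", s + 1, filter_log)

            stage = f"qc/study{s + 1}"
            clean, report = qc_summary_stats(
                read_sumstats(out / f"study{s + 1}.sumstats.tsv"),
                reference,
                maf_min=cfg["qc"]["maf_min"],
                info_min=cfg["qc"]["info_min"],
            )
            write_sumstats(clean, out / f"study{s + 1}.sumstats.qc.tsv")
            lam = lambda_median(clean["p"])
            log.info("study %d QC report: %s; lambda_median=%.4f", s + 1, report, lam)
            summary["studies"].append(
                {"study": s + 1, "gwas_filters": filter_log, "qc": report, "lambda_median": lam}
            )
            study_stats.append(clean)

        stage = "meta"
        meta = ivw_meta(study_stats, labels=[f"study{s + 1}" for s in range(n_studies)])
        meta.to_csv(out / "meta.tsv", sep="\t", index=False)
        lam_meta = lambda_median(meta["p"])
        summary["lambda_median_meta"] = lam_meta
        log.info("meta-analysis lambda_median=%.4f", lam_meta)

        stage = "hits"
        hits = genome_wide_hits(meta, threshold=cfg["hits"]["threshold"])
        hits.to_csv(out / "hits.tsv", sep="\t", index=False)
        summary["n_hits"] = len(hits)

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    except Exception as err:
        (out / "FAILED").write_text(f"stage {stage} failed: {err}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed") from err
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
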