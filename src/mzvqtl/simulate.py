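"""Generative model for twin cohorts carrying a variance QTL.

The data-generating model for twin ``t`` in monozygotic (MZ) pair ``i`` is

    y_it = alpha + beta1 * G_i + z_i + v_it + e_it

with

    G_i  ~ Binomial(2, p)                      shared genotype,
    z_i  ~ N(0, sigma2_g - 2 p (1-p) beta1^2)  shared residual polygenic value,
    v_it ~ N(0, beta2 * G_i)                   per-twin variance-heterogeneity term,
    e_it ~ N(0, 1 - sigma2_g - sigma2_v)       per-twin residual.

``beta1`` is the additive (mean) effect of the locus, ``beta2`` the per-allele
variance inflation: each copy of the effect allele adds ``beta2`` to the
conditional phenotypic variance.  ``sigma2_g`` is the narrow-sense heritability
h^2 and ``sigma2_v = E[var(v | G)] = 2 p beta2`` so that the total phenotypic
variance is exactly 1 by construction.

Genotype and polygenic value are shared within a pair; ``v`` and ``e`` are
drawn independently per twin, so all within-pair variability comes from
``v + e``.  Unrelated-individual cohorts are marginally equivalent to keeping
one twin per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimulationParams",
    "TwinCohort",
    "PopulationCohort",
    "TaggedLocusPair",
    "simulate_twin_cohort",
    "simulate_population_cohort",
    "simulate_tagged_locus",
    "simulate_tagged_twin_genotypes",
    "simulate_covariates",
    "simulate_mr_instruments",
]

N_PCS = 10


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the twin variance-QTL generative model.

    Attributes
    ----------
    p : effect-allele frequency, 0 < p < 1.
    beta1 : additive effect of the locus (phenotype SD units per allele).
    beta2 : per-allele variance inflation (variance units per allele), >= 0.
    sigma2_g : narrow-sense heritability h^2 (fraction of unit variance).
    alpha_intercept : intercept of the model (0 by default).
    n_pairs : number of MZ pairs in a twin cohort.
    n_individuals : number of unrelated individuals in a population cohort.
    seed : seed for the default random generator.
    alpha_sig : significance level used when counting discoveries.
    """

    p: float
    beta1: float = 0.0
    beta2: float = 0.0
    sigma2_g: float = 0.0
    alpha_intercept: float = 0.0
    n_pairs: int = 10_000
    n_individuals: int = 20_000
    seed: Optional[int] = None
    alpha_sig: float = 5e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"allele frequency p must lie in (0, 1), got {self.p}")
        if self.beta2 < 0.0:
            raise ValueError(f"variance effect beta2 must be >= 0, got {self.beta2}")
        if self.sigma2_g < self.locus_additive_variance - 1e-12:
            raise ValueError(
                "sigma2_g must be >= 2*p*(1-p)*beta1^2 so the residual polygenic "
                f"variance is non-negative (sigma2_g={self.sigma2_g}, "
                f"locus additive variance={self.locus_additive_variance:.6g})"
            )
        if self.sigma2_g + self.sigma2_v > 1.0 + 1e-12:
            raise ValueError(
                "sigma2_g + sigma2_v must be <= 1 so the residual variance is "
                f"non-negative (sigma2_g={self.sigma2_g}, sigma2_v={self.sigma2_v:.6g})"
            )
        if self.n_pairs <= 0 or self.n_individuals <= 0:
            raise ValueError("sample sizes must be positive")

    @property
    def locus_additive_variance(self) -> float:
        """Variance explained by the additive effect, 2 p (1-p) beta1^2."""
        return 2.0 * self.p * (1.0 - self.p) * self.beta1**2

    @property
    def sigma2_v(self) -> float:
        """Mean conditional variance of v, E[beta2 * G] = 2 p beta2."""
        return 2.0 * self.p * self.beta2

    @property
    def sigma2_z(self) -> float:
        """Variance of the residual polygenic value z."""
        return self.sigma2_g - self.locus_additive_variance

    @property
    def sigma2_e(self) -> float:
        """Variance of the independent individual residual e."""
        return 1.0 - self.sigma2_g - self.sigma2_v

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TwinCohort:
    """A cohort of MZ pairs: shared genotype/polygenic value, paired phenotypes."""

    G: np.ndarray
    z: np.ndarray
    yA: np.ndarray
    yB: np.ndarray
    covariates: Optional[pd.DataFrame] = None
    pair_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.G)
        for name in ("z", "yA", "yB"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has length {len(getattr(self, name))}, expected {n}")
        if self.pair_id is None:
            self.pair_id = np.arange(n)
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariate table length does not match the cohort")

    @property
    def n_pairs(self) -> int:
        return len(self.G)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"pair_id": self.pair_id, "G": self.G, "yA": self.yA, "yB": self.yB}
        )
        if self.covariates is not None:
            out = pd.concat([out, self.covariates.reset_index(drop=True)], axis=1)
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TwinCohort":
        df = pd.read_csv(path, sep="\t")
        base = {"pair_id", "G", "yA", "yB"}
        missing = base - set(df.columns)
        if missing:
            raise ValueError(f"twin cohort table is missing columns: {sorted(missing)}")
        cov_cols = [c for c in df.columns if c not in base]
        cov = df[cov_cols] if cov_cols else None
        return cls(
            G=df["G"].to_numpy(),
            z=np.zeros(len(df)),
            yA=df["yA"].to_numpy(),
            yB=df["yB"].to_numpy(),
            covariates=cov,
            pair_id=df["pair_id"].to_numpy(),
        )


@dataclass
class PopulationCohort:
    """Unrelated individuals: one genotype and one phenotype each."""

    G: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if len(self.G) != len(self.y):
            raise ValueError("G and y must have equal length")

    @property
    def n(self) -> int:
        return len(self.G)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"id": np.arange(self.n), "G": self.G, "y": self.y}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class TaggedLocusPair:
    """Genotypes at a causal locus and a second locus in LD with it."""

    G_causal: np.ndarray
    G_tag: np.ndarray
    r2_target: float


def _draw_phenotype(
    params: SimulationParams, G: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One phenotype per element of G with fresh z, v and e draws (population).

    z and e are independent constant-variance Gaussians, so they are drawn as
    a single N(0, sigma2_z + sigma2_e) term.
    """
    n = len(G)
    y = rng.normal(0.0, np.sqrt(params.sigma2_z + params.sigma2_e), n)
    if params.beta2 != 0.0:
        y += rng.normal(0.0, 1.0, n) * np.sqrt(params.beta2 * G)
    if params.beta1 != 0.0:
        y = y + params.beta1 * G
    if params.alpha_intercept != 0.0:
        y = y + params.alpha_intercept
    return y


def simulate_twin_cohort(
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    genotypes: Optional[np.ndarray] = None,
    covariates: bool = False,
) -> TwinCohort:
    """Draw a cohort of MZ pairs under the generative model.

    ``genotypes`` overrides the Binomial(2, p) draw (used for LD-tagging
    experiments where the phenotype is driven by a different locus than the
    one supplied to the test).  With ``covariates=True`` an age/sex/PC table
    is attached, drawn from the same generator.
    """
    rng = params.rng() if rng is None else rng
    n = params.n_pairs
    G = rng.binomial(2, params.p, n) if genotypes is None else np.asarray(genotypes)
    if genotypes is not None and len(G) != n:
        raise ValueError("supplied genotypes do not match n_pairs")
    z = rng.normal(0.0, np.sqrt(params.sigma2_z), n)
    sd_v = np.sqrt(params.beta2 * G)
    sd_e = np.sqrt(params.sigma2_e)
    yA = params.alpha_intercept + params.beta1 * G + z
    yB = yA.copy()
    yA = yA + rng.normal(0.0, 1.0, n) * sd_v + rng.normal(0.0, sd_e, n)
    yB = yB + rng.normal(0.0, 1.0, n) * sd_v + rng.normal(0.0, sd_e, n)
    cov = simulate_covariates(n, rng=rng) if covariates else None
    return TwinCohort(G=G, z=z, yA=yA, yB=yB, covariates=cov)


def simulate_population_cohort(
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    genotypes: Optional[np.ndarray] = None,
) -> PopulationCohort:
    """Draw unrelated individuals; marginally one randomly chosen twin per pair."""
    rng = params.rng() if rng is None else rng
    n = params.n_individuals
    G = rng.binomial(2, params.p, n) if genotypes is None else np.asarray(genotypes)
    y = _draw_phenotype(params, G, rng)
    return PopulationCohort(G=G, y=y)


def _haplotype_frequencies(p: float, r2: float) -> np.ndarray:
    """Frequencies of the four two-locus haplotypes (00, 01, 10, 11).

    Both loci have allele frequency ``p``; the gametic disequilibrium is
    D = sqrt(r2) * p * (1-p), which realises corr(G_causal, G_tag)^2 = r2.
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must lie in [0, 1], got {r2}")
    D = np.sqrt(r2) * p * (1.0 - p)
    f = np.array(
        [
            (1.0 - p) ** 2 + D,  # 0 at both loci
            p * (1.0 - p) - D,   # 0 at causal, 1 at tag
            p * (1.0 - p) - D,   # 1 at causal, 0 at tag
            p**2 + D,            # 1 at both
        ]
    )
    if np.any(f < -1e-12):
        raise ValueError(
            f"requested disequilibrium D={D:.6g} is infeasible for p={p}"
        )
    return np.clip(f, 0.0, None) / f.sum()


def tagged_r2_expected(p: float, r2: float) -> float:
    """Exact corr^2 between the locus genotypes implied by the haplotype table."""
    f = _haplotype_frequencies(p, r2)
    pa = f[2] + f[3]
    pb = f[1] + f[3]
    D = f[3] - pa * pb
    return D**2 / (pa * (1 - pa) * pb * (1 - pb))


def _draw_tagged_haplopairs(
    p: float, r2: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    f = _haplotype_frequencies(p, r2)
    cdf = np.cumsum(f)
    hap_a = np.array([0, 0, 1, 1])
    hap_b = np.array([0, 1, 0, 1])
    i1 = np.searchsorted(cdf, rng.random(n), side="right")
    i2 = np.searchsorted(cdf, rng.random(n), side="right")
    return hap_a[i1] + hap_a[i2], hap_b[i1] + hap_b[i2]


def simulate_tagged_locus(
    params: SimulationParams,
    r2: float,
    n: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> TaggedLocusPair:
    """Genotypes at a causal locus and a tag locus in LD r2, for n individuals."""
    rng = params.rng() if rng is None else rng
    n = params.n_individuals if n is None else n
    G_causal, G_tag = _draw_tagged_haplopairs(params.p, r2, n, rng)
    return TaggedLocusPair(G_causal=G_causal, G_tag=G_tag, r2_target=r2)


def simulate_tagged_twin_genotypes(
    params: SimulationParams, r2: float, rng: Optional[np.random.Generator] = None
) -> TaggedLocusPair:
    """Per-pair genotypes at a causal and a tag locus (shared within pair)."""
    rng = params.rng() if rng is None else rng
    G_causal, G_tag = _draw_tagged_haplopairs(params.p, r2, params.n_pairs, rng)
    return TaggedLocusPair(G_causal=G_causal, G_tag=G_tag, r2_target=r2)


def simulate_covariates(
    n_pairs: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    age_range: tuple[float, float] = (18.0, 70.0),
) -> pd.DataFrame:
    """Age, sex and ten genetic principal components for n pairs.

    These are test fixtures for the residualization step: age uniform over
    ``age_range``, sex Bernoulli(0.5), PCs independent standard normals.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    cols = {
        "age": rng.uniform(age_range[0], age_range[1], n_pairs),
        "sex": rng.integers(0, 2, n_pairs),
    }
    for k in range(1, N_PCS + 1):
        cols[f"PC{k}"] = rng.normal(0.0, 1.0, n_pairs)
    return pd.DataFrame(cols)


def simulate_mr_instruments(
    n_snps: int,
    true_effect: float,
    se_scale: float = 0.05,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    exposure_effect_sd: float = 0.1,
    se_exposure: float = 0.001,
) -> pd.DataFrame:
    """Harmonized instrument table with a known causal effect.

    Exposure effects are N(0, exposure_effect_sd^2); the outcome effect of
    instrument j is ``true_effect * beta_exp_j`` plus noise with standard
    deviation ``se_out_j`` (uniform around ``se_scale``).  The observed
    exposure effect carries measurement noise ``se_exposure`` (small by
    default, so inverse-variance weighting recovers ``true_effect``).
    """
    if n_snps < 2:
        raise ValueError("at least two instruments are required")
    rng = np.random.default_rng(seed) if rng is None else rng
    beta_true = rng.normal(0.0, exposure_effect_sd, n_snps)
    se_exp = np.full(n_snps, se_exposure)
    beta_exp = beta_true + rng.normal(0.0, se_exposure, n_snps)
    se_out = se_scale * rng.uniform(0.8, 1.2, n_snps)
    beta_out = true_effect * beta_true + rng.normal(0.0, 1.0, n_snps) * se_out
    return pd.DataFrame(
        {
            "snp": [f"rs{j + 1}" for j in range(n_snps)],
            "A1": "A",
            "A2": "G",
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "beta_out": beta_out,
            "se_out": se_out,
        }
    )
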