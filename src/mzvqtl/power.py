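"""Power and false-discovery simulation study for the two vQTL estimators.

The study has three parts:

* an analytic power approximation for the deviation regression model (DRM),
  used to calibrate the variance effect ``beta2`` to a target power at a
  reference sample size;
* Monte-Carlo power curves for the MZ-differences test across a grid of
  narrow-sense heritabilities, compared with DRM power at a matched sample
  size (2 x n_pairs unrelated individuals) and at a large-cohort size;
* a false-discovery experiment in which the tested locus only tags, with
  linkage disequilibrium r^2, a causal locus that carries an additive (mean)
  effect but no variance effect.  The within-pair difference cancels every
  shared term, so the MZ-differences test stays at its nominal size, while
  the population-based test sees a genotype-dependent mixture of phenotype
  means and its false-positive rate rises above nominal at incomplete LD.

The analytic DRM power uses the folded-normal mean of the absolute deviation:
E|y - m(g)| = sqrt(2/pi) * sd(y|g), with sd(y|g)^2 = c + beta2*g and
c = 1 - 2p(1-p)beta1^2 - sigma2_v.  Linearizing sqrt at the mean genotype
gives an expected slope sqrt(2/pi)*beta2 / (2*sqrt(c + 2p*beta2)) and slope
standard error sqrt((1 - 2/pi)(c + 2p*beta2) / (n * 2p(1-p))).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .association import _slope_p, drm_test
from .simulate import (
    SimulationParams,
    _draw_tagged_haplopairs,
    simulate_population_cohort,
    simulate_twin_cohort,
)

__all__ = [
    "PowerResult",
    "FDRResult",
    "analytic_drm_power",
    "calibrate_beta2",
    "power_curve",
    "fdr_study",
    "plot_power",
    "plot_fdr",
]


@dataclass
class PowerResult:
    """Monte-Carlo power of the MZ and DRM tests over a heritability grid."""

    h2_grid: np.ndarray
    power_mz: np.ndarray
    power_drm_matched: float
    power_drm_large: float
    n_pairs: int
    n_large: int
    reps: int
    alpha_sig: float
    beta2_used: float
    mc_se_mz: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mc_se_mz is None:
            self.mc_se_mz = np.sqrt(self.power_mz * (1 - self.power_mz) / self.reps)


@dataclass
class FDRResult:
    """False-positive rates at a tagging locus, per LD r^2 grid point."""

    r2_grid: np.ndarray
    fpr_mz: np.ndarray
    fpr_drm: np.ndarray
    reps: int
    alpha: float
    params: SimulationParams
    n_pairs: int
    n_individuals: int


def analytic_drm_power(
    params: SimulationParams, n: int, alpha: float = 5e-8
) -> float:
    """Normal-approximation power of the DRM slope test at sample size n."""
    if params.beta2 < 0:
        raise ValueError("beta2 must be non-negative")
    p, b1, b2 = params.p, params.beta1, params.beta2
    c = 1.0 - 2.0 * p * (1.0 - p) * b1**2 - params.sigma2_v
    vbar = c + 2.0 * p * b2
    slope = np.sqrt(2.0 / np.pi) * b2 / (2.0 * np.sqrt(vbar))
    se = np.sqrt((1.0 - 2.0 / np.pi) * vbar / (n * 2.0 * p * (1.0 - p)))
    z_crit = stats.norm.isf(alpha / 2.0)
    shift = abs(slope) / se
    return float(stats.norm.sf(z_crit - shift) + stats.norm.cdf(-z_crit - shift))


def calibrate_beta2(
    target_power: float,
    n: int,
    p: float,
    beta1: float = 0.0,
    alpha: float = 5e-8,
    beta2_max: float = 1.0,
    tol: float = 1e-4,
) -> float:
    """Variance effect giving the target analytic DRM power at sample size n."""
    if not 0.0 < target_power < 1.0:
        raise ValueError("target power must lie in (0, 1)")

    def gap(b2: float) -> float:
        pars = SimulationParams(p=p, beta1=beta1, beta2=b2, sigma2_g=2 * p * (1 - p) * beta1**2)
        return analytic_drm_power(pars, n, alpha) - target_power

    lo, hi = 0.0, beta2_max
    if gap(hi) < 0:
        raise ValueError(
            f"target power {target_power} is unreachable with beta2 <= {beta2_max}"
        )
    return float(optimize.brentq(gap, lo, hi, xtol=tol * 1e-2))


def _mz_rejections(
    params: SimulationParams, reps: int, alpha: float, rng: np.random.Generator
) -> int:
    """Replicate MZ-differences tests: |yA - yB| regressed on G, raw scale."""
    hits = 0
    for _ in range(reps):
        cohort = simulate_twin_cohort(params, rng=rng)
        if np.ptp(cohort.G) == 0:
            continue
        d = np.abs(cohort.yA - cohort.yB)
        _, _, pval = _slope_p(cohort.G.astype(float), d)
        hits += pval < alpha
    return hits


def _drm_power_sim(
    params: SimulationParams, n: int, reps: int, alpha: float, rng: np.random.Generator
) -> float:
    hits = 0
    pars = SimulationParams(
        p=params.p,
        beta1=params.beta1,
        beta2=params.beta2,
        sigma2_g=params.sigma2_g,
        n_individuals=n,
    )
    for _ in range(reps):
        cohort = simulate_population_cohort(pars, rng=rng)
        res = drm_test(cohort.y, cohort.G)
        hits += res.testable and res.p < alpha
    return hits / reps


def power_curve(
    h2_grid: Sequence[float],
    beta2: float,
    n_pairs: int = 10_000,
    n_large: int = 500_000,
    p: float = 0.3,
    beta1: float = 0.0,
    alpha: float = 5e-8,
    reps: int = 500,
    seed: Optional[int] = None,
) -> PowerResult:
    """Monte-Carlo power of both estimators across a heritability grid.

    DRM power does not depend on the heritability under this model (the
    polygenic term is absorbed into the residual), so it is computed once at
    each of the two population sample sizes.
    """
    h2_grid = np.asarray(list(h2_grid), dtype=float)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(h2_grid) + 2)
    power_mz = np.full(len(h2_grid), np.nan)
    for i, h2 in enumerate(h2_grid):
        try:
            pars = SimulationParams(
                p=p, beta1=beta1, beta2=beta2, sigma2_g=h2, n_pairs=n_pairs
            )
        except ValueError as err:
            warnings.warn(f"skipping h2={h2}: {err}")
            continue
        rng = np.random.default_rng(children[i])
        power_mz[i] = _mz_rejections(pars, reps, alpha, rng) / reps

    drm_pars = SimulationParams(p=p, beta1=beta1, beta2=beta2, sigma2_g=2 * p * (1 - p) * beta1**2)
    power_matched = _drm_power_sim(
        drm_pars, 2 * n_pairs, reps, alpha, np.random.default_rng(children[-2])
    )
    power_large = _drm_power_sim(
        drm_pars, n_large, reps, alpha, np.random.default_rng(children[-1])
    )
    return PowerResult(
        h2_grid=h2_grid,
        power_mz=power_mz,
        power_drm_matched=power_matched,
        power_drm_large=power_large,
        n_pairs=n_pairs,
        n_large=n_large,
        reps=reps,
        alpha_sig=alpha,
        beta2_used=beta2,
    )


def fdr_study(
    r2_grid: Sequence[float] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 2)),
    reps: int = 500,
    p: float = 0.1,
    beta1: float = 0.1,
    h2: float = 0.5,
    alpha: float = 0.05,
    n_pairs: int = 10_000,
    n_individuals: int = 500_000,
    seed: Optional[int] = None,
) -> FDRResult:
    """False-positive rates at a locus tagging an additive-only causal locus.

    The causal locus carries the additive effect ``beta1`` and no variance
    effect (beta2 = 0); both tests are run at the tag locus.  The MZ test
    uses the raw absolute pair difference; the DRM uses the raw phenotype of
    unrelated individuals.
    """
    r2_grid = np.asarray(list(r2_grid), dtype=float)
    params = SimulationParams(p=p, beta1=beta1, beta2=0.0, sigma2_g=h2, n_pairs=n_pairs)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(r2_grid))
    fpr_mz = np.empty(len(r2_grid))
    fpr_drm = np.empty(len(r2_grid))
    for i, r2 in enumerate(r2_grid):
        rng = np.random.default_rng(children[i])
        hits_mz = 0
        hits_drm = 0
        for _ in range(reps):
            g_c, g_t = _draw_tagged_haplopairs(p, r2, n_pairs, rng)
            cohort = simulate_twin_cohort(params, rng=rng, genotypes=g_c)
            d = np.abs(cohort.yA - cohort.yB)
            if np.ptp(g_t) > 0:
                _, _, pval = _slope_p(g_t.astype(float), d)
                hits_mz += pval < alpha

            g_c, g_t = _draw_tagged_haplopairs(p, r2, n_individuals, rng)
            pop = simulate_population_cohort(
                SimulationParams(
                    p=p, beta1=beta1, beta2=0.0, sigma2_g=h2, n_individuals=n_individuals
                ),
                rng=rng,
                genotypes=g_c,
            )
            res = drm_test(pop.y, g_t)
            hits_drm += res.testable and res.p < alpha
        fpr_mz[i] = hits_mz / reps
        fpr_drm[i] = hits_drm / reps
    return FDRResult(
        r2_grid=r2_grid,
        fpr_mz=fpr_mz,
        fpr_drm=fpr_drm,
        reps=reps,
        alpha=alpha,
        params=params,
        n_pairs=n_pairs,
        n_individuals=n_individuals,
    )


def plot_power(result: PowerResult, path: str) -> None:
    """Power of the MZ-differences test vs heritability, with DRM references."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        result.h2_grid, result.power_mz, yerr=result.mc_se_mz, marker="o",
        label=f"MZ differences ({result.n_pairs:,} pairs)",
    )
    ax.axhline(result.power_drm_matched, ls="--", color="grey",
               label=f"DRM ({2 * result.n_pairs:,} individuals)")
    ax.axhline(result.power_drm_large, ls=":", color="black",
               label=f"DRM ({result.n_large:,} individuals)")
    ax.set_xlabel("narrow-sense heritability $h^2$")
    ax.set_ylabel(f"power at $\\alpha$={result.alpha_sig:g}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fdr(result: FDRResult, path: str) -> None:
    """False-positive rate of both tests against the tagging LD r^2."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    se = np.sqrt(result.alpha * (1 - result.alpha) / result.reps)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(result.r2_grid, result.fpr_mz, yerr=se, marker="o", label="MZ differences")
    ax.errorbar(result.r2_grid, result.fpr_drm, yerr=se, marker="s", label="DRM (population)")
    ax.axhline(result.alpha, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("LD $r^2$ with the additive causal locus")
    ax.set_ylabel(f"false-positive rate at $\\alpha$={result.alpha:g}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
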