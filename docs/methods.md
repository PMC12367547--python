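# Methods

## The scientific problem

A variance quantitative trait locus (vQTL) is a variant associated with the
*variance* of a phenotype rather than its mean. Genotype-dependent variance
is the statistical footprint of environmental sensitivity: if a genotype
produces a wide range of phenotypes depending on environmental exposure, the
phenotypic variance differs across genotype groups even when the mean does
not. Population-based vQTL tests on unrelated individuals are vulnerable to
biases that family designs avoid — uncorrected stratification, dynastic
effects, assortative mating, and "phantom" variance signals at loci in
incomplete linkage disequilibrium (LD) with strong additive effects.

The monozygotic (MZ) twin-differences design sidesteps these. MZ twins share
genotype and polygenic background, so the within-pair difference cancels every
shared term; what remains is non-shared environment plus noise. Regressing
the absolute within-pair difference |y_A − y_B| on the shared genotype tests
whether the variant modulates sensitivity to the non-shared environment.

## Generative model

For twin t in pair i:

    y_it = α + β₁·G_i + z_i + v_it + e_it

| term | distribution | role |
|------|--------------|------|
| G_i  | Binomial(2, p), shared within pair | genotype (effect-allele count) |
| z_i  | N(0, σ²_g − 2p(1−p)β₁²), shared | residual polygenic value |
| v_it | N(0, β₂·G_i), per twin | variance-heterogeneity (vQTL) term |
| e_it | N(0, 1 − σ²_g − σ²_v), per twin | individual residual |

β₁ is the additive effect (phenotype SD per allele), β₂ the per-allele
variance inflation (variance units per allele), σ²_g the narrow-sense
heritability h². σ²_v is defined by the law of total variance as
σ²_v = E[var(v|G)] = 2pβ₂, which makes the unit phenotypic variance exact:
2p(1−p)β₁² + σ²_z + σ²_v + σ²_e = 1. v is drawn
independently per twin (within-pair variability comes only from v + e).
Population cohorts draw the same model once per individual, which is
marginally identical to keeping one twin per pair.

Validity constraints, enforced at construction: 0 < p < 1, β₂ ≥ 0,
σ²_g ≥ 2p(1−p)β₁² (non-negative polygenic variance), σ²_g + σ²_v ≤ 1
(non-negative residual variance).

**LD tagging.** A second locus with the same allele frequency is generated
from a two-locus haplotype table with gametic disequilibrium
D = √(r²)·p(1−p), giving corr(G, G*)² = r² exactly in expectation; genotypes
sum two independent haplotypes. This is the simplest construction reaching
any r² in [0, 1]; it keeps both allele frequencies equal, which real tag
pairs need not.

## Estimators

**MZ-differences test.** OLS of the prepared difference score on the pair
genotype, |y_A − y_B| ~ β₂·G + ε (model 1). Model 2 adds the within-pair
mean (y_A+y_B)/2 as a covariate (guards against pure mean effects, at the
price of over-correcting true vQTLs, which move both moments); model 3 skips
principal components in the phenotype preparation (for very small cohorts).
Inference uses the t reference on n − k df — indistinguishable from normal at
GWAS sample sizes.

**Phenotype preparation** is fixed-order: absolute difference → OLS
residualization on age, sex, 10 genetic PCs (+ study covariates) →
standardize → rank-based inverse-normal transform with Blom offset
(rank − 3/8)/(n + 1/4), average ranks for ties. The Blom offset is the common
GWAS convention; it is a configuration option. In the simulation studies the
raw absolute difference is used directly (no covariates exist there), which
matches the display model.

**Deviation regression model (DRM).** The population comparator: absolute
deviations from the genotype-group median, d_i = |y_i − median_{g(i)}|,
regressed on genotype. Median centring (default; mean available) makes the
test robust to additive effects at the tested locus itself. Dosages are
rounded to hard calls for grouping; groups below `min_group_size` (default
10) are excluded.

**Analytic DRM power.** For a normal conditional phenotype,
E[d|g] = √(2/π)·sd(y|g) with var(y|g) = c + β₂g, c = 1 − 2p(1−p)β₁² − σ²_v.
Linearizing √ at the mean genotype gives expected slope
√(2/π)·β₂ / (2√(c+2pβ₂)) and slope SE √((1−2/π)(c+2pβ₂)/(n·2p(1−p)));
power follows from the two-sided normal test. The linearization is accurate
to a fraction of a percent at calibration-scale effects (β₂ ≈ 0.02) and ~5%
at β₂ = 0.2. β₂ calibration inverts this by bisection (Brent) to 10⁻⁴ in
power.

## The simulation study

Defaults are the study conditions: β₂ calibrated for 80% DRM power in
500,000 unrelated individuals at α = 5×10⁻⁸ with p = 0.3, β₁ = 0
(β₂ ≈ 0.0207); MZ power over an h² grid with 10,000 pairs; DRM at a matched
size (20,000 independent individuals — whether the matched population should
instead be derived from the twin sample is not determined, so an independent
cohort is used) and at the 500,000 large-cohort size; 500 replicates per
condition with per-cell seeds spawned from a master seed. DRM power does not
depend on h² under this model (the polygenic term is absorbed into the
residual), so it is computed once per sample size.

The power-equivalence point reports the smallest grid h² at which MZ power
reaches the large-cohort DRM power within 5 percentage points, one-sided
(exceeding counts as attaining): MZ power jumps from ~0.15 at h² = 0.8 to
~1.0 at h² = 0.9, so a two-sided band of width 0.05 would usually contain no
grid point.

**False-discovery (phantom-vQTL) experiment.** The causal locus carries
β₁ = 0.1 and no variance effect; both tests run at a tag locus across an r²
grid (default 0, 0.1, …, 1), with h² = 0.5, p = 0.1, 500 repeats, rates
counted at α = 0.05. Sample sizes are not part of the published conditions;
we use 10,000 pairs and 500,000 individuals, matching the power study. The
MZ statistic is exactly null here at every r² (the pair difference cancels
all genotype-linked terms when β₂ = 0). The population test sees, within
each tag-genotype group, a mixture of phenotype means β₁·G with mixture
variance β₁²·Var(G|G*) — this inflates the DRM at incomplete LD. Note the
inflation vanishes at both r² = 0 (independence) and r² = 1 (no residual
mixture at perfect LD) and peaks at intermediate r²; at these parameter
values it is modest (false-positive rates ~0.055–0.068), so tests pool
interior grid points to detect it. The qualitative contrast — MZ flat at
nominal, population elevated under incomplete tagging — is the designed
check.

## QC and meta-analysis

Study-level summary statistics pass ordered filters (missing β/SE/p/info;
MAF < 0.01; info < 0.5; indels; monomorphic; absent from reference; allele
mismatch/ambiguous; position duplicates keeping largest n), with counts
reported per rule and a second pass removing nothing (idempotence is
tested). Harmonization to a chr:pos reference swaps alleles with a beta sign
flip and EAF complement, resolves strand flips by base complement, and
orients palindromic (A/T, C/G) variants by allele frequency when both
frequencies are at least 0.08 from 0.5, dropping them otherwise. cptids are
chr:pos:A1:A2 with A1 the effect allele; coordinates are 1-based.

Meta-analysis is inverse-variance-weighted and fixed-effect: w = 1/se²,
pooled β = Σwb/Σw, se = √(1/Σw), normal p, per-study direction string
(+/−/? in input order), sample-size-weighted mean EAF, and Cochran's Q
reported (not used as a filter). Post-meta filters: availability (non-"?"
share ≥ 50%) and the 5×10⁻⁸ genome-wide threshold. λ_median is the median
association χ² over the null median 0.4549.

## Mendelian randomization

Two-sample IVW of liability (mean-effect GWAS) on variability
(MZ-differences GWAS): after harmonization by chromosome/position with the
same orientation rules, β_IVW = Σ(b_x b_y/s_y²)/Σ(b_x²/s_y²), the
fixed-effect SE √(1/Σ(b_x²/s_y²)), Cochran's Q over Wald ratios, and a Wald
ratio fallback for a single instrument. A multiplicative random-effects SE
(inflation by √(Q/df) when Q > df) is available but fixed-effect is the
default, matching the reported scale. The child-vs-adult contrast is an
independent-samples z-test on the two IVW estimates — equivalent to a
group×exposure interaction in a two-group linear model, though the exact
regression behind the published interaction p is not fully specified, so
small discrepancies are possible. Instrument selection (LD clumping) is out
of scope; the module consumes a pre-selected list. The synthetic instrument
generator draws exposure effects N(0, 0.1²), outcome effects
true_effect·b_x plus noise at the stated outcome SEs, and near-noiseless
exposure SEs by default, so IVW recovery is unbiased (regression dilution
< 0.1% of the effect); real instrument sets have correlated LD structure and
winner's-curse-inflated exposure effects that the generator does not
emulate.

## What the synthetic data do and do not show

Passing tests demonstrate the estimators, QC algebra, meta-analysis
identities and power/FDR behaviour *under the stated generative model*:
single-locus architecture, exact Hardy–Weinberg genotypes, Gaussian
residuals, unit total variance, no missingness beyond what tests inject, no
real LD panel, European-like frequency ranges only via parameter choice.
They do not validate measurement-error handling, real imputation quality,
cross-study phenotype heterogeneity, or ancestry effects.

## Numerical choices and problem sizes

Routine unit tests run at reduced sizes (hundreds to thousands of pairs,
50–300 replicates) chosen so Monte-Carlo assertions have 3-SE tolerances;
the headline checks keep the full study conditions (500 replicates; cohorts
of 10,000 pairs and 500,000 individuals). All stochastic code takes either a
seed or a numpy Generator; grid drivers spawn per-cell child seeds from a
master SeedSequence so results are reproducible and insensitive to grid
order. Ties in the inverse-normal transform use average ranks; a constant
vector is an error (no ordering information). Monomorphic variants are
flagged untestable and excluded from GWAS output with a logged count.
Degenerate parameter sets (negative residual variance, infeasible LD) raise
at construction with the violated constraint named.

## Known limitations

- DRM inflation under tagging is demonstrated at α = 0.05 with pooled grid
  points; at genome-wide α the effect at these parameter values is far below
  detectability at 500 replicates.
- The analytic DRM power formula assumes homoskedastic OLS inference and a
  linearized folded-normal mean; both approximations are excellent at
  calibration-scale β₂ but degrade for β₂ ≳ 0.1.
- The VCF writer emits minimal GT:DS records (no phasing, no multi-allelic
  records); BGEN/PGEN are unsupported.
- MR sensitivity estimators (Egger, weighted median) are out of scope.
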