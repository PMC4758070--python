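# Methods

## Model

Read counts at a heterozygous SNV are modelled as beta-binomial: the alt
count at depth n is Binomial(n, θ) with θ ~ Beta(α, β). We use the
intraclass-correlation parameterization (p, ρ),

    α = p(1−ρ)/ρ,   β = (1−p)(1−ρ)/ρ,

so p is the mean alt fraction, ρ ∈ [0, 1) the overdispersion, and ρ = 0
recovers the binomial exactly. The variant null model BB(p⁰, ρ⁰) is
fitted by maximum likelihood to DNA-sequencing allele counts at
heterozygous sites (depth ≥ 10, ≥ 50 sites), where both alleles are
present in one copy and residual spread is technical. One global
(p⁰, ρ⁰) is fitted for the dataset; per-individual nulls are obtained by
subsetting the input. The likelihood is maximized over (p, ρ) with box
constraints (L-BFGS-B from a method-of-moments start, with a
derivative-free Nelder–Mead fallback for optima on the ρ = 0 boundary);
the log-pmf uses an ascending-factorial expansion of the Beta ratio,
which is stable in the near-binomial regime (α, β → ∞) where the betaln
difference cancels catastrophically, and it reduces to the binomial
log-pmf below ρ = 1e−12.

## Variant-level statistics

Static effect: ASE = |p − 0.5| ∈ [0, 0.5], p = alt/(alt+ref).
Condition-dependent effect: ΔASE = log2(odds(p_T)/odds(p_U)). Exact
tests: binomial test of the alt count against the variant's null ratio
(0.5 by default; a mapping-bias-adjusted ratio may be supplied per
variant), and Fisher's exact test on the 2×2 alt/ref × T/U table. Both
are two-sided by the minimum-likelihood rule (the convention of the scipy
implementations, verified against exhaustive enumeration for every table
with total ≤ 40). Depth filters: ≥ 10 reads per measurement; for the
condition-dependent variant test ≥ 100 reads summed over conditions and
alleles. BH correction within each sample.

The within-gene consistency score (SNR) is mean(|ΔASE|)/sd(|ΔASE|)
across a gene's variants (sample sd, n−1; +∞ when the spread is zero with
a positive mean); genes with SNR ≥ 2 are flagged consistent. The
sustained-effect screen reports variants whose |ΔASE| exceeds a threshold
in ≥ 2 individuals; the threshold may be given directly or as a
percentile (linear interpolation between order statistics) of observed
significant magnitudes.

## Gene-level test

Per variant, a 2×1 (static) or 2×2 (condition-dependent) count table is
formed; if any cell is zero, a pseudo-count of 1 is added to every cell
of that table. The normalized statistic is |effect|/se on the natural-log
scale:

* static: effect = ln(alt/ref); se from the 95% Wilson score interval
  for p, endpoints transformed to log-odds, se = (logit hi − logit lo)/
  (2·1.96). The Wilson construction keeps the se finite at extreme
  proportions; a delta-method alternative √(1/alt + 1/ref) is available
  via `se_method="delta"`.
* condition-dependent: effect = ln OR; se = √(1/a + 1/b + 1/c + 1/d)
  (Woolf). The log transform stabilizes the variance; the absolute value
  makes the statistic phase-free.

A gene's k statistics are Stouffer-combined: T = Σ tᵢ / √k. The null
distribution of T is resampled: per replicate and pseudo-variant, a depth
is drawn with replacement from the pooled empirical depth distribution of
all analyzed variants (per condition for the paired test), an alt count
from BB(p⁰, ρ⁰), and the table is pushed through the identical
pseudo-count/statistic/combination pipeline. One null of N draws (default
10⁵; the simulation experiments use 10⁴) is built per observed k and
shared by all genes with that k; genes with k > 100 share one aggregated
null whose replicates draw k uniformly from the observed over-cap values.
The empirical p-value is (1 + #{null ≥ T}) / (N + 1) — strictly positive,
ties counted conservatively — then BH-adjusted within each sample.

**Paired null for the condition-dependent test.** The icd null hypothesis
is "no change between conditions", not "no allelic imbalance": static
imbalance and variant-level technical noise are permitted under it. Each
pseudo-variant therefore draws a single latent θ ~ Beta(α⁰, β⁰) shared by
both conditions, with counts binomial per condition given θ. Drawing the
two conditions independently from BB⁰ would put the between-condition
consequences of static-scale noise into the null and destroy the power of
the paired design at realistic ρ; with the shared-θ null, power at
per-condition depth 50, OR 10, ρ = 0.22 is ≈ 99% (≈ 51% at depth 10),
consistent with the paired-data rationale of the method. The static null
keeps one draw per 2×1 table (the two constructions coincide there).

Pre-filtering for the main analysis: genes with ≥ 2 known-SNP variants
(configurable down to 1). For the condition-dependent analysis, genes are
gated on weak static evidence: nominal static gene p ≤ 0.2 (inclusive) in
at least one condition.

## Meta-analysis

Per-gene p-values from the m individuals in which the gene was testable
(genotypes differ) are combined by Fisher's method: χ² = −2 Σ ln p,
upper-tail p from χ² with **2m** degrees of freedom, so the single-input
identity p_meta = p holds. BH across genes; the reported call set is the
union of meta-significant and single-individual-significant genes with
provenance flags. The add-one empirical p-value convention guarantees
p > 0, so ln p is always finite.

## Synthetic data

The generators work at the allele-count level. DNA counts: alt ~
BB(depth, p₀, ρ) per site. Static genes: all k variants share a random
sign s, alt ~ BB(d, 0.5 + s·e, ρ), amplitude e ∈ [0, 0.5). Paired genes:
per variant θ_U ~ Beta(0.5, ρ), odds(θ_T) = OR^s · odds(θ_U), counts
binomial per condition at independently drawn depths; OR = 1 makes
θ_T = θ_U, the exact null reduction. Default noise ρ = 0.22, the
overdispersion level of genomic DNA data; effect grids follow the
evaluation protocol (static amplitudes 0.05–0.3, odds ratios 1.1–16,
power points at fixed depths 10/50/100 with k = 2 and 500 alternative +
500 null genes, BH FDR 5%). The mapping-bias perturbation multiplies ref
counts by (1+b) and alt counts by (1−b) with rounding and clamping at
zero (default b = 0.1).

What the generators do **not** emulate: read-level artefacts (mapping
bias as an emergent property of alignment, multiple variants per read),
genotyping error, annotation error, expression-level variation between
genes, or linkage between variants. Passing calibration/power tests on
these data therefore demonstrates the statistical machinery under the
stated count-level model, not performance on any particular cohort;
dataset-dependent headline counts from real cohorts are outside what
desk-scale simulation can reproduce.

## Numerical and design notes

* Experiments fit the null from companion simulated DNA counts (5000
  sites at fixed depth 50, same ρ) rather than plugging in the true
  parameters, mirroring the two-step procedure; problem sizes (N = 10⁴
  resamples, 2000 genes per calibration cell, 1000 genes per power
  point) were chosen so each experiment completes in seconds while
  keeping Monte-Carlo error well inside the asserted margins.
* At a fixed depth with small k the gene statistic has finite support,
  so empirical p-values are discrete: a one-sample KS test against the
  continuous uniform rejects on discreteness alone even for a perfectly
  calibrated test (type-I error remains nominal). Calibration is
  therefore checked by the equivalent exchangeability test — observed
  p-values versus p-values of fresh null draws under the identical
  p-value operator (two-sample KS, invariant under the monotone p
  transform) — plus a direct type-I error band.
* All randomness flows through a single numpy Generator per run; every
  experiment is bit-reproducible from (scenario, seed).
* Degenerate inputs: zero-depth variants are rejected at the effect-size
  layer and removed by the depth-10 filter; the ρ lower boundary reports
  a clean ρ = 0; empty result sets write header-only tables; ties in
  adjusted p order deterministically by gene id.
* Known limitations: the Wilson-based se is a documented surrogate for
  the original static se (config-switchable); per-k nulls pool depths
  across the dataset rather than resampling each gene's own depths, an
  O(k-values) approximation of gene-specific nulls; the count-level SNV
  FDR experiment cannot reproduce FDR estimates that depend on read-level
  simulation.
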