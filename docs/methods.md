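# Methods

## Dosage model

All estimators assume the standard linear relationship between an imputed
dosage and the underlying genotype at SNP m,

    E(G̃ᵢₘ | Gᵢₘ, ḠRₘ) = (1 − r²ₘ) ḠRₘ + r²ₘ Gᵢₘ,

with ḠRₘ the mean genotype of the imputation reference panel and r²ₘ the
squared dosage–genotype correlation (reported by imputation software, e.g.
BEAGLE `DR2`). Two consequences drive everything else: the centered dosage
is the centered genotype shrunk by r²ₘ, and cross-moments between two
individuals' dosages shrink by (r²ₘ)² because imputation noise is
independent between individuals. The estimators divide those factors back
out; they consume only `DS` and `DR2`/`R2` from a VCF and treat r̂²ₘ as
known (it is not re-estimated from genotype probabilities).

## Kinship estimators

Homogeneous form (sample dosage frequency p̃ₘ = Σᵢ G̃ᵢₘ / 2N):

    2φ̃ᵢⱼ = Σₘ (G̃ᵢₘ−2p̃ₘ)(G̃ⱼₘ−2p̃ₘ) / Σₘ 2p̃ₘ(1−p̃ₘ)(r̂²ₘ)²   (i ≠ j)
    2φ̃ᵢᵢ = Σₘ (G̃ᵢₘ−2p̃ₘ)² r̂²ₘ       / Σₘ 2p̃ₘ(1−p̃ₘ)(r̂²ₘ)²

The single r̂² in the self numerator (versus (r̂²)² in the pair denominator)
reflects that the self term contains the full noise variance while the pair
term contains none. The combination weights wₘ = 2p̃ₘ(1−p̃ₘ)(r̂²ₘ)²
down-weight low-MAF and poorly imputed SNPs; weights affect precision, not
expectation.

Structured/admixed form: individual-specific allele frequencies p̂ᵢₘ enter
both the centering and the weights,

    ũᵢₘ = p̃ₘ + r̂²ₘ (p̂ᵢₘ − p̂̄ₘ),   p̂̄ₘ = (1/N) Σᵢ p̂ᵢₘ,
    2φ̃ᵢⱼ = Σₘ (G̃ᵢₘ−2ũᵢₘ)(G̃ⱼₘ−2ũⱼₘ) / Σₘ 2√(p̂ᵢₘq̂ᵢₘ p̂ⱼₘq̂ⱼₘ)(r̂²ₘ)²,

with the analogous self form. The r̂² scaling of the ancestry shift is the
unique choice that removes the expected centering offset
E(G̃ᵢₘ − 2ũᵢₘ) = 2(r²ₘ − s)(qᵢₘ − q̄ₘ); the committed experiment
`scripts/calibrate_ustar_scaling.py` demonstrates this empirically against
the alternative s = √r² using an ancestry-contrast criterion that is
invariant to the noise law (the self-kinship mean cannot discriminate the
two scalings, because any bounded noise realization of the dosage model
contributes a structure-dependent variance term equally under both). The
square root over p̂ᵢq̂ᵢp̂ⱼq̂ⱼ in denominators makes the estimator collapse
onto the homogeneous form when p̂ᵢ = p̂ⱼ and onto PC-Relate when r̂² = 1;
both reductions are verified to 1e-12 in the test suite.

Individual-specific frequencies come from per-SNP OLS of reference
genotypes on the top K reference PCs (intercept included), evaluated at
each study sample's coordinates and clamped to [0.001, 0.999]. Coordinates
are an input (any upstream ancestry-placement tool); a genotype/dosage
projection onto the reference PC basis is provided for convenience.
Read-based placement (LASER-style) is out of scope; projecting noisy
dosages attenuates coordinates toward zero, so prefer upstream estimates
when dosage quality is low.

Numerical policy: per-SNP terms are accumulated blockwise (default
L = 10,000 SNPs) in double precision; results are invariant to L because
blocking is associative summation. Sites that are monomorphic in-sample or
have r̂² = 0 are dropped with a warning. With missing dosages (opt-in),
every pair accumulates numerator, denominator and SNP count over exactly
its jointly observed SNPs. Variant filters retain MAF ≥ 0.05 and
r̂² ≥ 0.5 by default (inclusive boundaries); 0.3 is a documented lower
r² alternative that trades per-SNP quality for SNP count.

Relationship classification uses the kinship ranges
(2^(−5/2), 2^(−3/2)] → PO/FS, (2^(−7/2), 2^(−5/2)] → 2nd degree,
(2^(−9/2), 2^(−7/2)] → 3rd degree; values above 2^(−3/2) are labeled
MZ/duplicate (an extension beyond the published ranges, labeled as such)
and values at or below 2^(−9/2) unrelated. PO and FS are not separated:
that requires zero-IBD-sharing probabilities, which moment kinship alone
does not provide.

## Known estimator biases at small N

Centering by in-sample frequencies (p̃ₘ, p̂̄ₘ) couples every pair to the
sample mean and biases estimates down by roughly the individuals' mean
relatedness to the sample (order 1/N plus family load). At N = 200 with a
family-heavy design this is ~0.005–0.010 — visible against a 3rd-degree
signal of 0.0625, negligible at biobank scale. The recovery tests assert
class means within ±0.015 of pedigree values with this bias included.

## Simulator

The generator produces ground truth for every estimator property:

- Subpopulation frequencies follow Balding–Nichols drift around an
  ancestral frequency p ~ U(0.05, 0.5): pₖ ~ Beta(p(1−F)/F, (1−p)(1−F)/F),
  so E(pₖ) = p and Var(pₖ) = F·p(1−p). Default F_ST = 0.1, two
  subpopulations (moderately differentiated Asian-populations scale).
- Founder admixture aᵢ ~ Dirichlet(1, …, 1) by default (fixed proportions
  supported); individual frequencies qᵢₘ = Σₖ aᵢₖ pₖₘ; founder genotypes
  Binomial(2, qᵢₘ) independently per SNP. No linkage is simulated: the
  estimators consume only per-SNP moments, and independence across loci is
  their working assumption.
- Non-founders are gene-dropped: each transmitted allele is alternative
  with probability (parental genotype)/2 per SNP, which is exact for
  unlinked biallelic loci. Family templates (trios, full-sib quartets,
  three-generation units, first-cousin units, full-sib-mating units with
  f = 0.25, singletons) yield pairs of every degree; the default study
  cohort is 200 individuals. Pedigree kinship is computed by the standard
  tabular recursion and checked against an allele-label Monte Carlo oracle.
- Imputation emulation: the default noise law is a bounded two-point
  mixture, G̃ᵢₘ = Gᵢₘ with probability r²ₘ and ḠRₘ otherwise,
  independently per individual and SNP. It satisfies the conditional-mean
  model exactly, keeps dosages in [0, 2] without clipping, and yields
  corr²(G̃, G) = r² exactly under HWE at every MAF. A Gaussian law with
  variance r²(1−r²)·2p(1−p) clipped to [0, 2] is retained as an option,
  but clipping affects 9–40% of draws under the default conditions and
  attenuates the dosage–genotype regression by ~5%, so it is suitable only
  for sensitivity analysis of miscalibrated r². The panel's reported r̂²
  equals the nominal r² by default; an option re-estimates it empirically
  from (G̃, G) to stress-test miscalibration. Per-SNP r² ~ U(0.5, 1) by
  default, emulating a mixed-quality low-coverage call set.

What the simulator does **not** emulate: linkage disequilibrium, the
haplotype-copying structure of real imputation (errors here are independent
across SNPs, so empirical variances of genome-wide estimates are smaller
than with correlated errors), reference-panel ancestry mismatch beyond a
single global ḠR, genotyping error in the "true" genotypes, and
sequencing-depth mechanics (lowering the r² distribution stands in for
lower depth, without a calibrated depth↔r² mapping). Passing tests
therefore demonstrate correctness of the estimators under their own model
assumptions, not end-to-end pipeline behavior on real reads.

## Heritability

Traits are drawn from N(0, h²K + (1−h²)I) with K = 2Φ (unit diagonal for
outbred samples, total variance 1); at h² = 0.5 this is the
y ~ N(0, 2Φ + I) family up to an overall scale that REML heritability is
invariant to. REML rotates y and the fixed-effect design into the
eigenbasis of K and maximizes the profiled restricted likelihood over
h² ∈ [0, 1] by bounded Brent search (xatol 1e-7); σ² and β are profiled in
closed form. Standard errors come from the numerical curvature of the
restricted log-likelihood. Indefinite kinship estimates are repaired by
flooring eigenvalues at 1e-6 before use; K proportional to the identity is
reported as unidentifiable (boundary flag) rather than an estimate.
Single-component only; covariates enter as a generic fixed-effect matrix
with an intercept added when absent.

Per-replicate sampling error of ĥ² in family designs of n ≈ 200 is large
(SD ≈ 0.15); recovery assertions therefore average ≥100 replicates, and the
null-boundary check uses large sibships so that truncation at h² = 0 barely
lifts the mean.

## Problem sizes

Test and acceptance workloads are sized for a laptop-class single core:
recovery runs use 200 individuals × 20,000 SNPs × 200 replicates,
classification 400 × 50,000 × 2, heritability 200 × 200 replicates,
calibration grids 30–40k draws per cell. These sizes were chosen so that
Monte Carlo standard errors are several times smaller than the asserted
tolerances.

## Command-line interface

`dosagekin {simulate, af, kinship, classify, h2}` is a thin layer over the
library. Every subcommand is deterministic given its inputs and `--seed`,
logs SNP counts at each filter stage, and writes a JSON run manifest
(resolved options, seed, package version) next to its outputs. Concurrency
is not implemented: the blocked accumulation contract (block-order
independence) is what matters for correctness, and the sequential path is
the reference.
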