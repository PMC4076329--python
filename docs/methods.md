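# Methods

This note records the models implemented in `transfinemap`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter for reproducing results.

## The fine-mapping procedure

The pipeline assumes a single associated region in which one or more causal
variants are hidden among many correlated SNPs. It operates in three stages.

**Partitioning.** Significant SNPs (nominal p < 0.05, with the
direction-consistency rule below) are greedily clumped: visiting SNPs in
order of ascending p, a SNP becomes a new index iff its r² to every accepted
index is below the independence threshold (default 0.9). Every significant
SNP is then assigned to the index with which it shows the strongest r²
(`assign_clusters`); ties break toward the physically nearer index, then
lexicographically, making partitions deterministic. SNPs whose best r² falls
below `r2_floor` (default 0.1) are reported unassigned rather than forced
into a bin. The 0.9 independence default reflects the trade-off at an
FTO-like locus: lower thresholds merge clusters that conditional analysis
could still separate, higher ones create index pairs that no realistic
sample size can distinguish.

**Screening.** Marginal association uses a direction-consistency
significance rule: p < 0.05 *and* the estimated effect must increase BMI /
disease risk on the pre-specified reference risk allele; a significant
effect in the wrong direction is treated as non-confirmation. Pairwise
conditional regression fits both SNPs' dosages jointly; a SNP is dropped
when, against **every** other screened SNP, its conditional p exceeds the
Bonferroni-adjusted level (0.05 / number of screened SNPs, recomputed from
the input — 0.0056 for a 9-SNP screen) while the partner's does not. Pairs
at r² ≥ 0.99 are declared statistically indistinguishable and do not
contest each other. Note an intrinsic property of this rule: two SNPs can
never mutually dominate, so a single screening round can only remove SNPs
that lose universally (as in the motivating study, where one SNP and its
complete proxy were removed); `exclusion_screen(iterate=True)` applies the
rule stepwise to the surviving set for workflows that want full elimination
orderings. Conditional fits are run per population and combined by
inverse-variance weighting (the default combination level; a pooled fit
with population indicators is a caller-side alternative).

**Filtering.** For each ancestry group, the proxy set of a retained index is
every SNP with r² at or above the group threshold (defaults: 0.9 for
array/HapMap-density panels, 0.95 for sequencing-density panels,
configurable per group). The candidate list is the intersection of the
per-group unions; Venn counts over all membership patterns are reported.
SNPs tagging population-specific haplotypes are intentionally *not* removed:
absence of a proxy from one group's panel is evidence, absence of the
haplotype from the population is not.

## Statistical components

**Two-locus EM.** Haplotype frequencies are estimated from the 3×3
genotype-pair table; only the double-heterozygote class is phase-ambiguous
and is split by expected counts each iteration. Start: linkage equilibrium
at observed allele frequencies; convergence: max-abs frequency change
< 1e-10 or 1000 iterations. The likelihood surface for two loci is unimodal
in practice; tests verify the EM optimum against a grid-search oracle at
1e-3 resolution. r² is clamped to [0, 1] against floating-point overshoot.

**Exact HWE test.** Conditional on allele counts, the heterozygote-count
distribution is computed by the standard recurrence and the p-value sums all
outcomes no more likely than the observed one (no mid-p correction). Used as
a QC gate with the retention rule p > 0.01; failing SNPs are flagged, never
silently dropped.

**Inverse-normal transform.** BMI is transformed per sex with Blom scores
Φ⁻¹((r − 3/8)/(n + ¼)), average ranks for ties. The 3/8 offset follows
common GWAS practice. Constant or size-<2 groups raise errors rather than
emitting zeros.

**Regression.** OLS (BMI) and maximum-likelihood logistic (T2D) fits come
from statsmodels; betas are per effect-allele copy (additive coding),
p-values are two-sided Wald. Complete separation and non-convergence raise
`FitError` rather than returning unstable estimates. Analyses are
complete-case per SNP (or SNP pair); missing genotypes are never imputed.

**Meta-analysis.** Fixed-effect inverse variance only; combination is
associative, so panel → population → trans-ethnic combining equals a
one-shot meta (verified to 1e-12). Cochran's Q uses the same weights with a
χ²(k−1) reference. Printed heterogeneity p-values from rounded
per-population cells are not recoverable (rounding error dominates Q), so
heterogeneity behaviour is validated by type-I-error simulation instead.

**Phasing and haplotype association.** Multilocus EM with exhaustive
diplotype expansion is deterministic and adequate for ≤ 12 SNPs in strong
LD; convergence at 1e-8 or 5000 iterations, haplotypes below 1e-4 pruned
after convergence. The log-likelihood is asserted non-decreasing at every
iteration. Ordered-pair posteriors are retained so per-sample dosages sum to
exactly 2. Coalescent-informed phasing (PHASE-style) can differ for rare
haplotypes; that discordance is acknowledged, not modelled. Haplotype
association regresses the trait on the posterior dosage with the same
covariates as single-SNP analysis; populations where the target haplotype is
absent (degenerate dosage) are dropped from the meta-combination with a
warning, mirroring the treatment of low-frequency haplotypes.

**Haplotype network.** Rooted at the all-ancestral haplotype (H2 for the
default set). Greedy minimum-Hamming attachment; ties toward the
higher-frequency parent, then the parent nearer the root. A multi-SNP
mutation edge is re-labelled as a recombination when the child equals a
single crossover of two placed haplotypes (one event beats k ≥ 2
substitutions); the breakpoint is reported as the SNP interval bracketing
all valid crossover points. The default frequency floor 0.004 matches the
"Low" label convention of the source frequency table; a floor of 0.05
restricts to the four principal haplotypes. The published placement of the
principal haplotypes (H2→H3→H4, H2→H1) is reproduced and asserted;
sub-haplotype placement depends on unstated event-cost assumptions and is
reported, not asserted.

**Default haplotype table.** Eight assayed SNPs define the haplotype
classes; rs7206790 shows recombination *within* classes (both alleles occur
on the same class backgrounds), so haplotype definitions default to the
seven non-recombinant SNPs, with `include_rs7206790=True` available using
its major allele. Effect alleles are the BMI/T2D-risk-increasing alleles; H1
carries all eight. Per-population frequencies code "Low" classes as 0.002
and are renormalised to sum to 1.

## Synthetic data: what it emulates, and what it does not

`simulate_panel` draws two haplotypes per individual i.i.d. from the
population's class frequencies — capturing the cross-population frequency
contrasts (e.g. ancestral H2 common only in African-ancestry panels) that
drive trans-ethnic filtering — and generates BMI additively on a
standardised scale (baseline 23, age and age² terms, Gaussian noise with
`noise_sd` default 1.0) from the number of H1 copies, plus T2D status from a
logistic model on the same count. Default effect sizes are the combined
Asian estimates for H1 (β = 0.064 z-units, OR = 1.221); baseline prevalence
0.3 reflects the enriched case fractions of the contributing case-control
panels; ages are uniform on 35–74 years and sex is Bernoulli(0.5) — cohort
demographics are emulated only to the extent of covariate presence.

Filler SNPs are created per haplotype by frequency-preserving asymmetric
allele switching (carrier switch probability (1−ρ)(1−p), non-carrier
(1−ρ)p, ρ = √r²), which hits the target r² at any allele frequency and
keeps haplotype structure coherent for phasing tests.
`simulate_clustered_panel` plants mutually independent LD clusters with an
exact truth record for clumping/assignment/conditional/filter validation.

Not emulated: coalescent genealogies, recombination maps, admixture,
genotyping error or missingness patterns, and imputation uncertainty.
Passing tests therefore demonstrate the *procedures* behave correctly under
the assumed generative model — i.i.d. diplotypes, additive effects,
logistic risk — not that they are robust to artefacts of real array data.

Simulation scale in tests and the acceptance script follows the study
conditions where stated (n = 10,000 for the BMI recovery at β = 0.07,
n = 20,000 for OR = 1.221, 1000 null replicates for Cochran's Q) and
otherwise uses panels of 1200–5000 individuals, which give comfortable
power for the planted-structure checks; the acceptance script uses 50
replicates for the two regression-recovery rates and reports the replicate
count alongside each value.

## Numerical conventions and edge cases

- Genotypes are counts of the per-variant *effect allele*; re-orienting a
  variant maps g → 2 − g and negates betas, leaving p-values unchanged.
- Coordinates are 1-based (VCF convention) in both genotype dialects; BED
  exports would be 0-based half-open.
- Multi-allelic VCF records are rejected, not split.
- PLINK-text alleles are inferred from data (allele_a = lexicographically
  smaller); monomorphic SNPs cannot round-trip their unobserved allele.
- Monomorphic SNPs raise `DegenerateError` wherever LD or association is
  undefined; proxy-set construction skips monomorphic non-index SNPs.
- Greedy choices (clumping order, cluster ties, phylogeny attachment) all
  have deterministic tie-breaks; pipeline runs are byte-identical for a
  fixed config and seed, with per-population seeds derived from the global
  seed by a counter-based scheme so that adding a stage never perturbs
  earlier stages.

## Known limitations

- Conditional screening is pairwise only; it cannot represent joint models
  of three or more SNPs and, by construction, removes at most the
  universally dominated SNP per round.
- The EM phasing posterior understates uncertainty relative to
  coalescent-informed methods for rare haplotypes.
- No Bayesian credible sets, colocalization, or annotation-informed
  prioritisation; the candidate list is a pure LD/association object.
- Genome-wide scalability is out of scope: pairwise EM LD is quadratic in
  the SNP count and intended for a single region (≈ tens of SNPs).
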