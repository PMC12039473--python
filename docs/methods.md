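# Methods

This note documents the statistical procedures `stillkit` implements,
the generative model behind its synthetic cohorts, the numerical
conventions chosen where several were defensible, and the limits of
what passing tests demonstrate.

## Variant prioritization and origin classification

Variant identity is the biallelic key (contig, 1-based position, ref,
alt) on GRCh38; multi-allelic VCF records are decomposed before any
filtering, with AD depths attributed per alternate allele. Cross-cohort
comparisons operate on variant keys with carrier lists aggregated per
variant, not on per-sample observations.

**Germline filter.** A call survives when its gene is in one of the
three primary panels, its consequence is protein-altering (missense or
nonsense), its population allele frequency is below 1% and its CADD
score above 20. Both thresholds are strict (exclusive of the
boundary): a variant at CADD exactly 20 or AF exactly 1% fails. A
variant absent from the population reference is treated as rare —
absence from the reference cannot make a variant common. Homozygous
calls are retained but flagged (`biallelic_flagged`) rather than
dropped, since the study design treats them as reportable anomalies.

**Somatic filter.** On top of the same panel/rarity/deleteriousness
predicates, somatic-caller calls need total depth ≥ 69 and alternate
reads ≥ 5. The depth floor corresponds to the shallowest
orthogonally-validated somatic call in the study design (69× with 8
variant reads). Prior somatic evidence in COSMIC waives only the
alternate-read rule — never the depth floor or the CADD threshold —
because the exception exists to rescue known clonal mutations at
marginal read support, not poorly covered or benign sites.

**Origin.** Classification is a pure function of (seen by somatic
caller, seen by germline caller, COSMIC evidence): somatic-only →
putative somatic; both with evidence → putative somatic; both without
→ uncertain; germline-only → putative germline; seen by neither is an
error. Caller concordance uses the raw call sets, so a filtered
somatic candidate that the germline caller also reported is "seen by
both" even if the germline call itself failed the germline filter.

## Enrichment testing

Each cohort-unique variant is tested with a one-sided Fisher exact
test on the 2×2 carrier table [[k, n−k], [K, N−K]] — k of n cohort
members versus K of N reference individuals — with p = P(X ≥ k) under
the fixed-margins hypergeometric null. The test uses individual
carrier counts rather than allele counts (heterozygous carriers
dominate rare-variant data, so the two coincide in practice; an
allele-count mode is available behind `RunConfig.enrichment_count_mode`
for sensitivity analysis). One-sided "greater in cohort" matches the
over-representation question being asked; control-cohort variants are
tested symmetrically with the control cohort's n.

The family for Bonferroni correction is the joint set of case-unique
plus control-unique variants (m = |case| + |control|), giving the
per-test threshold α/m. The implementation always computes α/m from
the actual family rather than hard-coding any printed threshold.
Zero cohort carriers give p = 1 by construction; the exact test is
conservative, so the family-wise error under the null sits well below
α (observed ≈ 0.006 at m = 142 over 1,000 replicates).

Printed-style proportions are carried as exact integer ratios with
percentages rounded half-up to one decimal (two decimals for
variants-per-gene), computed through `decimal` so no floating
accumulation can shift a boundary case.

## Expression analysis

Differential-expression model fitting is upstream; the module consumes
a results table and applies strict thresholds (log2FC > 1 or < −1, and
adjusted p < 0.001). "Genes shared between the top pathway terms" is
ambiguous between union, ≥2-of-3 and strict intersection; the default
is the union intersected with the DE set, because a ~170-gene
signature with almost all genes up-regulated is incompatible with a
strict 3-way intersection of modest pathway terms. All three modes are
implemented and selectable (`RunConfig.shared_gene_mode`).

Clustering is agglomerative with Ward linkage on Euclidean distance
over per-gene z-scored expression, cut to 7 clusters by default;
columns are sorted by sample id before linkage so the partition is
invariant to input order. The disease-activity regression takes one
point per cluster — cluster-mean SAS against cluster mean of the
per-sample mean z-scored expression — and fits OLS with a two-sided
t-test on the slope (n−2 df). At least 3 clusters are required.

The expression interferon score is the geometric mean of the 28
interferon-response genes divided by 10. A pseudocount of 1 is added
before the mean so zero-expression genes stay finite; a strict mode
(pseudocount 0, zeros propagate to score 0) preserves exact
homogeneity. The 28-gene list is a required input, not a built-in,
since the canonical list is defined outside this package.

## Serum scores and group statistics

The serological interferon score combines the five interferon-induced
chemokines as the arithmetic mean of log10(concentration + 1). The
upstream assay's exact scoring transform is not published; this form
was chosen because it is strictly monotone in every analyte, stable
under unit rescaling, and maps pg/mL concentrations in the 10³–10⁵
span onto the 4–5 score band where such scores are conventionally
reported. Absolute score values are therefore implementation-defined;
only orderings, shifts and correlations are meaningful, and the
score formula is pluggable.

Group comparisons use a two-sided Mann-Whitney test: exact by full
enumeration of group assignments when the combined sample size is
≤ 12 (midranks make the enumeration correct under ties), and the
tie-corrected, continuity-corrected normal approximation above that.
The switchover at 12 keeps enumeration cheap (≤ 924 assignments)
while all realistic cohort contrasts use the approximation.
Quartiles are linear-interpolation (type 7). Significance stars
follow the conventional ladder (\*, \*\*, \*\*\*, \*\*\*\* at 0.05,
0.01, 0.001, 0.0001). Pre/post treatment contrasts use the Wilcoxon
signed-rank test on matched samples (exact for ≤ 12 tie-free nonzero
differences; p = 1 when nothing changed). Pairwise p-values are
reported raw; variant-burden stratification bins carriers at
{0, 1, 2, 3+} and adds a Kruskal-Wallis omnibus across non-empty
bins. SAS severity bands partition 0–7 as mild 0–2, moderate 3–4,
severe 5–7.

## Synthetic cohort model

The generator plants every signal the pipeline is meant to recover,
with defaults at the study's conditions: 60 exome cases vs 49
controls; a 106-case biomarker cohort vs 30 controls; 27 + 10
expression samples; panels of 60/50/29 genes (139 total) plus 170
transcriptome genes.

- **Reads.** Total depth is a negative binomial around a 142× mean
  (dispersion 30, clamped to [60, 400]); alternate reads are binomial
  at the true allele fraction — 0.5 for heterozygous germline
  variants, uniform 0.08–0.30 for somatic clones. Only read *counts*
  are modelled; there is no sequence, alignment, or error model.
- **Germline planting.** Pass-filter variants arrive per sample as a
  Poisson draw (means 1.55 case / 1.16 control, matching the observed
  burden), each a fresh key in a random panel gene; failing "noise"
  variants (too common, low CADD, or non-coding) exercise the filter.
  Four variants are planted in both cohorts to exercise the shared
  partition.
- **Enrichment.** Ten designated variants are planted in exactly 4
  case samples each, while their reference carrier probability is the
  case carrier frequency divided by an odds factor of 50; background
  variants get reference carrier probabilities log-uniform on
  [10⁻⁴, 2×10⁻³], making singleton case carriers unremarkable. The
  null generator draws case and reference carriers from the same
  probability, so every rejection is a false positive.
- **Somatic planting.** Per-sample planting probability rises by age
  bracket (cases 0.20/0.30/0.50, controls 0.02/0.05/0.30), with 90%
  of somatic variants in CHIP genes. A few both-caller variants are
  added: COSMIC-backed ones (truly somatic) and unbacked ones
  (uncertain), exercising the full decision table.
- **Biomarkers.** Concentrations are log-normal per group —
  concentrations are positive and heavy-tailed, and only medians/IQRs
  are available to calibrate against. Speck and IL-18 location/scale
  are calibrated to the observed medians and IQRs (case specks 236.5
  [56.2–1693] vs control 48.1 [22.9–79.1] events/μL); other analytes
  use plausible pg/mL spans with modest case shifts. A latent
  per-sample interferon activity loads on both the serum chemokines
  (β = 0.5 on the log-median) and the interferon-response gene
  expression (γ = 0.6), which is what makes the serum and expression
  scores positively correlated. The treatment arm multiplies
  post-treatment specks by 0.4 (canakinumab) or 1.0 (placebo) with
  log-normal noise.
- **Expression.** Samples are assigned round-robin to 7 clusters; the
  signature genes shift by effect × (7 − c)/6 in each gene's planted
  DE direction, and SAS is drawn around 3 × (7 − c)/6, producing the
  monotone cluster→activity gradient the regression should find.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, clonal phylogenies, caller-specific error modes,
batch effects, count-level RNA noise, or assay detection limits.
Passing recovery tests therefore demonstrates that the pipeline's
logic is correct under its own statistical assumptions, not that the
thresholds are optimal for real sequencing data.

## Problem sizes and determinism

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configurations produce
byte-identical output files. The test suite and the acceptance script
use the default cohort sizes throughout; the null-calibration run uses
1,000 replicates of the 142-test family and the recovery runs use
single cohorts (~200 planted variants) or 100 seeded replicates for
detection rates — sizes chosen to make Monte-Carlo error small
relative to the margins being asserted while the whole suite runs in
seconds.

## Known limitations

- Tumor-only somatic calling without matched normals cannot fully
  separate high-VAF somatic variants from germline ones; the
  "uncertain" class is the honest output for both-caller variants
  without prior evidence, and no attempt is made to resolve it.
- Absolute serum interferon scores are not comparable across scoring
  transforms; only within-study contrasts are meaningful.
- The enrichment test inherits the reference's ascertainment: carrier
  counts from a population database are not age- or
  ancestry-matched controls, and the one-sided test assumes the
  reference frequency is the correct null.
- Male X-chromosome calls are flagged but VAFs are reported without
  ploidy correction.
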