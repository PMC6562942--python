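# Methods

This note documents the statistical procedures implemented in
`comopath`, the synthetic study conditions they are tested under, the
numerical choices, and the known limitations.

## Pathway-space disease overlap

**Shared-pathway matrix.** With binary membership matrix M (genes ×
pathways) over the catalog's retained gene universe, the shared-pathway
matrix is n = M Mᵀ, so n(α, β) is the number of pathways genes α and β
are both annotated to and the diagonal is each gene's own membership
count. Genes absent from the annotation have all-zero rows. Symmetry and
the bound n(α, β) ≤ min(n(α, α), n(β, β)) are asserted on every build.

**Catalog filter.** Only diseases with at least `min_genes` (default 25)
associated genes are analysed, truncated to the `top_k` (default 25)
strongest associations, so every disease contributes a comparably sized
gene set. Tied p-values are broken by input order, then gene symbol,
making the retained set deterministic.

**Overlap test.** For diseases A, B the samples are built over unordered
gene pairs of the retained universe, each counted once:

- S⁺: pairs with one gene in A's set and the other in B's (pairs within
  A ∩ B count toward S⁺, never S⁻);
- S⁻: pairs touching A or B on exactly one side, the partner ranging
  over the full retained universe;
- pairs with α = β (the diagonal) enter neither sample, so a gene shared
  by both diseases cannot drive the test through the pathways it shares
  with itself.

The one-tailed Wilcoxon rank-sum test of "S⁺ stochastically greater"
uses midranks with tie-corrected variance and a continuity correction in
the normal approximation; when both samples have at most 8 observations
the permutation distribution of the U statistic is enumerated exactly
(conditioning on the observed tie pattern). If either sample has fewer
than 3 values the test is not attempted and p = 1 is returned with a
flag. All-pairs analysis corrects by Bonferroni over the number of
tested pairs (Benjamini–Hochberg available behind a flag); no parametric
clustering is applied — the "cluster" readout is the significance
graph's connected components and per-disease neighbour counts.

A caveat the test suite quantifies rather than hides: gene pairs sharing
a gene are statistically dependent (a promiscuously annotated "hub" gene
raises all of its pair counts), so the rank-sum p-value, which assumes
independent observations, is mildly anti-conservative — roughly 6–7%
rejection at nominal 5% under the null generator. Calibration tests
therefore use independent simulation seeds as the replication unit, one
designated test per seed, with an exact binomial acceptance region.

## Pathway load and matched comorbidity

load(A, p) = m(A, p) / Σ_ρ m(A, ρ), where m(A, p) counts A's retained
genes annotated to p. The denominator counts membership *incidences*
(a gene in three pathways contributes three), normalising away how
heavily a disease's genes are annotated; loads sum to one per disease,
asserted at construction. Diseases with no annotated gene are excluded
with a warning.

Cases are patients carrying the index code (default ICD-9-CM 331.0)
aged strictly over 60. Matching is 1:1 exact on (sex, age in integer
years, race, survey year), without replacement: cases are processed in
a seeded random order and each draws a uniformly random eligible
control, so competition for scarce controls resolves reproducibly;
unmatched cases are dropped and counted. An optional ±k-year age caliper
(default 0) relaxes the age component. The matched arms have identical
key multisets by construction, which the suite asserts.

A patient counts toward a disease when any diagnosis code equals or
extends the disease's code (prefix matching follows the ICD-9-CM
hierarchy; exact matching is a switch). ratio_AD(A) = case-arm count /
control-arm count, computed only for diseases with strictly more than
`min_patients` (default 15) carriers across both arms and a non-zero
control count. Per pathway, Pearson correlation of load against ratio is
computed over the diseases present in both tables (≥ 3 required;
constant load vectors are skipped), Bonferroni-corrected over the
pathways actually tested. Restricting to a disease subset (e.g. an
inflammatory panel) is a generic filter argument, not hard-coded.

## Expression analysis

Per gene: logistic regression of diagnosis (group1 = 1) on standardised
expression plus age, sex and centre (categoricals dummy-coded; centre
omitted for single-centre studies), Wald p-value for the expression
term. Standardisation only conditions the optimisation — Wald p-values
are invariant to affine rescaling of a regressor. Genes with zero
variance, perfect separation or non-convergence are flagged with p = NaN
and never counted significant. Samples with missing covariates are
dropped globally, with counts recorded.

Pathway enrichment: with k of n measured pathway genes significant under
the chosen rule (raw α, Bonferroni over the n genes, or BH-FDR), the
p-value is the exact upper tail P(X ≥ k), X ~ Binomial(n, p₀), computed
by direct summation of the mass function. The null proportion is fixed
at p₀ = 0.05 regardless of the gene-level rule; with the worked-example
counts (15/47, 6/47, 10/47, 8/32, 53/153) this reproduces the published
values of this test to one significant figure, which is the
self-consistent reading even where the gene-level rule is described as
corrected. Cross-study concordance is Spearman correlation of per-gene
p-values on the gene intersection (≥ 5 genes), by default over the
pathway genes. Merging studies concatenates samples on the gene
intersection and prefixes the centre covariate with the study label, so
study-of-origin is absorbed by the centre term.

## qPCR quantification

Per biological sample, technical replicates are averaged per gene; the
normaliser is the arithmetic mean of the housekeeping genes'
replicate-mean CTs (equivalently the geometric mean of their linear
quantities — the two-gene combination is unordered, asserted by test).
ΔCT = CT(target) − normaliser; ΔΔCT subtracts the control-group mean
ΔCT, making the control group's mean ΔΔCT exactly zero and its geometric
mean fold exactly one; fold = 2^−ΔΔCT. Folds are invariant to adding a
constant to every CT on the plate. Group comparison is an equal-variance
two-sample t-test on ΔΔCT, where the noise model is closest to Gaussian
(folds are log-normal); testing on the fold scale is a switch. Zero
pooled variance with equal means returns p = 1 (no evidence) rather than
NaN. Biological samples are the test units; technical replicates never
are.

## Synthetic study conditions

All stages are exercised against generated data with known structure.
The reference conditions, fixed once:

- **Annotation:** 1000 genes, 200 pathways with sizes uniform on 10–20
  and members drawn uniformly, giving ≈ 3 memberships per gene — the
  density of a typical curated pathway collection, and enough tie
  structure in n(α, β) to stress the midrank machinery.
- **Catalog:** 20 diseases × 25 genes with strictly increasing synthetic
  association p-values; gene identity is independent of association
  rank. A planted pair (A, B, k) assigns k fresh genes to each disease
  (disjoint between the two, so the signal is shared pathways, not
  shared genes) and adds all 2k to three common "linker" pathways.
- **Comorbidity gradient:** optionally, one dedicated pathway receives a
  linearly increasing number of each disease's genes across the panel;
  deriving relative risks as ρ(A) = 1 + s·load(A, p*)/max load (default
  strength s = 3, i.e. relative risks up to 4) plants a linear
  load–ratio relationship spread over all diseases. The pair-linker
  pathways are unsuitable for this purpose by construction: their load
  vectors have support only on the planted pair, so near-collinear
  siblings would tie for the top correlation rank.
- **Cohort:** 50 000 discharge records; 60% of ages above 60; index
  condition only above 60 at 5% prevalence; each disease coded at 5%
  baseline prevalence, multiplied by its relative risk in index-coded
  patients; at least one filler code per record. The 5% coding
  prevalences keep per-disease carrier counts informative at this cohort
  size (the real survey this emulates is two orders of magnitude
  larger). No survey design (strata, weights) is modelled.
- **Expression:** 100 samples per group (AD/MCI/control), Gaussian noise
  (SD 1) around per-gene baselines; pathway genes shifted by
  effect_size·noise_sd in AD and half that in MCI; covariates drawn
  independently of diagnosis. Optional per-gene effect heterogeneity
  scales each gene's shift by a factor in [1−h, 1+h] that is a
  deterministic function of the gene name, so independently simulated
  studies share a dysregulation profile — without it, a strong
  homogeneous effect saturates every p-value and cross-study rank
  concordance is vacuous. The default h = 0 keeps the planted shift
  exact.
- **qPCR:** housekeeping CTs around 20, targets around 25, a per-sample
  RNA-input offset (SD 0.3 cycles) that normalisation must cancel,
  replicate noise SD 0.05 cycles, and treated-group target CTs lowered
  by log2(fold), so the expected 2^−ΔΔCT equals the requested fold.

All randomness flows from one seed; each stage draws from an
independent, deterministically derived stream, so identical
configurations give byte-identical outputs and stages can be regenerated
in isolation.

**What passing tests do and do not show.** The generator reproduces the
statistical structure the analysis assumes — not real pathway topology,
hub-gene annotation bias beyond binomial membership, survey sampling
design, linkage between association p-values and pathway membership, or
microarray normalisation artefacts. Parameter recovery here demonstrates
that the pipeline detects what it is designed to detect at realistic
sizes; it cannot validate the epidemiological assumptions (e.g. that
exact matching removes confounding in real discharge data).

## Problem sizes in the standard test run

Null calibration uses 100 seeds with one designated test per seed at the
reference conditions above. Recovery checks use 100 seeds for the
planted disease pair and 50 seeds each for the comorbidity pathway, the
47-gene expression pathway (effect 1 SD, 100 per group) and qPCR fold
recovery. The acceptance script's multi-seed sweeps use 20 sub-seeds.

## Known limitations

- The overlap test inherits the anti-conservatism described above from
  its dependent gene pairs; its p-values order disease pairs well but
  should not be read as exact tail probabilities.
- Exact rank-sum enumeration is only used when both samples are ≤ 8; at
  pipeline scale the normal approximation always applies.
- Matching treats age in integer years with no caliper by default;
  diseases whose matched controls contain no carrier are excluded rather
  than smoothed.
- The logistic GLM assumes pre-normalised, roughly Gaussian expression;
  no probe summarisation or batch correction beyond the centre covariate
  is provided.
- qPCR amplification efficiency is assumed to be exactly 2 per cycle (no
  efficiency correction, no melt-curve QC).
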