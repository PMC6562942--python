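# comopath

Multi-modal integration of genetic association, clinical co-occurrence,
expression and qPCR evidence around a shared pathway annotation.

When genome-wide association studies nominate dozens of susceptibility
genes per disease, the biology is often clearer at the level of molecular
pathways than of single genes. `comopath` implements a sequential
analysis built on that idea, with Alzheimer's disease (AD) as the index
condition:

1. **Pathway-space disease overlap.** From a disease–gene catalog
   (top-25 genes per disease by association p-value) and a KEGG-style
   pathway annotation, build the gene×gene matrix n(α, β) counting the
   pathways genes α and β share. For diseases A and B, compare the sample
   S⁺ = {n(α, β) : α ∈ A, β ∈ B} against
   S⁻ = {n(α, β) : exactly one of α, β in the corresponding disease set}
   with a one-tailed Wilcoxon rank-sum test (midranks, tie-corrected
   variance; exact enumeration for tiny samples). Self pairs (α = β) are
   excluded, so shared *genes* cannot masquerade as shared *pathways*.
   Bonferroni correction is over all disease pairs, and the significance
   graph (adjacency, connected components, per-disease neighbour counts)
   is the cluster readout.
2. **Pathway load vs comorbidity.** The pathway load
   load(A, p) = m(A, p) / Σ_ρ m(A, ρ) is the fraction of disease A's
   gene–pathway membership incidences on pathway p. From hospital-
   discharge-style records, AD cases (ICD-9-CM 331.0, age > 60) are
   1:1 exactly matched to controls on sex, age, race and survey year;
   ratio_AD(A) is the count of A-coded patients among cases over the
   count among matched controls (diseases with ≤ 15 carriers excluded).
   Per pathway, Pearson correlation of load(A, p) against ratio_AD(A)
   across diseases asks which pathway's genetic burden tracks real-world
   co-occurrence with AD.
3. **Expression dysregulation.** Per gene, logistic regression
   status ~ expression + age + sex + centre with a Wald test on the
   expression term; at the pathway level, the count k of significant
   genes among n measured is tested against Binomial(n, p₀ = 0.05) with
   the exact one-sided upper tail P(X ≥ k). Cross-study agreement is the
   Spearman correlation of per-gene p-values on the gene intersection.
4. **qPCR quantification.** 2^−ΔΔCT fold changes with multi-gene
   housekeeping normalisation, calibrated to the control group, and
   equal-variance Student's t-tests on ΔΔCT.

No external data are required: the `simulate` module generates all five
input types with plantable effects (disease pairs sharing pathway-linked
genes, a pathway whose load drives comorbidity, a dysregulated pathway,
induced fold changes), so every stage is backed by parameter-recovery
and null-calibration tests.

## Worked example

Run the end-to-end synthetic pipeline (a 20-disease panel, 200 pathways,
a 50 000-patient cohort, and a planted disease pair, comorbidity pathway
and expression effect):

```bash
comopath run-all --outdir demo --seed 1
```

The run report (`demo/run_report.json`) shows, with this seed:

- the planted pair D01–D02 is the most significant of the 190 disease
  pairs in pathway space (Bonferroni-adjusted p below double precision),
  and the diseases given elevated comorbidity form their own connected
  component in the significance graph;
- the planted comorbidity pathway ranks first among 200 pathways in the
  load–ratio correlation, r = 0.86, p = 1.2 × 10⁻⁶ (Bonferroni-adjusted
  2.4 × 10⁻⁴) across the 20 diseases passing the comorbidity filter;
- all 141 measured genes of the dysregulated pathway reach p < 0.05 in
  the per-gene GLM (binomial enrichment p ≈ 10⁻¹⁸⁴), and per-gene
  p-values from two independently simulated studies agree with Spearman
  ρ = 0.74;
- qPCR targets simulated at fold 2 are recovered at 2.04, 1.95 and 2.02
  (Jak1, Jak2, Tyk2), while the null target Jak3 reads 1.00.

Individual stages are available as `comopath simulate | overlap |
comorbidity | expression | qpcr` over the plain-text formats (catalog
TSV, GMT, cohort CSV, expression TSV + sample sheet, qPCR CSV); every
output file carries a header with the tool version, configuration hash
and seed.

As a quick library call, the exact pathway enrichment test:

```python
>>> from comopath import pathway_binomial_test
>>> pathway_binomial_test(15, 47, 0.05)   # 15 of 47 pathway genes significant
4.9601380762766e-09
```

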