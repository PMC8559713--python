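# tecsplice

A tested, reusable pipeline for a census of splice-isoform representation
in medullary thymic epithelial cells (mTEC) compared with peripheral
tissues, runnable end-to-end on synthetic data with planted ground truth.

## The scientific problem

mTEC establish central immune tolerance through *promiscuous gene
expression* (PGE): they transcribe most of the protein-coding genome so
that developing T cells can be screened against a molecular mirror of
self. Gene counts alone understate the question — self-peptidome
diversity also depends on alternative splicing, and a tissue-restricted
splice isoform that is never made in the thymus is a potential
autoimmunity liability. This package implements the analytical machinery
for asking how completely a TEC-like sample reproduces the peripheral
isoform repertoire:

* **Reproducibility filtering (npIDR).** For transcripts detected in two
  replicate pools, the non-parametric irreproducible discovery rate of an
  expression bin is the fraction of transcripts seen in exactly one
  replicate among those seen in at least one. The binned curve is
  smoothed by isotonic (non-increasing in expression) regression and
  transcripts with smoothed npIDR ≤ 0.1 are accepted.
* **Tissue specificity (τ).** For per-tissue expression x (log2(TPM+1)),
  τ = Σᵢ (1 − xᵢ/x_max) / (N − 1) ∈ [0, 1]. Genes with τ ≥ 0.9 across
  the peripheral panel are tissue-restricted antigen (TRA) genes; each is
  assigned to its maximal-expression ("iTRA") tissue. Genes down > 2-fold
  in Aire-knockout TEC at BH p < 0.05 are Aire-regulated, giving the
  three-way partition Aire-TRA / non-Aire-TRA / non-TRA.
* **Detection census.** Per-sample detection fractions over a TPM
  threshold grid, the fraction of each multi-isoform gene's annotated
  isoforms detected (TPM > 0), Shannon entropy of isoform usage
  H = −Σ pᵢ log2 pᵢ, the alternatively spliced fraction of multi-isoform
  genes by expression quartile, and an ANCOVA
  (transcripts ~ genes × group) contrasting the transcripts-per-gene
  trend of TEC against peripheral samples.
* **Junction census.** Distinct splice junctions per gene are compared
  between a TEC-like sample and each tissue with a conditional
  negative-binomial exact test (BH p < 0.05, |fc| > 2), followed by a
  one-sided Fisher test for enrichment of that tissue's iTRA genes among
  genes with more junctions in the periphery.
* **Differential splicing (PSI).** Local events (SE/RI/MX/A3/A5/AF/AL)
  are enumerated from transcript models; PSI comes either from transcript
  TPM ratios or from length-normalized inclusion/skipping counts,
  ψ = (I/ℓᵢ)/(I/ℓᵢ + S/ℓₛ). Differential events use a binomial
  likelihood-ratio test with FDR < 0.05 and |ΔPSI| > 0.2 gates, plus the
  exon-inclusion-pattern filter (mTEC mean PSI < 0.1, max < 0.2, ≥ 1
  tissue PSI > 0.5) and microexon (≤ 30 bp) summaries.
* **Aire and transcript structure.** Differential transcript usage
  (Aire-knockout vs Aire-positive), "classical" structure classification
  (coding with both 5′ and 3′ UTRs), and length / UTR / CDS shift tests
  (Kolmogorov–Smirnov, rank-sum).
* **RBFOX motif enrichment.** The WGCAUGM recognition element (W = A/U,
  M = A/C) is scanned in sense-strand windows around regulated exons
  (250 nt intron / 50 nt exon, 31-nt smoothing); enrichment against a
  background exon pool is assessed with an empirical permutation null
  (default 1000 draws) and a BH FDR ≤ 0.05 mask per offset.

Real junction tables, expression matrices or GTFs in the supported
formats can be fed to the same functions; the bundled generator exists so
that every stage is testable against known planted truth.

## Worked example

```bash
tecsplice all --config examples/toy.yaml --seed 7 --outdir results_toy
```

simulates a 120-gene, 6-tissue instance of the study design and runs
every stage. `gene_classification.tsv` starts:

```text
gene_id  tau        is_tra  is_aire_regulated  category  itra_tissue  max_tissue_expression
G0001    0.0484989  False   False              non-TRA   .            3906.67
G0002    0.0393262  False   False              non-TRA   .            1213.56
G0003    0.218807   False   False              non-TRA   .            354.509
```

Broadly expressed genes score τ ≈ 0–0.2 and are non-TRA; across the toy
run the classifier recovers 48 TRA genes (18 Aire-TRA, 30 non-Aire-TRA)
against 72 non-TRA, matching the generator's planted 40 % TRA fraction.
In `isoform_fraction.tsv` the TEC-like sample's median fraction of
annotated isoforms detected per TRA gene is 0.50 (vs 1.0 for non-TRA
genes) — exactly the planted TEC isoform restriction.
`junction_itra_enrichment.tsv` reports, per tissue, the Fisher test for
iTRA enrichment among genes with more junctions in the periphery; at toy
scale only the strongest tissue reaches significance (bladder: 8 of 8
iTRA genes with a TEC junction deficit, p ≈ 1e-12), while the full-scale
run in `scripts/acceptance.py` recovers the enrichment in every tissue.
`differential_events.tsv`, `transcript_usage.tsv` and
`motif_profile_enhanced.tsv` expose the other stages the same way, and
the `truth_*.tsv` tables hold the planted ground truth for comparison.

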