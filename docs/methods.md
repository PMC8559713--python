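# Methods

This note documents the models, statistical procedures and design
decisions behind `tecsplice`, in the order the pipeline runs them. All
coordinates are held internally as 0-based half-open intervals; GTF
boundary conversion happens only in `tecsplice.io`, so there is a single
conversion site. 5′/3′ orientation is resolved through the strand field;
unstranded transcripts are rejected by UTR decomposition and accepted
elsewhere.

## Synthetic study design

The generator (`tecsplice.simulate`) emulates a multi-tissue splicing
study: a panel of peripheral tissues (default 21, one high-depth sample
each) plus a TEC-like population sampled as immature, mature
(Aire-positive) and Aire-knockout conditions with two replicates each.
Defaults (all are `SimulationConfig` keys):

| parameter | default | meaning |
|---|---|---|
| `n_tissues` / `n_genes` | 21 / 1000 | panel breadth and gene count |
| `frac_tra` | 0.40 | fraction of genes tissue-restricted (TRA) |
| `frac_aire` | 0.40 | fraction of TRA genes Aire-dependent |
| `tec_expression_fraction` | 0.05 | TRA level in TEC vs home tissue |
| `tec_isoform_fraction` | 0.50 | fraction of a TRA gene's isoforms expressed in TEC |
| `aire_ko_fold` | 4 | knockout reduction of Aire-regulated transcripts |
| `planted_delta_psi` | 0.4 | PSI shift of regulated cassette exons |
| `motif_enrichment_rate` | 5 | planted WGCAUGM rate near enhanced exons vs background (1/kb) |
| `noise` | 0.1 | negative-binomial dispersion on all counts |
| `event_coverage` | 100 | reads per event per replicate |

Gene architectures are archetype-based. TRA genes are junction-rich
skipped-exon genes (25–40 exons, 4–8 isoforms: a full isoform plus
variants each skipping one cassette); this mirrors the observation that
heavily spliced tissue-restricted genes carry the junction signal, and
gives the per-gene junction test realistic power. Non-TRA genes mix SE
genes (4–10 exons) with two-isoform archetypes for RI, MX, A5, A3, AF and
AL events. A configurable fraction of cassettes are microexons (≤ 30 nt)
whose inclusion isoforms dominate only in the cerebellum sample; a
further fraction of non-TRA cassettes get a random usage-bias tissue, so
the exon-inclusion-pattern filter has true positives. TRA expression is
exactly zero off the home tissue (τ = 1 by construction); non-TRA genes
are present in each peripheral tissue with probability 0.9 so detection
counts vary across samples. TEC-like samples express every gene:
non-TRA at full level, TRA at `tec_expression_fraction` of home level
through a fixed isoform subset of size `max(1, round(frac · m))`. In
Aire-dependent TRA genes the Aire-regulated isoforms carry 90 % of usage
(so the knockout effect is visible at gene level), are preferentially the
TEC-expressed isoforms, are built "classical" (CDS with both UTRs) with
their terminal exon extended by ~1 kb, and are reduced `aire_ko_fold`-fold
in the knockout; sibling isoforms are untouched and skew nonclassical.
TPM values get multiplicative log-normal noise and per-sample
renormalization to 1e6; junction, transcript and gene counts are negative
binomial around TPM-proportional means. The genome is uniform-random
ACGT per gene; motif planting overwrites bases in place (sense-oriented,
reverse-complemented on minus-strand genes) at 1/kb background
everywhere, plus `motif_enrichment_rate − 1` extra expected copies per
250-nt window downstream of "enhanced" and upstream of "repressed"
cassettes. Everything is a deterministic function of the configuration;
each generator operation draws from its own seed-derived stream.

What the generator does **not** emulate: read-level sampling (no FASTQ),
realistic exon/intron length distributions, sequence composition or
conservation, correlated gene programs, mappability or annotation error.
Passing tests therefore demonstrate that the analysis chain is correct
and well calibrated under its stated noise models — not that its power
estimates transfer to any particular real dataset.

## Reproducibility filter (npIDR)

Expression-binned irreproducibility: npIDR(bin) = |detected in exactly
one replicate| / |detected in at least one|, over 20 equal-occupancy bins
on log10(TPM + 1e-3), left-closed. The raw curve is smoothed by isotonic
regression constrained non-increasing in expression (occupancy-weighted,
scikit-learn); empty bins inherit by interpolation/clipping. A transcript
is accepted when the smoothed npIDR at its expression is ≤ 0.1
(configurable). This is the standard expression-binned npIDR; no
particular published refinement of it is claimed.

## Gene classification

τ is computed on log2(TPM + 1)-transformed per-tissue summaries (the
common practice; a config flag disables the transform — on the raw scale
τ is exactly scale-invariant, after the log transform only ordering is
guaranteed). The tissue panel for τ excludes TEC-like samples: tissue
restriction is scored against the periphery only. Restriction is τ ≥ 0.9
(inclusive comparison); home tissue is the raw-expression argmax with
lexicographic tie-breaking (ties are logged). Aire regulation requires
fold change > 2 **down** in the knockout and BH p < 0.05; fold changes
are always reported as a positive magnitude with a `direction` field to
avoid sign ambiguity. Splicing-factor-style analyses reuse the same
machinery at τ > 0.5 with a user gene list.

## Count statistics

Library-size factors are column totals over their geometric mean. The
two-group test is a conditional exact test on the group sums: given
s = a + b, at dispersion 0 the group-A sum is Binomial(s, π) with π
proportional to summed size factors — the exact binomial test — and at
dispersion φ > 0 it follows the conditional law of two negative binomials
with group-sum dispersions φ/n_reps (the µ plug-in cancels at equal
factors). Two-sided p-values double the smaller tail, capped at 1. For
very large totals (s > 20 000) the smooth conditional density is
evaluated on a uniform ~20 000-point grid; the stride cancels in
normalization and tail sums are accurate to well below p-value
resolution. Fold changes use normalized means with a 0.5 pseudo-count.
No-replicate comparisons (the junction census) use a fixed dispersion,
default 0.1. BH adjustment is the standard step-up (statsmodels); note
that BH is *not* idempotent in general, so only monotonicity and
order-invariance are asserted. Fisher tests use the minimum-likelihood
two-sided convention; odds ratios are the sample estimate ad/bc with
OR = ∞ when bc = 0 and ad > 0 (serialized as the string "inf" in TSV) and
missing for 0/0.

The junction census counts **distinct junctions per gene** with ≥ 1
supporting read (configurable), not junction-spanning reads, matching how
per-gene junction numbers are usually reported; per gene the TEC-like
sample is tested against one tissue sample in no-replicate mode, and
significance needs BH p < 0.05 and |fc| > 2. The per-tissue enrichment
is a one-sided Fisher test of {significantly more junctions in the
tissue} × {iTRA of that tissue} over all tested genes. Set-overlap
enrichment requires an explicit universe argument — there is no sensible
default universe for overlap statistics.

## Events and differential splicing

Events are enumerated by pairwise transcript-structure comparison with
coordinate-derived ids (`TYPE:gene:chrom:coords:strand`). A5/A3 naming is
strand-aware (a genomic-left alternative donor on the minus strand is an
A3); AF/AL require non-overlapping terminal exons sharing the inner
splice site, with inclusion defined as the distal form; for A5/A3 the
longer exonic form is "inclusion"; for RI the retaining form. PSI has two
routes: transcript-ratio (Σ TPM inclusion / Σ TPM of the event, missing
below 1 TPM) and count-based, ψ = (I/ℓᵢ)/(I/ℓᵢ + S/ℓₛ), with
junction-count effective lengths (2 for SE inclusion, 1 for skipping),
missing below 10 reads. Differential events use a closed-form binomial
likelihood-ratio test on pooled inclusion proportions per condition
(χ² with 1 df), BH across tested events, with the caller's FDR and
|ΔPSI| gates; a hierarchical read-level model is deliberately not
replicated — at the decision-rule level the thresholds carry the
conclusions. The microexon cutoff (≤ 30 nt) is inclusive.

## Aire transcript structure

Transcript length is mature length (sum of exon lengths), not genomic
span — the natural metric for "transcripts". "Classical" means a coding
transcript with non-empty 5′ and 3′ UTRs. Usage tests reuse the NB exact
test per transcript (fold ≥ 2, BH p < 0.05, higher in Aire-positive);
length comparisons (restricted to genes with ≥ 1 significantly regulated
transcript) use the exact two-sample KS statistic and the two-sided
Mann–Whitney test with midranks and tie correction.

## Motif enrichment

Windows are 250 nt of intron and 50 nt of exon at each boundary with a
31-nt smoothing window (rMAPS-style conventions); coverage at an offset
is the fraction of exons with ≥ 1 match-start within the smoothing window,
computed on the sense strand with U/T equivalence and overlapping matches
counted. Flanks truncated at gene ends drop out of that offset's
denominator. The null resamples same-size exon sets from the unregulated
background pool (preserving sequence composition, unlike shuffling);
empirical p = (1 + #{null ≥ obs})/(n_perm + 1), never zero. Significance
is BH ≤ 0.05 across offsets. Caveat of that choice: when a flank carries
a strong true signal, the BH threshold rises and occasional correlated
blocks of null offsets elsewhere can cross it; conclusions should be read
per region (the planted flank saturates; the opposite flank stays far
below it), which is how the tests assert the pattern. A
permutation max-statistic control would avoid this at the cost of power;
BH was chosen as the conventional reading of a per-offset FDR mask.

## Problem sizes and determinism

The packaged toy configuration (120 genes, 6 tissues, 300 permutations)
exercises every stage in a few seconds; the full-scale configuration used
by `scripts/acceptance.py` and the planted-truth tests (1000 genes, 21
tissues, 1000 permutations) runs in well under a minute. All pipeline
outputs are byte-identical across runs with the same seed and
configuration: every random draw comes from seed-derived generator
streams, TSV floats are formatted to six significant digits, and all
orderings are explicit.

## Known limitations

* The npIDR module implements the standard expression-binned estimator;
  whatever refinements a specific study applied on top are not modelled.
* The NB exact test uses a fixed, user-supplied dispersion rather than
  empirical-Bayes moderation; with dispersion 0.1 and two replicates its
  power saturates for very large counts (the conditional spread grows
  with the total), which is faithful to the model but means deeper
  sequencing does not buy significance indefinitely.
* Event enumeration assumes clean shared flanking boundaries; partially
  overlapping flank variants are reported as separate A5/A3 events rather
  than merged complexes.
* Transcript-ratio PSI inherits whatever quantification bias the input
  TPMs carry; no re-quantification is attempted.
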