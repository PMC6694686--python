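# allelescan

Design of personalized and allele-specific CRISPR sgRNAs from an
individual's phased genetic variants, and optimization of small guide-pair
sets to cover the maximum number of individuals in a cohort.

## The problem

CRISPR guides are usually designed against a reference genome, but people
are not the reference. A heterozygous variant can create or destroy a PAM
(protospacer adjacent motif, e.g. NGG for SpCas9) or change the protospacer
an sgRNA hybridizes to. That is both a hazard — reference-designed guides
silently mismatch personal genomes — and an opportunity: a guide that
incorporates a heterozygous variant perfectly matches only one of the two
haplotypes, enabling **allele-specific** editing (e.g. excising one coding
allele of a dominant-negative disease gene while leaving the other intact).

`allelescan` implements that whole chain for phased diploid cohorts:

1. **PAM scanning** — locate every occurrence of each Cas enzyme's IUPAC
   PAM motif on both strands of a reference (`scan_sequence`, `scan_genome`).
   The default registry ships 11 enzymes (SpCas9 NGG, SaCas9 NNGRRT, 5′-PAM
   Cas12a enzymes, ...) and is user-extensible.
2. **Variant annotation** — for each variant × Cas, reconstruct both allele
   sequences (indel-aware) and decide whether the alternate allele *makes*
   or *breaks* a PAM, and whether the variant falls in the 20-bp protospacer
   window of any PAM on either allele (`annotate_variant`,
   `annotate_cohort`). Variants touching only an unconstrained 'N' PAM
   position change nothing and are ignored.
3. **Guide design** — enumerate allele-resolved protospacer+PAM candidates
   anchored at a variant (`enumerate_guides`), classify them per sample and
   haplotype (`classify_allele_specific`), or design *personalized* guides
   on the individual's own sequence — homozygous variants incorporated,
   heterozygous ones avoided (`design_personalized`). Precomputed
   specificity scores can be used as a filter (`filter_by_specificity`).
4. **Targetability** — a gene is *putatively targetable* in an individual
   if two allele-specific sites < 10 kb apart lie in cis and their excision
   span disrupts a coding exon (paired strategy), or a single
   allele-specific guide sits in a coding exon (single strategy)
   (`cohort_targetability`).
5. **Coverage optimization** — choosing ≤ k guide pairs to cover the most
   individuals is a maximum-coverage problem, solved exactly as a binary
   integer linear program

       max Σ_s y_s   s.t.   Σ_p x_p ≤ k,   y_s ≤ Σ_{p∈N(s)} x_p,   x, y ∈ {0,1}

   (`solve_max_coverage_ilp`, HiGHS backend), alongside the naive
   "top-k most shared pairs" baseline, a greedy heuristic and an
   exhaustive oracle (`top_k_baseline`, `greedy_max_coverage`,
   `exhaustive_oracle`).

A fixtures module generates a deterministic synthetic world — toy genome,
phased cohort with founder-block haplotype sharing, gene models, optional
planted guide-pair signals — so every stage is testable offline.

## Worked example

```bash
allelescan make-fixtures --seed 7 --out fix --n-samples 8 --n-variants 40
allelescan targetability --vcf fix/cohort.vcf --fasta fix/genome.fa \
    --genes fix/genes.tsv --flank 5000 --out tgt
```

or, in Python, the same pipeline the acceptance script runs:

```python
>>> from scripts.acceptance import run
>>> run(seed=1)
{'pam_sites_total': 56673,
 'mean_targetable_fraction_flank0': 0.59,
 'mean_targetable_fraction_flank5k': 0.855,
 'mean_ilp_coverage_k5': 0.785,
 'mean_top5_coverage': 0.635}
```

Reading: the default 11-enzyme registry finds 56,673 PAM occurrences on the
100-kb toy genome; the average synthetic individual is pair-targetable at
59% of the 5 toy genes, rising to 85.5% when 5-kb flanking regions are
included (more room for cis site pairs); and an optimal combination of 5
SpCas9 guide pairs covers on average 78.5% of the 40-sample cohort per
gene, versus 63.5% for the naive top-5 most-shared pairs — the ILP avoids
picking pairs that are common in the same subgroup of people.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic world from the seed and recomputes the full
pipeline — PAM scan, cohort annotation, targetability with and without
flanks, and ILP-vs-top-5 coverage — printing the summary above.
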