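# Methods

## Scope and model

`allelescan` classifies how genetic variants interact with CRISPR target
sites and turns that classification into per-individual gene targetability
and cohort-level guide-pair selection. It operates on three abstractions:

* a **Cas enzyme** = (IUPAC PAM motif, PAM side, protospacer length);
* a **variant** = biallelic (ref, alt) at a 0-based reference position,
  SNV or short indel, with phased diploid genotypes per sample;
* a **gene model** = a reference span plus disjoint coding exons.

All coordinates are 0-based half-open on the forward strand; VCF's 1-based
POS is converted exactly once, at the VCF reader boundary.

## PAM algebra and scanning

A motif position matches a window base iff the base is in the position's
IUPAC expansion. Two deliberate choices:

* **PAM size** counts every non-N motif position as constraining, including
  degenerate codes (R, Y, ...): NGG has size 2, NNGRRT size 4.
* **Assembly 'N' bases never match**, even against motif 'N': an unknown
  base cannot be confirmed as part of a PAM. Soft-masked lowercase bases
  are treated as their uppercase equivalents — masking is irrelevant to
  PAM presence.

Scanning reports *every* occurrence on both strands, overlapping and
nested alike, since each anchors distinct guides. The scanner is a
vectorized per-position set-membership test; the test suite checks it
against an independent naive window enumerator on random sequences for all
registry enzymes.

The default registry lists 11 commonly used enzymes (SpCas9, SpCas9-VQR,
SpCas9-VRER, SpCas9-EQR, SaCas9, SaCas9-KKH, NmeCas9, CjCas9, StCas9,
AsCas12a, LbCas12a). The set is representative, not canonical: only the
SpCas9/SaCas9/Cas12a identities are fixed by the method's description, and
the registry is a YAML file users can replace.

## Allele windows and the make/break/near flags

For a variant × Cas, both allele sequences are reconstructed locally with
flank = protospacer_length + PAM length (sufficient to contain every
occurrence whose protospacer or PAM can touch the variant), clipped at
contig edges. Flags:

* `makes_pam` — an occurrence exists on the alt window with no homologous
  occurrence on the ref window; `breaks_pam` — the converse. Both can be
  true at once.
* `var_near_pam` — the variant's *minimal edit* (alleles trimmed of their
  common prefix/suffix) intersects the protospacer window of an occurrence
  on either allele: the 20 bp 5′ of the PAM for 3′-PAM enzymes, 3′ of the
  PAM for 5′-PAM (Cas12a-family) enzymes.

**Homologous correspondence** between allele windows is the subtle part,
since an indel shifts coordinates. For length-preserving variants both
windows share one coordinate system and occurrences compare positionally —
which makes the N-position rule automatic: a substitution at an
unconstrained motif position leaves the occurrence present on both alleles
and sets neither flag. For indels, occurrences strictly 5′ of the edit
compare by left-anchored offset, strictly 3′ by right-anchored offset
(distance from the window end), and occurrences overlapping the edited
bases compare by existence per strand within the edited neighborhood.
Double anchoring prevents spurious make/break calls far from an indel;
existence-comparison in the edited neighborhood is deliberately coarse —
an indel that replaces one overlapping occurrence by another at a shifted
offset is not called make+break. This is the weakest defensible reading;
the flags are inputs to *site existence*, and guide enumeration re-derives
discriminability explicitly.

## Guide enumeration and discriminability

`enumerate_guides` emits, for the chosen allele, one guide per PAM
occurrence per strand whose protospacer or PAM overlaps the variant's
minimal edit — **provided the guide discriminates between alleles**:

* variant in the protospacer → the two allele protospacers differ → keep;
* variant only in the PAM → keep iff the homologous occurrence is absent
  on the other allele (the variant hits a constrained position). A variant
  touching only the 'N' of NGG leaves an identical protospacer and a valid
  PAM on both alleles and is never emitted.

This resolves a tension between "every overlapping occurrence yields a
guide" and "guides are discriminating by construction" in favor of the
latter; it is also what the N-position exclusion demands.

Guides spanning an indel report their footprint projected to reference
space (inserted bases collapse onto the insertion point), so downstream
interval logic (exon overlap, pair distance) stays in reference
coordinates. Phase encoding is fixed: hapA is the first allele of the
phased GT field, hapB the second.

`design_personalized` builds the sample's personalized sequence
(homozygous-alt substituted), enumerates all guides on it, and rejects any
whose footprint overlaps a heterozygous variant; tests verify the returned
protospacer+PAM strings occur exactly in both reconstructed haplotype
sequences. Specificity scores are a pluggable precomputed table — scoring
engines are external and not re-implemented.

## Targetability

Paired strategy: all unordered same-Cas site pairs with both targeted
alleles on the same haplotype and positions < `max_distance` (default
10,000 bp) apart; a gene is targetable iff some pair's excision span
(inclusive of both site positions) overlaps a coding exon. Overlap is the
default reading of "disrupt"; full exon containment is available via
`require_containment=True`. Pair distance is measured between variant
positions, not predicted cut sites, to avoid enzyme-specific cut-offset
models. The search region is the gene span, optionally extended by `flank`
(5,000 bp reproduces the flanking-region scenario); flank only ever adds
sites, so targetability is monotone in it, as it is in `max_distance` and
in registry size.

Single strategy: one allele-specific site whose tightest guide footprint
intersects a coding exon.

Heterozygous sites contribute a site on *each* haplotype for which a
discriminating guide exists on the allele that haplotype carries
(ref-allele guides target the ref haplotype and vice versa). Unphased
heterozygous genotypes are an error, not a guess: pairing is
phase-dependent.

"Putatively targetable" asserts that qualifying sites exist — not that
cutting will be allele-exclusive or that exon excision will abolish
expression.

## Coverage optimization

The cover graph joins pair ids `(v1, v2, Cas)` to the samples in which
both variants are heterozygous with targeted alleles in cis. Selection of
≤ k pairs maximizing covered individuals is solved exactly as the binary
ILP in the README via `scipy.optimize.milp` (HiGHS); the model, not the
engine, is the contract, and the coverage of a solution is always
recomputed from the chosen set rather than trusted from solver indicator
values. Ties between optima are solver-determined; tests canonicalize via
the exhaustive oracle (lexicographically smallest optimal subset) and
compare coverage values, not chosen sets. The top-k baseline ranks pairs
by neighborhood size with lexicographic tie-break. The greedy helper
exists as the classical (1 − 1/e) reference point and is tested against
that bound.

## Synthetic worlds

The fixture generator states one world per spec and seed:

* genome: uniform-random ACGT (default one 100-kb contig) — no repeat or
  GC structure;
* cohort: default 50 samples, 300 variants (10% short indels ≤ 5 bp), MAF
  uniform on [0.05, 0.5]. Haplotype sharing via founders: each 10-kb block
  carries 20 founder haplotypes; every sample haplotype copies one founder
  per block, biased 3:1 toward founders of its own group (two groups by
  default). A variant's alt allele is assigned to round(MAF × 20)
  founders, so realized frequencies concentrate near target (±0.05 at 500
  samples). Founder copying is what creates shared cis pairs — and the
  redundancy among top-shared pairs that makes the ILP strictly beat the
  naive top-5 baseline on these cohorts;
* genes: 2–10 coding exons, 3–15-kb spans, non-overlapping, placed left to
  right;
* planted pairs: two SNVs, each inside an SpCas9 protospacer, 0.5–8 kb
  apart around a chosen exon, heterozygous in cis (alt on hapB) in an
  exact sample subset and absent elsewhere — ground truth for recovery
  tests.

What a green test does *not* establish: behavior on real haplotype
structure (recombination gradients, rare variants, population-specific
LD), on multi-contig genomes at scale, or any experimental editing
outcome. The generator is a structural stand-in for a phased cohort, not
a population-genetic simulation.

## Numerical and degenerate-input choices

* Windows are clipped at contig edges; guides whose protospacer would run
  off the sequence are skipped with a warning.
* Multiallelic VCF records are split per alt allele before annotation;
  symbolic alleles are skipped. Unsorted VCFs and contigs missing from the
  FASTA are errors.
* An empty cohort, an edge-less cover graph, or k exceeding the number of
  pairs are all legal degenerate inputs with defined results; k < 1 is an
  error. The exhaustive oracle refuses more than 20 pairs.
* Witness pairs tie-break by (smallest excision span, leftmost position).
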