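"""Gene-level putative targetability per individual.

Two strategies are evaluated:

* **paired (excision)** — a gene is putatively targetable in an individual
  if two allele-specific sgRNA sites exist less than ``max_distance`` apart
  (default 10 kb) on the *same haplotype*, and excising the intervening
  segment would disrupt a coding exon. Optionally the search region is the
  gene span extended by ``flank`` bases on each side (5 kb reproduces the
  extended scenario).
* **single** — a single allele-specific guide whose reference footprint lies
  within a coding exon.

"Disrupt a coding exon" is operationalized as excision-span ∩ coding-exon
≠ ∅ (the weakest defensible reading); a stricter full-containment reading
is available via ``require_containment``. "Putatively" is load-bearing:
the classification asserts that qualifying sites exist, not that editing
will succeed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd
import pysam
from pyfaidx import Fasta

from .annotate import Variant, iter_vcf_variants
from .cas import CasRegistry
from .design import SampleGenotype, enumerate_guides

__all__ = [
    "GeneModel",
    "AlleleSpecificSite",
    "GuidePairSite",
    "TargetabilityRecord",
    "find_pairs",
    "gene_targetable_paired",
    "gene_targetable_single",
    "cohort_targetability",
    "read_gene_table",
    "collect_sites",
]

DEFAULT_MAX_DISTANCE = 10_000
DEFAULT_FLANK = 0


@dataclass(frozen=True)
class GeneModel:
    """A gene span (introns included) with its coding exons."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: bad gene span")
        prev = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside span")
            if prev is not None and s < prev:
                raise ValueError(f"{self.gene_id}: exons unsorted/overlapping")
            prev = e


@dataclass(frozen=True)
class AlleleSpecificSite:
    """A heterozygous variant usable as an allele-specific guide site in one
    sample, on one haplotype, for one Cas."""

    sample: str
    vid: str
    contig: str
    pos: int
    haplotype: str  # 'hapA' | 'hapB'
    cas_name: str
    ref_start: int | None = None  # tightest guide footprint, if known
    ref_end: int | None = None


@dataclass(frozen=True)
class GuidePairSite:
    """Two same-haplotype allele-specific sites defining an excision span."""

    v1: str
    v2: str
    pos1: int
    pos2: int
    cas_name: str
    haplotype: str

    def __post_init__(self) -> None:
        if self.pos2 < self.pos1:
            raise ValueError("pair positions must be ordered (pos1 <= pos2)")

    @property
    def span(self) -> tuple[int, int]:
        """Excision interval, half-open, inclusive of both site positions."""
        return self.pos1, self.pos2 + 1

    @property
    def length(self) -> int:
        return self.pos2 - self.pos1

    @property
    def pair_id(self) -> str:
        return f"{self.v1}|{self.v2}|{self.cas_name}"


@dataclass(frozen=True)
class TargetabilityRecord:
    sample: str
    gene_id: str
    cas_name: str
    strategy: str  # 'paired' | 'single'
    targetable: bool
    witness: GuidePairSite | AlleleSpecificSite | None = None
    reason: str | None = None


def find_pairs(
    sites: list[AlleleSpecificSite],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> list[GuidePairSite]:
    """All unordered site pairs < ``max_distance`` apart in cis.

    Pairs mixing haplotypes are excluded: the two cuts must fall on the
    chromosome copy being excised.
    """
    out = []
    for a, b in combinations(sorted(sites, key=lambda s: (s.pos, s.vid)), 2):
        if a.haplotype != b.haplotype or a.cas_name != b.cas_name:
            continue
        if a.vid == b.vid:
            continue
        if abs(b.pos - a.pos) < max_distance:
            out.append(
                GuidePairSite(
                    v1=a.vid, v2=b.vid, pos1=a.pos, pos2=b.pos,
                    cas_name=a.cas_name, haplotype=a.haplotype,
                )
            )
    return out


def _overlap(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def gene_targetable_paired(
    gene: GeneModel,
    pairs: list[GuidePairSite],
    flank: int = DEFAULT_FLANK,
    sample: str = "",
    require_containment: bool = False,
) -> TargetabilityRecord:
    """Paired-strategy verdict for one gene.

    Only pairs whose sites lie within the gene span extended by ``flank``
    are considered. Targetable iff some pair's excision span overlaps (or,
    under ``require_containment``, fully contains) a coding exon; the
    witness is the qualifying pair with the smallest excision span, ties
    broken leftmost.
    """
    cas = pairs[0].cas_name if pairs else ""
    if not gene.exons:
        return TargetabilityRecord(
            sample, gene.gene_id, cas, "paired", False, reason="no_coding_exons"
        )
    lo, hi = gene.start - flank, gene.end + flank
    best: GuidePairSite | None = None
    for p in pairs:
        if not (lo <= p.pos1 and p.pos2 < hi):
            continue
        s0, s1 = p.span
        if require_containment:
            hit = any(s0 <= e0 and e1 <= s1 for e0, e1 in gene.exons)
        else:
            hit = any(_overlap(s0, s1, e0, e1) for e0, e1 in gene.exons)
        if hit and (
            best is None
            or (p.length, p.pos1) < (best.length, best.pos1)
        ):
            best = p
    return TargetabilityRecord(
        sample, gene.gene_id, cas, "paired", best is not None, witness=best
    )


def gene_targetable_single(
    gene: GeneModel,
    sites: list[AlleleSpecificSite],
    sample: str = "",
) -> TargetabilityRecord:
    """Single-guide verdict: an allele-specific guide footprint inside a
    coding exon. Sites without a recorded footprint use their variant
    position as a point footprint."""
    cas = sites[0].cas_name if sites else ""
    if not gene.exons:
        return TargetabilityRecord(
            sample, gene.gene_id, cas, "single", False, reason="no_coding_exons"
        )
    for s in sorted(sites, key=lambda s: s.pos):
        f0 = s.ref_start if s.ref_start is not None else s.pos
        f1 = s.ref_end if s.ref_end is not None else s.pos + 1
        if any(_overlap(f0, f1, e0, e1) for e0, e1 in gene.exons):
            return TargetabilityRecord(
                sample, gene.gene_id, cas, "single", True, witness=s
            )
    return TargetabilityRecord(sample, gene.gene_id, cas, "single", False)


def _genotype_of(rec, sample: str, vid: str, alt_index: int) -> SampleGenotype:
    call = rec.samples[sample]
    gt = call.get("GT")
    if gt is None or len(gt) != 2:
        return SampleGenotype(sample, vid, None, None, phased=False)
    a, b = gt
    conv = lambda x: None if x is None else (1 if x == alt_index else 0)
    return SampleGenotype(sample, vid, conv(a), conv(b), phased=bool(call.phased))


def collect_sites(
    vcf_path: str | Path,
    fasta_path: str | Path,
    registry: CasRegistry,
    samples: list[str] | None = None,
    region: tuple[str, int, int] | None = None,
) -> tuple[list[AlleleSpecificSite], list[str]]:
    """Allele-specific sites for every sample × variant × Cas in a VCF.

    A heterozygous variant contributes a site on a haplotype iff a
    discriminating guide exists for the allele that haplotype carries
    (ref-allele guides target the ref-bearing haplotype and vice versa).
    Unphased heterozygous genotypes raise: pairing is phase-dependent.
    """
    fasta = Fasta(str(fasta_path), sequence_always_upper=True)
    contig_cache: dict[str, str] = {}
    with pysam.VariantFile(str(vcf_path)) as vcf:
        vcf_samples = list(vcf.header.samples)
    if samples is None:
        samples = vcf_samples
    missing = sorted(set(samples) - set(vcf_samples))
    if missing:
        raise ValueError(f"samples absent from VCF: {missing}")

    sites: list[AlleleSpecificSite] = []
    for variant, rec in iter_vcf_variants(vcf_path):
        if region is not None:
            rcontig, rlo, rhi = region
            if variant.contig != rcontig or not (rlo <= variant.pos < rhi):
                continue
        if variant.contig not in contig_cache:
            if variant.contig not in fasta:
                raise ValueError(f"contig {variant.contig!r} absent from FASTA")
            contig_cache[variant.contig] = str(fasta[variant.contig])
        seq = contig_cache[variant.contig]
        alt_index = (rec.alts or ()).index(variant.alt) + 1 if rec.alts else 1

        # per-Cas, per-allele guide existence, computed once per variant
        for cas in registry.enzymes:
            per_allele: dict[str, list] = {}
            for allele in ("ref", "alt"):
                per_allele[allele] = enumerate_guides(variant, seq, cas, allele)
            if not (per_allele["ref"] or per_allele["alt"]):
                continue
            for sample in samples:
                gt = _genotype_of(rec, sample, variant.vid, alt_index)
                if gt.hapA is None or gt.hapB is None or gt.hapA == gt.hapB:
                    continue
                if not gt.phased:
                    raise ValueError(
                        f"{sample}@{variant.vid}: unphased heterozygous "
                        "genotype; phase the VCF (pairing is phase-dependent)"
                    )
                for hap, allele_idx in (("hapA", gt.hapA), ("hapB", gt.hapB)):
                    allele = "alt" if allele_idx == 1 else "ref"
                    guides = per_allele[allele]
                    if not guides:
                        continue
                    f0 = min(g.ref_start for g in guides)
                    f1 = max(g.ref_end for g in guides)
                    sites.append(
                        AlleleSpecificSite(
                            sample=sample,
                            vid=variant.vid,
                            contig=variant.contig,
                            pos=variant.pos,
                            haplotype=hap,
                            cas_name=cas.name,
                            ref_start=f0,
                            ref_end=f1,
                        )
                    )
    return sites, samples


def cohort_targetability(
    genes: list[GeneModel],
    vcf_path: str | Path,
    fasta_path: str | Path,
    registry: CasRegistry,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    flank: int = DEFAULT_FLANK,
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Targetability of every gene in every sample under every Cas.

    Returns (record table, per-sample fraction of genes targetable by the
    paired strategy under any Cas, per-gene fraction of samples targetable).
    The record table has one row per sample × gene × Cas with
    ``paired_targetable``/``single_targetable`` columns and the witness
    pair's identity when present.
    """
    sites, samples = collect_sites(vcf_path, fasta_path, registry, samples)
    by_key: dict[tuple[str, str, str], list[AlleleSpecificSite]] = {}
    for s in sites:
        by_key.setdefault((s.sample, s.cas_name, s.contig), []).append(s)

    rows = []
    for gene in genes:
        glo, ghi = gene.start - flank, gene.end + flank
        for sample in samples:
            for cas in registry.enzymes:
                in_region = [
                    s
                    for s in by_key.get((sample, cas.name, gene.contig), [])
                    if glo <= s.pos < ghi
                ]
                pairs = find_pairs(in_region, max_distance)
                paired = gene_targetable_paired(gene, pairs, flank=flank, sample=sample)
                in_gene = [s for s in in_region if gene.start <= s.pos < gene.end]
                single = gene_targetable_single(gene, in_gene, sample=sample)
                rows.append(
                    {
                        "sample": sample,
                        "gene_id": gene.gene_id,
                        "cas_name": cas.name,
                        "paired_targetable": paired.targetable,
                        "single_targetable": single.targetable,
                        "witness_pair": (
                            paired.witness.pair_id if paired.witness else None
                        ),
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "sample", "gene_id", "cas_name",
            "paired_targetable", "single_targetable", "witness_pair",
        ],
    )
    if table.empty:
        empty = pd.Series(dtype=float)
        return table, empty, empty
    any_cas = (
        table.groupby(["sample", "gene_id"])["paired_targetable"].any().reset_index()
    )
    per_sample = any_cas.groupby("sample")["paired_targetable"].mean()
    per_gene = any_cas.groupby("gene_id")["paired_targetable"].mean()
    return table, per_sample, per_gene


def gene_pair_edges(
    gene: GeneModel,
    sites: list[AlleleSpecificSite],
    max_distance: int = DEFAULT_MAX_DISTANCE,
    flank: int = DEFAULT_FLANK,
    exon_overlap_only: bool = True,
) -> pd.DataFrame:
    """(pair_id, sample_id) usability edges for one gene's cover graph.

    A pair is usable in a sample iff both its variants are heterozygous with
    the targeted alleles in cis there (that is exactly what a per-sample
    :class:`AlleleSpecificSite` pair encodes); with ``exon_overlap_only``
    the excision span must additionally disrupt a coding exon.
    """
    lo, hi = gene.start - flank, gene.end + flank
    by_sc: dict[tuple[str, str], list[AlleleSpecificSite]] = {}
    for s in sites:
        if s.contig == gene.contig and lo <= s.pos < hi:
            by_sc.setdefault((s.sample, s.cas_name), []).append(s)
    rows = []
    for (sample, _cas), group in by_sc.items():
        for p in find_pairs(group, max_distance):
            if exon_overlap_only:
                s0, s1 = p.span
                if not any(_overlap(s0, s1, e0, e1) for e0, e1 in gene.exons):
                    continue
            rows.append({"pair_id": p.pair_id, "sample_id": sample})
    return pd.DataFrame(rows, columns=["pair_id", "sample_id"]).drop_duplicates()


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read gene models from a TSV with columns gene, contig, start, end,
    strand, exon_starts, exon_ends (comma-separated, BED-style)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes = []
    for r in df.itertuples(index=False):
        starts = [int(x) for x in str(r.exon_starts).split(",") if x]
        ends = [int(x) for x in str(r.exon_ends).split(",") if x]
        if len(starts) != len(ends):
            raise ValueError(f"{r.gene}: exon_starts/exon_ends length mismatch")
        genes.append(
            GeneModel(
                gene_id=r.gene,
                contig=r.contig,
                start=int(r.start),
                end=int(r.end),
                strand=r.strand,
                exons=tuple(zip(starts, ends)),
            )
        )
    return genes


def write_gene_table(genes: list[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene": g.gene_id,
            "contig": g.contig,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "exon_starts": ",".join(str(s) for s, _ in g.exons),
            "exon_ends": ",".join(str(e) for _, e in g.exons),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
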