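"""Guide enumeration, allele-specificity classification and personalized
(non-allele-specific) guide design.

Guide classes, in the sense used throughout this package:

* **reference guides** — designed on the reference sequence, oblivious to the
  individual's variants (may mismatch one or both haplotypes);
* **personalized guides** — designed on the individual's own sequence:
  homozygous variants incorporated, heterozygous variants avoided, so the
  guide matches both haplotypes exactly (:func:`design_personalized`);
* **allele-specific guides** — guides that incorporate a heterozygous
  variant in their protospacer, or whose PAM exists on only one allele, and
  therefore discriminate between the two haplotypes
  (:func:`enumerate_guides` + :func:`classify_allele_specific`).

Guides are emitted *discriminating by construction*: a candidate whose only
relationship to the variant is an unconstrained ('N') PAM position is not
allele-specific (both alleles keep a valid PAM and an identical protospacer)
and is never returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .annotate import (
    AlleleWindow,
    Variant,
    _overlaps,
    default_flank,
    protospacer_interval,
    reconstruct_allele_window,
)
from .cas import CasEnzyme, reverse_complement
from .pam_scan import scan_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GuideCandidate",
    "SampleGenotype",
    "NON_DESIGNABLE",
    "enumerate_guides",
    "classify_allele_specific",
    "design_personalized",
    "filter_by_specificity",
]

#: Sentinel for a non-designable allele (PAM lost on that allele) in
#: tabular output.
NON_DESIGNABLE = "---"


@dataclass(frozen=True)
class GuideCandidate:
    """An allele-resolved protospacer + PAM.

    ``ref_start``/``ref_end`` give the reference-projected footprint of the
    protospacer+PAM (for indel-spanning guides, inserted bases have no
    reference coordinate and the span covers the insertion point).
    ``allele`` is 'ref' or 'alt' for variant-anchored guides, 'both' for
    personalized guides that match both haplotypes.
    """

    cas_name: str
    allele: str
    strand: str
    protospacer: str
    pam_seq: str
    ref_start: int
    ref_end: int
    contig: str = ""
    vid: str | None = None
    variant_position_class: str | None = None  # 'in_pam' | 'in_protospacer'
    specificity_score: float | None = None


@dataclass(frozen=True)
class SampleGenotype:
    """One sample's genotype at one biallelic variant.

    ``hapA``/``hapB`` are allele indices (0 = ref, 1 = alt) for the first
    and second phased allele in the GT field; the ordering is meaningful
    only when ``phased``.
    """

    sample: str
    vid: str
    hapA: int | None
    hapB: int | None
    phased: bool = True

    def __post_init__(self) -> None:
        for h in (self.hapA, self.hapB):
            if h is not None and h not in (0, 1):
                raise ValueError(
                    f"{self.sample}@{self.vid}: allele index {h} not in {{0,1}}"
                )


def _extract_guide(
    win: AlleleWindow,
    site,
    cas: CasEnzyme,
    contig: str,
) -> GuideCandidate | None:
    """Pull protospacer and PAM sequences for one occurrence, reported in
    the guide's own 5'->3' orientation; None if the protospacer runs off
    the window (contig edge)."""
    p0, p1 = protospacer_interval(site, cas)
    if p0 < 0 or p1 > len(win.seq):
        return None
    proto = win.seq[p0:p1]
    pam = win.seq[site.start : site.end]
    if site.strand == "-":
        proto, pam = reverse_complement(proto), reverse_complement(pam)
    f0, f1 = min(p0, site.start), max(p1, site.end)
    r0, r1 = win.ref_span(f0, f1)
    return GuideCandidate(
        cas_name=cas.name,
        allele=win.allele,
        strand=site.strand,
        protospacer=proto,
        pam_seq=pam,
        ref_start=r0,
        ref_end=r1,
        contig=contig,
    )


def enumerate_guides(
    variant: Variant,
    ref_seq: str,
    cas: CasEnzyme,
    allele: str,
) -> list[GuideCandidate]:
    """All discriminating guides on one allele of a variant.

    Scans the chosen allele's local window; every PAM occurrence whose
    protospacer or constrained PAM positions overlap the variant's minimal
    edit yields one guide per strand, provided the guide discriminates
    between the alleles (protospacer differs, or the homologous PAM is
    absent on the other allele).
    """
    flank = default_flank(cas)
    win = reconstruct_allele_window(ref_seq, variant, allele, flank)
    other = reconstruct_allele_window(
        ref_seq, variant, "alt" if allele == "ref" else "ref", flank
    )
    other_sites = scan_sequence(other.seq, cas)
    other_keys = {other.occurrence_key(s) for s in other_sites}
    e0, e1 = win.edit_interval()
    out: list[GuideCandidate] = []
    for site in scan_sequence(win.seq, cas):
        p0, p1 = protospacer_interval(site, cas)
        in_proto = _overlaps(max(p0, 0), min(p1, len(win.seq)), e0, e1)
        in_pam = _overlaps(site.start, site.end, e0, e1)
        if not (in_proto or in_pam):
            continue
        if in_proto:
            discriminating = True
            if variant.is_snv and 0 <= p0 and p1 <= len(other.seq):
                # same-length windows: compare homologous protospacers
                discriminating = win.seq[p0:p1] != other.seq[p0:p1]
        else:
            # variant only in the PAM: allele-specific iff the homologous
            # occurrence is absent on the other allele (non-N position hit)
            discriminating = win.occurrence_key(site) not in other_keys
        if not discriminating:
            continue
        guide = _extract_guide(win, site, cas, variant.contig)
        if guide is None:
            logger.warning(
                "%s: guide at window offset %d skipped (contig edge)",
                variant.vid, site.start,
            )
            continue
        out.append(
            replace(
                guide,
                vid=variant.vid,
                variant_position_class=(
                    "in_protospacer" if in_proto else "in_pam"
                ),
            )
        )
    return out


def classify_allele_specific(guide: GuideCandidate, genotype: SampleGenotype) -> str:
    """Allele-specificity of a guide in one sample.

    A guide targeting allele *a* is allele-specific in a heterozygous
    sample and is assigned to the haplotype carrying *a*; homozygous-for-*a*
    samples are cut on both alleles; homozygous-for-the-other on neither.
    """
    if genotype.hapA is None or genotype.hapB is None:
        raise ValueError(
            f"missing genotype for {genotype.sample} at {genotype.vid}"
        )
    if guide.allele not in ("ref", "alt"):
        raise ValueError(f"guide allele {guide.allele!r} is not allele-resolved")
    target = 1 if guide.allele == "alt" else 0
    if genotype.hapA == genotype.hapB:
        return "both_alleles" if genotype.hapA == target else "neither"
    if not genotype.phased:
        raise ValueError(
            f"{genotype.sample}@{genotype.vid}: phased genotype required "
            "for haplotype-resolved classification"
        )
    return "allele_specific_hapA" if genotype.hapA == target else "allele_specific_hapB"


def _apply_substitutions(
    seq: str, variants: list[Variant], region: tuple[int, int]
) -> tuple[str, list[tuple[int, int]]]:
    """Substitute variants (sorted, non-overlapping) into seq[region].

    Returns the edited slice and a breakpoint table mapping reference
    coordinates to edited-slice offsets: list of (ref_coord, offset_shift)
    applying to positions >= ref_coord.
    """
    lo, hi = region
    pieces = []
    shifts: list[tuple[int, int]] = []
    cursor = lo
    shift = 0
    prev_end = -1
    for v in variants:
        if v.pos < prev_end:
            raise ValueError(
                f"overlapping homozygous variants cannot be jointly applied: "
                f"{v.vid} overlaps the previous variant"
            )
        prev_end = v.pos + len(v.ref)
        pieces.append(seq[cursor : v.pos])
        pieces.append(v.alt)
        cursor = v.pos + len(v.ref)
        shift += len(v.alt) - len(v.ref)
        shifts.append((cursor, shift))
    pieces.append(seq[cursor:hi])
    return "".join(pieces).upper(), shifts


def _ref_to_slice(pos: int, lo: int, shifts: list[tuple[int, int]]) -> int:
    off = 0
    for ref_coord, shift in shifts:
        if pos >= ref_coord:
            off = shift
    return pos - lo + off


def design_personalized(
    region: tuple[str, int, int],
    ref_seq: str,
    genotyped_variants: list[tuple[Variant, SampleGenotype]],
    cas: CasEnzyme,
) -> list[GuideCandidate]:
    """Personalized guides for one sample over a reference interval.

    The sample's personalized sequence is the reference with homozygous-alt
    alleles substituted. Guides are every protospacer+PAM on that sequence
    whose footprint overlaps no heterozygous variant; each returned guide
    therefore matches both haplotypes exactly.
    """
    contig, start, end = region
    hom_alt = sorted(
        (v for v, g in genotyped_variants if (g.hapA, g.hapB) == (1, 1)),
        key=lambda v: v.pos,
    )
    het = [
        v for v, g in genotyped_variants
        if g.hapA is not None and g.hapB is not None and g.hapA != g.hapB
    ]
    for v, g in genotyped_variants:
        if g.hapA is None or g.hapB is None:
            raise ValueError(f"ungenotyped variant {v.vid} in region")
    margin = default_flank(cas)
    lo = max(0, start - margin)
    hi = min(len(ref_seq), end + margin)
    applicable = [v for v in hom_alt if lo <= v.pos and v.pos + len(v.ref) <= hi]
    pseq, shifts = _apply_substitutions(ref_seq, applicable, (lo, hi))
    # heterozygous footprints in personalized-slice coordinates
    het_intervals = [
        (
            _ref_to_slice(v.pos, lo, shifts),
            _ref_to_slice(v.pos + len(v.ref), lo, shifts),
        )
        for v in het
    ]
    out = []
    for site in scan_sequence(pseq, cas):
        p0, p1 = protospacer_interval(site, cas)
        if p0 < 0 or p1 > len(pseq):
            continue
        f0, f1 = min(p0, site.start), max(p1, site.end)
        if any(_overlaps(f0, f1, h0, h1) for h0, h1 in het_intervals):
            continue
        # keep guides anchored inside the requested region
        r0 = _slice_to_ref(f0, lo, applicable)
        r1 = _slice_to_ref(f1 - 1, lo, applicable) + 1
        if r1 <= start or r0 >= end:
            continue
        proto = pseq[p0:p1]
        pam = pseq[site.start : site.end]
        if site.strand == "-":
            proto, pam = reverse_complement(proto), reverse_complement(pam)
        out.append(
            GuideCandidate(
                cas_name=cas.name,
                allele="both",
                strand=site.strand,
                protospacer=proto,
                pam_seq=pam,
                ref_start=r0,
                ref_end=r1,
                contig=contig,
            )
        )
    return out


def _slice_to_ref(offset: int, lo: int, applied: list[Variant]) -> int:
    """Inverse of _ref_to_slice for a single base offset; bases inside an
    applied alt allele project onto the variant's reference interval."""
    # walk applied variants left to right adjusting the cumulative shift
    off = offset
    cum = 0
    for v in applied:
        v_start_slice = v.pos - lo + cum
        v_end_slice = v_start_slice + len(v.alt)
        if off < v_start_slice:
            return lo + off - cum
        if off < v_end_slice:
            return min(v.pos + (off - v_start_slice), v.pos + len(v.ref) - 1)
        cum += len(v.alt) - len(v.ref)
    return lo + off - cum


def filter_by_specificity(
    guides: list[GuideCandidate],
    score_table: pd.DataFrame | dict,
    min_score: float,
    strict: bool = True,
) -> list[GuideCandidate]:
    """Keep guides with predicted specificity score >= ``min_score``.

    ``score_table`` maps (protospacer, pam_seq) -> score in [0, 100]; a
    DataFrame needs columns protospacer, pam_seq, score. Guides absent from
    the table are dropped in strict mode, retained with a warning otherwise.
    Scores are attached to the returned guides.
    """
    if isinstance(score_table, pd.DataFrame):
        table = {
            (r.protospacer, r.pam_seq): float(r.score)
            for r in score_table.itertuples(index=False)
        }
    else:
        table = {k: float(v) for k, v in score_table.items()}
    out = []
    for g in guides:
        score = table.get((g.protospacer, g.pam_seq))
        if score is None:
            if strict:
                continue
            logger.warning(
                "guide %s/%s has no specificity score; retained (non-strict)",
                g.protospacer, g.pam_seq,
            )
            out.append(g)
        elif score >= min_score:
            out.append(replace(g, specificity_score=score))
    return out


def guides_to_frame(guides: list[GuideCandidate]) -> pd.DataFrame:
    """Tabular guide report; non-designable alleles are written as '---'."""
    rows = []
    for g in guides:
        rows.append(
            {
                "vid": g.vid,
                "cas_name": g.cas_name,
                "allele": g.allele,
                "strand": g.strand,
                "protospacer": g.protospacer or NON_DESIGNABLE,
                "pam_seq": g.pam_seq or NON_DESIGNABLE,
                "contig": g.contig,
                "ref_start": g.ref_start,
                "ref_end": g.ref_end,
                "variant_position_class": g.variant_position_class,
                "specificity_score": g.specificity_score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "vid", "cas_name", "allele", "strand", "protospacer", "pam_seq",
            "contig", "ref_start", "ref_end", "variant_position_class",
            "specificity_score",
        ],
    )
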