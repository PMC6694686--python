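"""Variant/PAM annotation: does a variant create or destroy a PAM, and does
it sit inside a protospacer window?

For each (variant, Cas) pair three flags are computed by reconstructing the
local sequence of both alleles and comparing PAM occurrence sets:

* ``makes_pam`` — a PAM occurrence exists on the alternate-allele sequence
  but not at the homologous location on the reference-allele sequence;
* ``breaks_pam`` — the converse;
* ``var_near_pam`` — the variant lies inside the protospacer window
  (``protospacer_length`` bases on ``pam_side``) of a PAM present on either
  allele.

Homologous correspondence across alleles is anchored at both window ends:
occurrences strictly 5' of the edit compare by left-anchored offset, strictly
3' by right-anchored offset, and occurrences overlapping the edited bases
compare by motif-instance existence within the edited neighborhood. For SNVs
this reduces to position identity, which makes the N-position rule automatic:
a substitution at an unconstrained (N) motif position leaves the occurrence
present on both alleles and therefore sets neither flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam
from pyfaidx import Fasta

from .cas import CasEnzyme, CasRegistry
from .pam_scan import PamSite, scan_sequence

__all__ = [
    "Variant",
    "AlleleWindow",
    "VariantPamAnnotation",
    "reconstruct_allele_window",
    "annotate_variant",
    "annotate_cohort",
    "read_vcf_variants",
    "library_intersect",
]

_DNA = set("ACGT")


class DataIntegrityError(ValueError):
    """Variant record inconsistent with the reference sequence."""


@dataclass(frozen=True)
class Variant:
    """A biallelic variant; ``pos`` is 0-based (VCF POS − 1).

    ``ref`` must match the reference sequence at ``[pos, pos + len(ref))``;
    this is checked when windows are reconstructed.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    vid: str

    def __post_init__(self) -> None:
        ref, alt = self.ref.upper(), self.alt.upper()
        if not ref or not alt:
            raise ValueError(f"{self.vid}: ref and alt must be non-empty")
        if ref == alt:
            raise ValueError(f"{self.vid}: ref and alt are identical")
        if set(ref) - _DNA or set(alt) - _DNA:
            raise ValueError(f"{self.vid}: non-ACGT allele")
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def minimal_edit(self) -> tuple[int, str, str]:
        """(offset within ref allele, trimmed ref, trimmed alt) after
        stripping the common prefix and suffix of the two alleles."""
        r, a = self.ref, self.alt
        pre = 0
        while pre < min(len(r), len(a)) and r[pre] == a[pre]:
            pre += 1
        suf = 0
        while (
            suf < min(len(r), len(a)) - pre and r[-1 - suf] == a[-1 - suf]
        ):
            suf += 1
        return pre, r[pre : len(r) - suf], a[pre : len(a) - suf]


@dataclass
class AlleleWindow:
    """A variant-substituted local sequence plus its coordinate bookkeeping.

    ``seq = left flank + allele + right flank``; ``start`` is the reference
    coordinate of the window's first base, ``left_len``/``allele_len`` give
    the window offsets of the substituted allele.
    """

    seq: str
    start: int  # reference coordinate of window offset 0
    left_len: int
    allele_len: int
    variant: Variant
    allele: str  # 'ref' or 'alt'

    @property
    def allele_interval(self) -> tuple[int, int]:
        """Window offsets [start, end) of the substituted allele."""
        return self.left_len, self.left_len + self.allele_len

    def edit_interval(self) -> tuple[int, int]:
        """Window offsets of the minimal edit (may be empty: a junction).

        Bases shared between ref and alt (anchor bases of VCF indels) are
        excluded; for a deletion viewed on the alt allele this is a
        zero-length junction at the deletion point.
        """
        pre, tr, ta = self.variant.minimal_edit()
        lo = self.left_len + pre
        changed = len(tr) if self.allele == "ref" else len(ta)
        return lo, lo + changed

    def to_ref(self, offset: int) -> int:
        """Reference coordinate for a window offset (edited bases clamp to
        the reference allele interval)."""
        a0, a1 = self.allele_interval
        if offset < a0:
            return self.start + offset
        if offset >= a1:
            # right-anchored: flank bases keep their reference coordinates
            return self.variant.pos + len(self.variant.ref) + (offset - a1)
        # edited bases project onto the reference allele interval; inserted
        # bases beyond it collapse onto its last base
        return min(
            self.variant.pos + (offset - a0),
            self.variant.pos + len(self.variant.ref) - 1,
        )

    def ref_span(self, lo: int, hi: int) -> tuple[int, int]:
        """Reference-projected footprint of window interval [lo, hi)."""
        if hi <= lo:
            raise ValueError("empty window interval")
        start = self.to_ref(lo)
        end = self.to_ref(hi - 1) + 1
        return start, max(end, start + 1)

    def occurrence_key(self, site: PamSite) -> tuple:
        """Allele-comparable identity of a PAM occurrence in this window.

        'L' keys are left-anchored offsets, 'R' keys right-anchored offsets
        (distance from the window end), 'M' marks occurrences overlapping
        the substituted allele, compared by existence per strand.

        For length-preserving variants (SNVs, MNVs) both windows share one
        coordinate system and every occurrence compares positionally.
        """
        if len(self.variant.ref) == len(self.variant.alt):
            return ("L", site.start, site.strand)
        a0, a1 = self.allele_interval
        if site.end <= a0:
            return ("L", site.start, site.strand)
        if site.start >= a1:
            return ("R", len(self.seq) - site.start, site.strand)
        return ("M", site.strand)


def reconstruct_allele_window(
    ref_seq: str, variant: Variant, allele: str, flank: int
) -> AlleleWindow:
    """Extract ``ref_seq[pos−flank : pos+len(ref)+flank]`` with the chosen
    allele substituted, clipped at contig edges.

    Raises :class:`DataIntegrityError` if the variant's ref allele does not
    match the reference sequence.
    """
    if allele not in ("ref", "alt"):
        raise ValueError(f"allele must be 'ref' or 'alt', got {allele!r}")
    pos, ref = variant.pos, variant.ref
    if ref_seq[pos : pos + len(ref)].upper() != ref:
        raise DataIntegrityError(
            f"{variant.vid}: ref allele {ref!r} does not match reference at "
            f"{variant.contig}:{pos} "
            f"({ref_seq[pos : pos + len(ref)].upper()!r})"
        )
    wstart = max(0, pos - flank)
    wend = min(len(ref_seq), pos + len(ref) + flank)
    left = ref_seq[wstart:pos].upper()
    right = ref_seq[pos + len(ref) : wend].upper()
    mid = ref if allele == "ref" else variant.alt
    return AlleleWindow(
        seq=left + mid + right,
        start=wstart,
        left_len=len(left),
        allele_len=len(mid),
        variant=variant,
        allele=allele,
    )


@dataclass(frozen=True)
class VariantPamAnnotation:
    vid: str
    cas_name: str
    makes_pam: bool
    breaks_pam: bool
    var_near_pam: bool


def protospacer_interval(site: PamSite, cas: CasEnzyme) -> tuple[int, int]:
    """Window/reference interval of the protospacer adjacent to a PAM
    occurrence, honoring strand and PAM side.

    For a 3'-PAM enzyme the protospacer is 5' of the PAM in the motif's
    reading orientation; for a 5'-PAM enzyme it is 3' of the PAM.
    """
    P = cas.protospacer_length
    upstream = (site.strand == "+") == (cas.pam_side == "three_prime")
    if upstream:
        return site.start - P, site.start
    return site.end, site.end + P


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    """Half-open interval overlap; an empty interval is a junction point
    that overlaps only intervals containing it strictly inside."""
    if a0 == a1:
        return b0 < a0 < b1
    if b0 == b1:
        return a0 < b0 < a1
    return a0 < b1 and b0 < a1


def default_flank(cas: CasEnzyme) -> int:
    return cas.protospacer_length + cas.pam_length


def annotate_variant(
    variant: Variant, ref_seq: str, cas: CasEnzyme, flank: int | None = None
) -> VariantPamAnnotation:
    """Compute makes/breaks/near flags for one variant under one Cas.

    Both allele windows are scanned; occurrence sets are compared under the
    double-anchored coordinate map. ``var_near_pam`` is true iff the
    variant's minimal edit intersects the protospacer window of any PAM
    occurrence on either allele.
    """
    if flank is None:
        flank = default_flank(cas)
    windows = {
        a: reconstruct_allele_window(ref_seq, variant, a, flank)
        for a in ("ref", "alt")
    }
    keys: dict[str, set] = {}
    near = False
    for a, win in windows.items():
        sites = scan_sequence(win.seq, cas, contig=variant.contig)
        keys[a] = {win.occurrence_key(s) for s in sites}
        e0, e1 = win.edit_interval()
        for s in sites:
            p0, p1 = protospacer_interval(s, cas)
            if _overlaps(max(p0, 0), min(p1, len(win.seq)), e0, e1):
                near = True
    return VariantPamAnnotation(
        vid=variant.vid,
        cas_name=cas.name,
        makes_pam=bool(keys["alt"] - keys["ref"]),
        breaks_pam=bool(keys["ref"] - keys["alt"]),
        var_near_pam=near,
    )


def _check_sorted(prev: dict, contig: str, pos: int, path) -> None:
    if prev.get("contig") == contig and pos < prev.get("pos", -1):
        raise ValueError(f"{path}: VCF not coordinate-sorted at {contig}:{pos + 1}")
    prev["contig"], prev["pos"] = contig, pos


def iter_vcf_variants(vcf_path: str | Path):
    """Yield (Variant, record) pairs from a VCF, splitting multiallelic
    records into one Variant per alt allele. Checks coordinate sorting."""
    prev: dict = {}
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            _check_sorted(prev, rec.chrom, rec.start, vcf_path)
            for alt in rec.alts or ():
                if alt is None or set(alt.upper()) - _DNA:
                    continue  # symbolic/spanning alleles are not designable
                vid = f"{rec.chrom}_{rec.pos}_{rec.ref}_{alt}"
                yield Variant(rec.chrom, rec.start, rec.ref, alt, vid), rec


def annotate_cohort(
    vcf_path: str | Path,
    fasta_path: str | Path,
    registry: CasRegistry,
) -> pd.DataFrame:
    """Annotate every VCF variant against every registry enzyme.

    Returns one row per variant × Cas with columns vid, contig, pos, ref,
    alt, cas_name, makes_pam, breaks_pam, var_near_pam. Fails if any VCF
    contig is missing from the FASTA.
    """
    fasta = Fasta(str(fasta_path), sequence_always_upper=True)
    contigs: dict[str, str] = {}
    missing: set[str] = set()
    rows = []
    for variant, _rec in iter_vcf_variants(vcf_path):
        if variant.contig not in contigs:
            if variant.contig not in fasta:
                missing.add(variant.contig)
                continue
            contigs[variant.contig] = str(fasta[variant.contig])
        seq = contigs[variant.contig]
        for cas in registry.enzymes:
            ann = annotate_variant(variant, seq, cas)
            rows.append(
                {
                    "vid": variant.vid,
                    "contig": variant.contig,
                    "pos": variant.pos,
                    "ref": variant.ref,
                    "alt": variant.alt,
                    "cas_name": cas.name,
                    "makes_pam": ann.makes_pam,
                    "breaks_pam": ann.breaks_pam,
                    "var_near_pam": ann.var_near_pam,
                }
            )
    if missing:
        raise ValueError(
            f"VCF contigs absent from FASTA: {sorted(missing)}"
        )
    cols = [
        "vid", "contig", "pos", "ref", "alt",
        "cas_name", "makes_pam", "breaks_pam", "var_near_pam",
    ]
    return pd.DataFrame(rows, columns=cols)


def read_vcf_variants(
    vcf_path: str | Path, af_from: str = "info"
) -> pd.DataFrame:
    """Variant table with allele frequencies for library intersection.

    ``af_from`` is 'info' (INFO/AF per alt) or 'genotypes' (computed from
    cohort GT fields). Columns: contig, pos (0-based), ref, alt, vid, af
    (NaN when unavailable).
    """
    rows = []
    prev: dict = {}
    with pysam.VariantFile(str(vcf_path)) as vcf:
        n_samples = len(vcf.header.samples)
        for rec in vcf:
            _check_sorted(prev, rec.chrom, rec.start, vcf_path)
            alts = rec.alts or ()
            if af_from == "info":
                af_vals = rec.info.get("AF")
                if af_vals is not None and not isinstance(af_vals, tuple):
                    af_vals = (af_vals,)
            elif af_from == "genotypes":
                counts = [0] * (len(alts) + 1)
                total = 0
                for sample in rec.samples.values():
                    for a in sample.get("GT") or ():
                        if a is not None:
                            counts[a] += 1
                            total += 1
                af_vals = tuple(
                    counts[i + 1] / total if total else float("nan")
                    for i in range(len(alts))
                ) if n_samples else None
            else:
                raise ValueError(f"af_from must be 'info' or 'genotypes', got {af_from!r}")
            for i, alt in enumerate(alts):
                if alt is None or set(alt.upper()) - _DNA:
                    continue
                af = float("nan")
                if af_vals is not None and i < len(af_vals) and af_vals[i] is not None:
                    af = float(af_vals[i])
                rows.append(
                    {
                        "contig": rec.chrom,
                        "pos": rec.start,
                        "ref": rec.ref,
                        "alt": alt,
                        "vid": f"{rec.chrom}_{rec.pos}_{rec.ref}_{alt}",
                        "af": af,
                    }
                )
    return pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "vid", "af"]
    )


def _pam_layout(
    start: int, end: int, strand: str, cas: CasEnzyme
) -> tuple[tuple[int, int], list[int]]:
    """(PAM genomic interval, genomic positions of non-N PAM bases) for a
    guide whose protospacer+PAM footprint occupies [start, end)."""
    L = cas.pam_length
    pam_left = (strand == "+") == (cas.pam_side == "three_prime")
    pam = (end - L, end) if pam_left else (start, start + L)
    non_n = []
    for j, code in enumerate(cas.pam_motif):
        if code == "N":
            continue
        # motif reads left-to-right on '+', right-to-left on '-'
        g = pam[0] + j if strand == "+" else pam[1] - 1 - j
        non_n.append(g)
    return pam, non_n


def library_intersect(
    guides: pd.DataFrame,
    variants: pd.DataFrame,
    registry: CasRegistry,
    maf_min: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Flag library guides overlapped by common variants.

    ``guides``: columns contig, start, end, strand, cas_name — the
    protospacer+PAM footprint of each library guide in reference
    coordinates. A guide is flagged if at least one variant with
    MAF > ``maf_min`` overlaps its protospacer or a constrained (non-N) PAM
    position; variants overlapping only unconstrained PAM 'N' positions are
    ignored. Returns (per-guide report, flagged fraction).
    """
    if maf_min > 0:
        if "af" not in variants.columns or variants["af"].isna().any():
            raise ValueError(
                "allele frequencies required when maf_min > 0 "
                "(missing 'af' values)"
            )
        variants = variants[variants["af"] > maf_min]
    flags = []
    for g in guides.itertuples(index=False):
        cas = registry[g.cas_name]
        pam, non_n = _pam_layout(g.start, g.end, g.strand, cas)
        hit = False
        on_contig = variants[variants["contig"] == g.contig]
        for v in on_contig.itertuples(index=False):
            v0, v1 = v.pos, v.pos + len(v.ref)
            if not _overlaps(v0, v1, g.start, g.end):
                continue
            in_proto = (
                _overlaps(v0, v1, g.start, pam[0])
                or _overlaps(v0, v1, pam[1], g.end)
            )
            in_nonn_pam = any(v0 <= p < v1 for p in non_n)
            if in_proto or in_nonn_pam:
                hit = True
                break
        flags.append(hit)
    report = guides.copy()
    report["flagged"] = flags
    frac = float(report["flagged"].mean()) if len(report) else 0.0
    return report, frac
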