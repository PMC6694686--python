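"""Deterministic synthetic inputs: toy genome, phased cohort, gene models.

The generator emulates the *structure* of a phased population-scale cohort
— biallelic SNVs and short indels, a controllable allele-frequency
spectrum, and haplotype-block sharing — without any population-genetic
realism (no recombination maps, no coalescent). Sharing is induced by a
founder-haplotype device: each contig is cut into blocks of
``block_length`` bp; within a block, ``n_founders`` founder haplotypes are
drawn and every sample haplotype copies one founder per block. Allele
frequencies are controlled by assigning each variant's alternate allele to
``round(maf * n_founders)`` founders, so the realized cohort frequency
concentrates near the target. Samples belong to labeled groups that
preferentially copy their own subset of founders, giving the
population-structured sharing that makes cohort-level guide-pair
optimization non-trivial.

Optionally, a known allele-specific guide-pair signal can be *planted*: two
heterozygous-in-cis SNVs, each inside an SpCas9 protospacer, carried by an
exact, known subset of samples — ground truth for targetability recovery.

All randomness flows from a single integer seed through labeled child
streams (genome/cohort/genes), so adding one generator never perturbs the
others and identical specs give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FixtureSpec", "PlantedPair", "Cohort", "generate_genome",
           "generate_cohort", "generate_genes", "write_fasta"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedPair:
    """A known-truth pair of het-cis SNVs carried by an exact sample subset."""

    contig: str
    region: tuple[int, int]
    samples: tuple[str, ...]
    max_separation: int = 8_000
    min_separation: int = 500


@dataclass
class FixtureSpec:
    """Parameters of one synthetic world.

    Defaults describe a desk-scale cohort: one 100-kb contig, 50 diploid
    samples in two groups, 300 variants (10% short indels) with MAF drawn
    uniformly from [0.05, 0.5], 10-kb haplotype blocks with 20 founders.
    """

    seed: int = 0
    contig_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 100_000})
    n_samples: int = 50
    n_variants: int = 300
    indel_fraction: float = 0.1
    maf_min: float = 0.05
    maf_max: float = 0.5
    block_length: int = 10_000
    n_founders: int = 20
    n_groups: int = 2
    n_genes: int = 5
    phased: bool = True
    planted: tuple[PlantedPair, ...] = ()

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.contig_lengths.values()):
            raise ValueError("contig lengths must be positive")
        for name, val in [("n_samples", self.n_samples),
                          ("block_length", self.block_length),
                          ("n_founders", self.n_founders),
                          ("n_groups", self.n_groups)]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.indel_fraction <= 1.0):
            raise ValueError("indel_fraction must be in [0, 1]")
        if not (0.0 < self.maf_min <= self.maf_max <= 0.5):
            raise ValueError("need 0 < maf_min <= maf_max <= 0.5")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    @property
    def sample_names(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.n_samples)]

    @property
    def groups(self) -> dict[str, str]:
        return {
            s: f"pop{i % self.n_groups}" for i, s in enumerate(self.sample_names)
        }


def generate_genome(spec: FixtureSpec) -> dict[str, str]:
    """Uniform-random ACGT sequence per contig; seed-deterministic."""
    rng = spec.rng(0)
    return {
        contig: np.frombuffer(
            rng.choice(_BASES, size=length).tobytes(), dtype="S1"
        ).tobytes().decode()
        for contig, length in spec.contig_lengths.items()
    }


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class _Var:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    target_maf: float
    planted: bool = False


@dataclass
class Cohort:
    """In-memory synthetic cohort: variants plus per-sample haplotypes."""

    spec: FixtureSpec
    variants: list[_Var]
    # genotypes[i] is an (n_samples, 2) array of allele indices for variant i
    genotypes: list[np.ndarray]

    @property
    def truth(self) -> pd.DataFrame:
        """Per-variant truth: target and realized allele frequency, plus
        each sample's phased haplotypes as 'a|b' strings."""
        rows = []
        names = self.spec.sample_names
        for v, gt in zip(self.variants, self.genotypes):
            row = {
                "vid": f"{v.contig}_{v.pos + 1}_{v.ref}_{v.alt}",
                "contig": v.contig,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "target_maf": v.target_maf,
                "realized_af": float(gt.mean()),
                "planted": v.planted,
            }
            for j, s in enumerate(names):
                row[s] = f"{gt[j, 0]}|{gt[j, 1]}"
            rows.append(row)
        return pd.DataFrame(rows)

    def write_vcf(self, path: str | Path) -> None:
        sep = "|" if self.spec.phased else "/"
        names = self.spec.sample_names
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for contig, length in self.spec.contig_lengths.items():
                fh.write(f"##contig=<ID={contig},length={length}>\n")
            fh.write(
                '##INFO=<ID=AF,Number=A,Type=Float,'
                'Description="Alternate allele frequency">\n'
            )
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(names)
                + "\n"
            )
            order = sorted(
                range(len(self.variants)),
                key=lambda i: (self.variants[i].contig, self.variants[i].pos),
            )
            for i in order:
                v, gt = self.variants[i], self.genotypes[i]
                af = gt.mean()
                gts = "\t".join(
                    f"{gt[j, 0]}{sep}{gt[j, 1]}" for j in range(len(names))
                )
                fh.write(
                    f"{v.contig}\t{v.pos + 1}\t"
                    f"{v.contig}_{v.pos + 1}_{v.ref}_{v.alt}\t{v.ref}\t{v.alt}"
                    f"\t.\tPASS\tAF={af:.6f}\tGT\t{gts}\n"
                )


def _draw_variant(rng, seq: str, pos: int, indel: bool) -> tuple[str, str]:
    ref_base = seq[pos]
    if not indel:
        alt = rng.choice([b for b in "ACGT" if b != ref_base])
        return ref_base, str(alt)
    length = int(rng.integers(1, 6))
    if rng.random() < 0.5:  # insertion after the anchor base
        ins = "".join(rng.choice(list("ACGT"), size=length))
        return ref_base, ref_base + ins
    return seq[pos : pos + 1 + length], ref_base  # deletion


def _find_protospacer_snv(
    seq: str, lo: int, hi: int, rng: np.random.Generator
) -> int | None:
    """A position inside [lo, hi) lying in the protospacer of an SpCas9 NGG
    PAM ('GG' downstream on + or 'CC' upstream on -)."""
    candidates = []
    for i in range(lo, hi):
        down = seq[i + 2 : i + 22]
        up = seq[max(0, i - 21) : i - 1]
        if "GG" in down or "CC" in up:
            candidates.append(i)
    if not candidates:
        return None
    return int(rng.choice(candidates))


def generate_cohort(spec: FixtureSpec, genome: dict[str, str]) -> Cohort:
    """Phased synthetic cohort with founder-block haplotype sharing.

    Positions are rejection-sampled to avoid collisions (error after a
    bounded number of attempts); planted pairs are injected with exact
    genotypes (het in cis on hapB for the named samples, hom-ref elsewhere).
    """
    rng = spec.rng(1)
    n, F = spec.n_samples, spec.n_founders
    contigs = list(spec.contig_lengths)
    group_of = spec.groups
    names = spec.sample_names

    # founder choice per sample-haplotype per block, biased 3:1 toward the
    # sample's own group's founder subset (population structure)
    founder_group = np.arange(F) % spec.n_groups

    def founder_pick(sample_idx: int, block_rng) -> int:
        g = sample_idx % spec.n_groups
        w = np.where(founder_group == g, 3.0, 1.0)
        return int(block_rng.choice(F, p=w / w.sum()))

    taken: dict[str, set[int]] = {c: set() for c in contigs}
    variants: list[_Var] = []
    genotypes: list[np.ndarray] = []

    # block -> per-sample founder assignment, lazily drawn and cached so
    # variants in one block share phase structure
    block_assign: dict[tuple[str, int], np.ndarray] = {}

    def assignment(contig: str, block: int) -> np.ndarray:
        key = (contig, block)
        if key not in block_assign:
            brng = np.random.default_rng(
                [spec.seed, 1000 + contigs.index(contig), block]
            )
            arr = np.empty((n, 2), dtype=np.int64)
            for j in range(n):
                arr[j, 0] = founder_pick(j, brng)
                arr[j, 1] = founder_pick(j, brng)
            block_assign[key] = arr
        return block_assign[key]

    # planted pairs first: they reserve their positions
    prng = spec.rng(3)
    for plant in spec.planted:
        seq = genome[plant.contig]
        lo, hi = plant.region
        pos1 = _find_protospacer_snv(seq, lo, hi - plant.min_separation, prng)
        if pos1 is None:
            raise ValueError(f"no plantable protospacer position in {plant.region}")
        lo2 = pos1 + plant.min_separation
        hi2 = min(hi, pos1 + plant.max_separation)
        pos2 = _find_protospacer_snv(seq, lo2, hi2, prng)
        if pos2 is None:
            raise ValueError(
                f"no second plantable position within {plant.max_separation} bp"
            )
        carrier = np.isin(names, plant.samples)
        for pos in (pos1, pos2):
            ref, alt = _draw_variant(prng, seq, pos, indel=False)
            gt = np.zeros((n, 2), dtype=np.int8)
            gt[carrier, 1] = 1  # alt on hapB -> het in cis
            variants.append(
                _Var(plant.contig, pos, ref, alt, float(carrier.mean()), planted=True)
            )
            genotypes.append(gt)
            taken[plant.contig].add(pos)

    margin = 60  # keep full guide windows inside the contig
    for _ in range(spec.n_variants):
        contig = contigs[int(rng.integers(len(contigs)))]
        seq = genome[contig]
        for _attempt in range(1000):
            pos = int(rng.integers(margin, len(seq) - margin))
            if all(abs(pos - t) > 10 for t in taken[contig]):
                break
        else:
            raise RuntimeError("could not place variant without collision")
        taken[contig].add(pos)
        indel = bool(rng.random() < spec.indel_fraction)
        ref, alt = _draw_variant(rng, seq, pos, indel)
        maf = float(rng.uniform(spec.maf_min, spec.maf_max))
        # assign the alt allele to round(maf * F) founders
        k_carriers = max(1, round(maf * F))
        carriers = rng.choice(F, size=k_carriers, replace=False)
        founder_allele = np.zeros(F, dtype=np.int8)
        founder_allele[carriers] = 1
        assign = assignment(contig, pos // spec.block_length)
        genotypes.append(founder_allele[assign])
        variants.append(_Var(contig, pos, ref, alt, maf))

    return Cohort(spec=spec, variants=variants, genotypes=genotypes)


def generate_genes(spec: FixtureSpec, genome: dict[str, str]):
    """Non-overlapping gene models with 2-10 coding exons each.

    Genes are placed left to right with random gaps; raises if the contigs
    cannot hold the requested count.
    """
    from .targetability import GeneModel

    rng = spec.rng(2)
    genes = []
    contigs = list(genome)
    per_contig = spec.n_genes // len(contigs) + (spec.n_genes % len(contigs) > 0)
    gid = 0
    for contig in contigs:
        length = len(genome[contig])
        cursor = int(rng.integers(200, 2000))
        for _ in range(per_contig):
            if gid >= spec.n_genes:
                break
            span = int(rng.integers(3_000, 15_000))
            if cursor + span > length - 200:
                break
            n_exons = int(rng.integers(2, 11))
            bounds = np.sort(
                rng.choice(np.arange(span - 400), size=2 * n_exons, replace=False)
            )
            exons = []
            for i in range(n_exons):
                s = cursor + int(bounds[2 * i])
                e = cursor + int(bounds[2 * i + 1]) + 50
                if exons and s <= exons[-1][1]:
                    s = exons[-1][1] + 10
                    e = max(e, s + 50)
                exons.append((s, min(e, cursor + span)))
            genes.append(
                GeneModel(
                    gene_id=f"GENE{gid:03d}",
                    contig=contig,
                    start=cursor,
                    end=cursor + span,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=tuple(exons),
                )
            )
            gid += 1
            cursor += span + int(rng.integers(1_000, 5_000))
    if gid < spec.n_genes:
        raise ValueError(
            f"insufficient genome space for {spec.n_genes} genes (placed {gid})"
        )
    return genes


def write_groups(spec: FixtureSpec, path: str | Path) -> None:
    pd.DataFrame(
        [{"sample": s, "group": g} for s, g in spec.groups.items()]
    ).to_csv(path, sep="\t", index=False)
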