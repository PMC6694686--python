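import numpy as np
import pandas as pd
import pytest

from _oracles import oracle_scan
from allelescan.annotate import (
    DataIntegrityError,
    Variant,
    annotate_cohort,
    annotate_variant,
    library_intersect,
    read_vcf_variants,
    reconstruct_allele_window,
)
from allelescan.cas import CasEnzyme, CasRegistry

from conftest import random_dna


def snv_oracle_flags(seq, pos, alt, cas):
    """Independent dual-window re-scan: substitute the base, enumerate PAM
    occurrences on both full-length allele sequences, diff them, and check
    the variant against every occurrence's protospacer window."""
    ref_occ = set(oracle_scan(seq, cas.pam_motif))
    alt_seq = seq[:pos] + alt + seq[pos + 1 :]
    alt_occ = set(oracle_scan(alt_seq, cas.pam_motif))
    near = False
    L, P = len(cas.pam_motif), cas.protospacer_length
    for i, strand in ref_occ | alt_occ:
        upstream = (strand == "+") == (cas.pam_side == "three_prime")
        lo, hi = (i - P, i) if upstream else (i + L, i + L + P)
        if lo <= pos < hi:
            near = True
    return bool(alt_occ - ref_occ), bool(ref_occ - alt_occ), near


class TestReconstructAlleleWindow:
    def test_snv_substitution(self):
        seq = "AAAAAAACCTACTGAAAAAAA"  # ref base 'A' at pos 10
        v = Variant("c", 10, "A", "G", "v")
        assert reconstruct_allele_window(seq, v, "ref", 3).seq == "CCTACTG"
        assert reconstruct_allele_window(seq, v, "alt", 3).seq == "CCTGCTG"

    def test_deletion_splices_out_bases(self):
        seq = "AAAAAAAATTACGTTAAAAAA"  # 'ACG' at pos 10
        v = Variant("c", 10, "ACG", "A", "v")
        assert reconstruct_allele_window(seq, v, "alt", 2).seq == "TTATT"

    def test_insertion_splices_in_bases(self):
        seq = "AAAAAAAAGGAGGAAAAAAAA"  # 'A' at pos 10
        v = Variant("c", 10, "A", "ATT", "v")
        assert reconstruct_allele_window(seq, v, "alt", 2).seq == "GGATTGG"

    def test_window_clipped_at_contig_edges(self):
        v = Variant("c", 1, "C", "T", "v")
        win = reconstruct_allele_window("ACGT", v, "alt", 10)
        assert win.seq == "ATGT" and win.start == 0

    def test_ref_mismatch_raises_naming_the_variant(self):
        v = Variant("c", 5, "G", "T", "bad_vid")
        with pytest.raises(DataIntegrityError, match="bad_vid"):
            reconstruct_allele_window("A" * 20, v, "ref", 4)


class TestAnnotateVariant:
    def test_snv_creating_pam(self, spcas9):
        seq = "T" * 30 + "AAG" + "T" * 30  # A->G makes AGG
        ann = annotate_variant(Variant("c", 31, "A", "G", "v"), seq, spcas9)
        assert ann.makes_pam and not ann.breaks_pam

    def test_snv_destroying_pam(self, spcas9):
        seq = "T" * 30 + "AGG" + "T" * 30
        ann = annotate_variant(Variant("c", 32, "G", "T", "v"), seq, spcas9)
        assert ann.breaks_pam and not ann.makes_pam

    def test_n_position_snv_sets_no_flags(self, spcas9):
        # TGG -> CGG: both alleles keep the PAM; AT background has no other
        seq = "AT" * 15 + "TGG" + "AT" * 15
        ann = annotate_variant(Variant("c", 30, "T", "C", "v"), seq, spcas9)
        assert not ann.makes_pam and not ann.breaks_pam

    def test_distant_snv_has_all_flags_false(self, spcas9):
        seq = "AT" * 40 + "AGG" + "AT" * 40
        ann = annotate_variant(Variant("c", 10, "A", "C", "v"), seq, spcas9)
        assert ann == ann.__class__("v", "SpCas9", False, False, False)

    def test_protospacer_snv_is_near_pam(self, spcas9):
        seq = "AT" * 20 + "AGG" + "AT" * 20
        ann = annotate_variant(Variant("c", 30, "A", "C", "v"), seq, spcas9)
        assert ann.var_near_pam

    def test_flags_match_dual_window_oracle(self, registry):
        rng = np.random.default_rng(123)
        for _ in range(60):
            seq = random_dna(rng, int(rng.integers(60, 200)))
            pos = int(rng.integers(5, len(seq) - 5))
            alt = rng.choice([b for b in "ACGT" if b != seq[pos]])
            v = Variant("c", pos, seq[pos], str(alt), "v")
            cas = registry.enzymes[int(rng.integers(len(registry)))]
            ann = annotate_variant(v, seq, cas)
            assert (ann.makes_pam, ann.breaks_pam, ann.var_near_pam) == \
                snv_oracle_flags(seq, pos, str(alt), cas), (seq, pos, cas.name)

    def test_allele_symmetry_for_snvs(self, registry):
        """Swapping ref/alt (on the alt background) exchanges makes/breaks."""
        rng = np.random.default_rng(9)
        for _ in range(40):
            seq = random_dna(rng, 120)
            pos = int(rng.integers(10, 110))
            alt = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
            cas = registry.enzymes[int(rng.integers(len(registry)))]
            fwd = annotate_variant(Variant("c", pos, seq[pos], alt, "v"), seq, cas)
            alt_seq = seq[:pos] + alt + seq[pos + 1 :]
            rev = annotate_variant(
                Variant("c", pos, alt, seq[pos], "v"), alt_seq, cas
            )
            assert (fwd.makes_pam, fwd.breaks_pam) == (rev.breaks_pam, rev.makes_pam)
            assert fwd.var_near_pam == rev.var_near_pam

    def test_near_pam_monotone_in_protospacer_length(self, spcas9):
        rng = np.random.default_rng(5)
        for _ in range(25):
            seq = random_dna(rng, 150)
            pos = int(rng.integers(10, 140))
            alt = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
            v = Variant("c", pos, seq[pos], alt, "v")
            near = [
                annotate_variant(
                    v, seq, CasEnzyme("a", "NGG", protospacer_length=P)
                ).var_near_pam
                for P in (10, 20, 30)
            ]
            assert near == sorted(near), "longer window can only add PAMs"

    def test_indel_annotation_detects_pam_disruption(self, spcas9):
        # deleting the G of AGG destroys the PAM occurrence
        seq = "TA" * 20 + "AGGT" + "TA" * 20
        v = Variant("c", 40, "AG", "A", "v")  # removes one G
        ann = annotate_variant(v, seq, spcas9)
        assert ann.breaks_pam


def write_vcf(path, rows, samples=(), extra_info="."):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=chr1,length=1000>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="af">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n')
        header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if samples:
            header += "\tFORMAT\t" + "\t".join(samples)
        fh.write(header + "\n")
        for row in rows:
            fh.write(row + "\n")


class TestAnnotateCohort:
    @pytest.fixture()
    def toy_ref(self, tmp_path):
        rng = np.random.default_rng(77)
        seq = random_dna(rng, 1000)
        fasta = tmp_path / "ref.fa"
        fasta.write_text(f">chr1\n{seq}\n")
        return seq, fasta

    def test_rows_match_per_variant_annotation(self, tmp_path, toy_ref, registry):
        seq, fasta = toy_ref
        two = CasRegistry(registry.enzymes[:2])
        positions = [100, 220, 380, 500, 640]
        rows = [
            f"chr1\t{p + 1}\t.\t{seq[p]}\t{'A' if seq[p] != 'A' else 'C'}\t.\tPASS\t."
            for p in positions
        ]
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, rows)
        table = annotate_cohort(vcf, fasta, two)
        assert len(table) == 10  # 5 variants x 2 Cas
        for r in table.itertuples(index=False):
            cas = two[r.cas_name]
            ann = annotate_variant(Variant(r.contig, r.pos, r.ref, r.alt, r.vid), seq, cas)
            assert (r.makes_pam, r.breaks_pam, r.var_near_pam) == (
                ann.makes_pam, ann.breaks_pam, ann.var_near_pam,
            )

    def test_multiallelic_records_split_per_alt(self, tmp_path, toy_ref, registry):
        seq, fasta = toy_ref
        one = CasRegistry(registry.enzymes[:1])
        p = 300
        alts = sorted(set("ACGT") - {seq[p]})[:2]
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, [f"chr1\t{p + 1}\t.\t{seq[p]}\t{','.join(alts)}\t.\tPASS\t."])
        table = annotate_cohort(vcf, fasta, one)
        assert len(table) == 2 and table.vid.nunique() == 2

    def test_empty_vcf_gives_empty_table_with_header(self, tmp_path, toy_ref, registry):
        _, fasta = toy_ref
        vcf = tmp_path / "v.vcf"
        write_vcf(vcf, [])
        table = annotate_cohort(vcf, fasta, registry)
        assert table.empty and "makes_pam" in table.columns

    def test_unknown_contig_errors(self, tmp_path, toy_ref, registry):
        _, fasta = toy_ref
        vcf = tmp_path / "v.vcf"
        with open(vcf, "w") as fh:
            fh.write(
                "##fileformat=VCFv4.2\n##contig=<ID=chrZ,length=99>\n"
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                "chrZ\t10\t.\tA\tG\t.\tPASS\t.\n"
            )
        with pytest.raises(ValueError, match="chrZ"):
            annotate_cohort(vcf, fasta, registry)

    def test_unsorted_vcf_errors(self, tmp_path, toy_ref, registry):
        seq, fasta = toy_ref
        vcf = tmp_path / "v.vcf"
        write_vcf(
            vcf,
            [
                f"chr1\t500\t.\t{seq[499]}\t{'G' if seq[499] != 'G' else 'T'}\t.\tPASS\t.",
                f"chr1\t100\t.\t{seq[99]}\t{'G' if seq[99] != 'G' else 'T'}\t.\tPASS\t.",
            ],
        )
        with pytest.raises(ValueError, match="sorted"):
            annotate_cohort(vcf, fasta, registry)


class TestLibraryIntersect:
    def guides(self, registry):
        # ten SpCas9 guides: 23-bp footprints (20 protospacer + NGG), + strand
        return pd.DataFrame(
            {
                "contig": ["chr1"] * 10,
                "start": [i * 100 for i in range(10)],
                "end": [i * 100 + 23 for i in range(10)],
                "strand": ["+"] * 10,
                "cas_name": ["SpCas9"] * 10,
            }
        )

    def variants(self, rows):
        return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "vid", "af"])

    def test_flagged_fraction(self, registry):
        guides = self.guides(registry)
        variants = self.variants([("chr1", 105, "A", "G", "v", 0.10)])
        report, frac = library_intersect(guides, variants, registry, maf_min=0.05)
        assert frac == pytest.approx(0.1)
        assert report.flagged.sum() == 1

    def test_low_maf_variant_does_not_flag(self, registry):
        guides = self.guides(registry)
        variants = self.variants([("chr1", 105, "A", "G", "v", 0.01)])
        _, frac = library_intersect(guides, variants, registry, maf_min=0.05)
        assert frac == 0.0

    def test_variant_on_pam_n_position_is_ignored(self, registry):
        guides = self.guides(registry)
        # + strand 3' PAM occupies [120, 123); the N is at 120
        variants = self.variants([("chr1", 120, "A", "G", "v", 0.5)])
        _, frac = library_intersect(guides, variants, registry, maf_min=0.05)
        assert frac == 0.0
        # ...but a constrained G position (121) does flag
        variants = self.variants([("chr1", 121, "G", "T", "v", 0.5)])
        _, frac = library_intersect(guides, variants, registry, maf_min=0.05)
        assert frac == pytest.approx(0.1)

    def test_maf_zero_counts_all_overlapping_variants(self, registry):
        guides = self.guides(registry)
        variants = self.variants([("chr1", 5, "A", "G", "v", float("nan"))])
        _, frac = library_intersect(guides, variants, registry, maf_min=0.0)
        assert frac == pytest.approx(0.1)

    def test_missing_af_with_maf_threshold_errors(self, registry):
        guides = self.guides(registry)
        variants = self.variants([("chr1", 5, "A", "G", "v", float("nan"))])
        with pytest.raises(ValueError, match="frequenc"):
            library_intersect(guides, variants, registry, maf_min=0.05)


def test_read_vcf_variants_af_modes(tmp_path):
    vcf = tmp_path / "v.vcf"
    write_vcf(
        vcf,
        ["chr1\t10\t.\tA\tG\t.\tPASS\tAF=0.25\tGT\t0|1\t0|0"],
        samples=("s1", "s2"),
    )
    info = read_vcf_variants(vcf, af_from="info")
    assert info.af.iloc[0] == pytest.approx(0.25)
    gt = read_vcf_variants(vcf, af_from="genotypes")
    assert gt.af.iloc[0] == pytest.approx(0.25)
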