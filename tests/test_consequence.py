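"""Consequence annotation: coordinate mapping, codon effects, HGVS, oracles."""

import numpy as np
import pytest

from privar.consequence import (
    ConsequenceError,
    CodingEffect,
    EffectClass,
    TranscriptModel,
    annotate_snv,
    cds_to_genomic,
    genomic_to_cds,
    is_protein_changing,
    read_gene_models,
    read_gene_models_bed,
    write_gene_models_gff3,
)
from privar.variants import VariantIOError, VariantRecord

from conftest import random_reference, random_transcript
from oracles import revcomp, translate_diff_oracle

AA1TO3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}


def single_exon_tm(start=101, end=250, strand="+"):
    return TranscriptModel("tx1", "G1", "chr1", strand, ((start, end),))


class TestGenomicToCds:
    def test_first_base_plus_strand(self):
        assert genomic_to_cds(single_exon_tm(), 101) == 1

    def test_two_intervals_plus_strand(self):
        tm = TranscriptModel("tx1", "G1", "chr1", "+", ((101, 150), (201, 252)))
        assert genomic_to_cds(tm, 201) == 51

    def test_first_base_minus_strand(self):
        tm = TranscriptModel("tx1", "G1", "chr1", "-", ((201, 252), (101, 150)))
        assert genomic_to_cds(tm, 252) == 1
        assert genomic_to_cds(tm, 101) == 102

    def test_outside_cds_is_none(self):
        tm = TranscriptModel("tx1", "G1", "chr1", "+", ((101, 150), (201, 252)))
        assert genomic_to_cds(tm, 175) is None
        assert genomic_to_cds(tm, 50) is None

    def test_injective_image_is_full_cds_range(self):
        """Mapping is a bijection between CDS bases and 1..CDS_length."""
        rng = np.random.default_rng(2)
        for strand in "+-":
            for _ in range(10):
                tm = random_transcript(rng, "chr1", 5000, int(rng.integers(5, 40)), strand)
                genomic = [
                    p for s, e in sorted(tm.cds_intervals) for p in range(s, e + 1)
                ]
                images = [genomic_to_cds(tm, p) for p in genomic]
                assert sorted(images) == list(range(1, tm.cds_length + 1))
                for p in genomic:
                    assert cds_to_genomic(tm, genomic_to_cds(tm, p)) == p


def build_transcript_with_codon(n_codons, codon_index, codon, strand="+",
                                contig_len=None, seed=0):
    """Random single-contig reference + multi-exon transcript with a fixed codon."""
    rng = np.random.default_rng(seed)
    contig_len = contig_len or 3 * n_codons + 2000
    seq = list(random_reference(rng, contig_len))
    tm = random_transcript(rng, "chr1", contig_len, n_codons, strand, n_exons=4)
    for k in range(3):
        g = cds_to_genomic(tm, (codon_index - 1) * 3 + 1 + k)
        base = codon[k] if strand == "+" else revcomp(codon[k])
        seq[g - 1] = base
    return tm, {"chr1": "".join(seq)}


class TestAnnotateSnv:
    def test_cga_codon_553_g_to_a_is_arg553gln(self):
        """A G>A at CDS 1658 of a CGA codon 553 is missense Arg -> Gln."""
        tm, ref = build_transcript_with_codon(560, 553, "CGA")
        g = cds_to_genomic(tm, 1658)
        v = VariantRecord("chr1", g, "G", "A")
        eff = annotate_snv(tm, ref, v)
        assert isinstance(eff, CodingEffect)
        assert eff.residue_index == 553
        assert (eff.ref_aa, eff.alt_aa) == ("Arg", "Gln")
        assert eff.effect_class is EffectClass.MISSENSE
        assert eff.c_hgvs == "c.1658G>A"
        assert eff.p_hgvs() == "p.(Arg553Gln)"
        assert eff.p_hgvs(parenthesized=False) == "p.Arg553Gln"

    def test_third_base_degenerate_is_synonymous(self):
        tm, ref = build_transcript_with_codon(60, 20, "CGA")
        g = cds_to_genomic(tm, 60)  # third base of codon 20
        v = VariantRecord("chr1", g, ref["chr1"][g - 1], "G" if ref["chr1"][g - 1] != "G" else "C")
        eff = annotate_snv(tm, ref, v)
        assert eff.effect_class is EffectClass.SYNONYMOUS
        assert eff.ref_aa == "Arg"
        assert eff.p_hgvs() == "p.(Arg20=)"

    def test_stop_gain_naming(self):
        tm, ref = build_transcript_with_codon(30, 10, "GAA")  # Glu
        g = cds_to_genomic(tm, 28)  # first base of codon 10
        base = "G" if tm.strand == "+" else "C"
        v = VariantRecord("chr1", g, base, "T" if tm.strand == "+" else "A")
        eff = annotate_snv(tm, ref, v)
        assert eff.effect_class is EffectClass.NONSENSE
        assert eff.alt_aa == "Ter"
        assert eff.p_hgvs(parenthesized=False, ter_symbol="*") == "p.Glu10*"

    def test_intronic_and_intergenic(self):
        tm = TranscriptModel("tx1", "G1", "chr1", "+", ((101, 150), (201, 252)))
        ref = {"chr1": "A" * 400}
        assert annotate_snv(tm, ref, VariantRecord("chr1", 175, "A", "G")) is EffectClass.INTRONIC
        assert annotate_snv(tm, ref, VariantRecord("chr1", 300, "A", "G")) is EffectClass.INTERGENIC

    def test_ref_mismatch_errors(self):
        tm, ref = build_transcript_with_codon(30, 10, "GAA")
        g = cds_to_genomic(tm, 28)
        wrong = next(b for b in "ACGT" if b != ref["chr1"][g - 1])
        with pytest.raises(VariantIOError, match="REF mismatch"):
            annotate_snv(tm, ref, VariantRecord("chr1", g, wrong, ref["chr1"][g - 1]))

    def test_non_snv_rejected(self):
        tm, ref = build_transcript_with_codon(30, 10, "GAA")
        with pytest.raises(ConsequenceError, match="SNV"):
            annotate_snv(tm, ref, VariantRecord("chr1", 5, "AT", "A"))

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_translate_and_diff_oracle(self, strand):
        """>=200 random SNVs per strand agree with whole-CDS translation."""
        rng = np.random.default_rng(17 if strand == "+" else 18)
        checked = 0
        while checked < 200:
            n_codons = int(rng.integers(10, 31))
            contig_len = 3 * n_codons + 1500
            seq = random_reference(rng, contig_len)
            ref = {"chr1": seq}
            tm = random_transcript(rng, "chr1", contig_len, n_codons, strand)
            lo, hi = tm.span
            pos = int(rng.integers(max(1, lo - 30), min(contig_len, hi + 30)))
            ref_base = seq[pos - 1]
            alt_base = "ACGT"[int(rng.integers(4))]
            if alt_base == ref_base:
                continue
            got = annotate_snv(tm, ref, VariantRecord("chr1", pos, ref_base, alt_base))
            klass, ref_aa, alt_aa, residue = translate_diff_oracle(
                tm.cds_intervals, strand, seq, pos, alt_base
            )
            if isinstance(got, CodingEffect):
                assert got.effect_class.value == klass
                assert got.residue_index == residue
                assert (got.ref_aa, got.alt_aa) == (AA1TO3[ref_aa], AA1TO3[alt_aa])
            else:
                assert got.value == klass
            checked += 1

    def test_strand_mirror_symmetry(self):
        """Annotation is invariant under reverse-complementing the fixture."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            n_codons = int(rng.integers(8, 25))
            contig_len = 3 * n_codons + 800
            seq = random_reference(rng, contig_len)
            tm = random_transcript(rng, "chr1", contig_len, n_codons, "+")
            lo, hi = tm.span
            pos = int(rng.integers(lo, hi + 1))
            alt = next(b for b in "ACGT" if b != seq[pos - 1])
            v = VariantRecord("chr1", pos, seq[pos - 1], alt)
            eff = annotate_snv(tm, {"chr1": seq}, v)

            L = contig_len
            mirror_seq = revcomp(seq)
            mirror_ivs = tuple(
                (L - e + 1, L - s + 1) for s, e in tm.cds_intervals
            )
            mirror_tm = TranscriptModel("tx-rand", "RANDGENE", "chr1", "-", mirror_ivs)
            mirror_v = VariantRecord(
                "chr1", L - pos + 1, revcomp(v.ref), revcomp(v.alt)
            )
            mirror_eff = annotate_snv(mirror_tm, {"chr1": mirror_seq}, mirror_v)
            if isinstance(eff, CodingEffect):
                for field in ("cds_pos", "ref_codon", "alt_codon", "ref_aa",
                              "alt_aa", "residue_index", "effect_class"):
                    assert getattr(eff, field) == getattr(mirror_eff, field)
            else:
                assert eff == mirror_eff


class TestProteinChanging:
    @pytest.mark.parametrize(
        "klass,expected",
        [
            (EffectClass.MISSENSE, True),
            (EffectClass.NONSENSE, True),
            (EffectClass.STOP_LOSS, True),
            (EffectClass.START_LOSS, True),
            (EffectClass.SYNONYMOUS, False),
            (EffectClass.INTRONIC, False),
            (EffectClass.UTR_OR_NONCODING, False),
            (EffectClass.INTERGENIC, False),
        ],
    )
    def test_class_set(self, klass, expected):
        assert is_protein_changing(klass) is expected


class TestGeneModelIO:
    def test_gff3_round_trip(self, tmp_path):
        rng = np.random.default_rng(31)
        models = [
            random_transcript(rng, "chr1", 5000, 12, "+"),
            random_transcript(rng, "chr2", 5000, 9, "-"),
        ]
        models[0] = TranscriptModel("tx-a", "GA", "chr1", "+", models[0].cds_intervals)
        models[1] = TranscriptModel("tx-b", "GB", "chr2", "-", models[1].cds_intervals)
        p = tmp_path / "g.gff3"
        write_gene_models_gff3(models, p)
        back = read_gene_models(p)
        assert [(t.transcript_id, t.gene, t.contig, t.strand, t.cds_intervals)
                for t in back] == [
            (t.transcript_id, t.gene, t.contig, t.strand, t.cds_intervals)
            for t in sorted(models, key=lambda t: t.transcript_id)
        ]

    def test_bed_like_reader(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "chr1\t101\t150\ttx1\t+\tG1\n"
            "chr1\t201\t252\ttx1\t+\tG1\n"
            "chr2\t300\t350\ttx2\t-\tG2\n"
            "chr2\t100\t150\ttx2\t-\tG2\n"
            "chr2\t200\t250\ttx2\t-\tG2\n"
        )
        models = read_gene_models(p)
        assert models[0].cds_intervals == ((101, 150), (201, 252))
        assert models[1].strand == "-"
        assert models[1].cds_intervals == ((300, 350), (200, 250), (100, 150))
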