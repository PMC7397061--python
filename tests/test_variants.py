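"""Variant I/O: GT decoding, round-trips, allele splitting, normalization."""

import numpy as np
import pytest

from privar.variants import (
    MISSING,
    GenotypeMatrix,
    MultiallelicSite,
    Sample,
    SampleSheet,
    VariantIOError,
    VariantRecord,
    normalize_variant,
    read_vcf,
    split_multiallelic,
    write_vcf,
)

from oracles import normalize_oracle, parse_vcf_text

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_text_vcf(path, body, samples=("s1", "s2")):
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    path.write_text(VCF_HEADER + cols + "\t".join(samples) + "\n" + body)


class TestReadVcf:
    def test_direct_gt_decoding(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_text_vcf(p, "chr1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n")
        matrix, _ = read_vcf(p)
        assert matrix.variants == [VariantRecord("chr1", 100, "A", "G")]
        assert matrix.calls.tolist() == [[1, 2]]

    def test_missing_phased_and_homref(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_text_vcf(
            p,
            "chr1\t100\t.\tA\tG\t.\t.\t.\tGT\t./.\t1|0\n"
            "chr1\t200\t.\tC\tT\t.\t.\t.\tGT\t0/0\t0|1\n",
        )
        matrix, _ = read_vcf(p)
        assert matrix.calls.tolist() == [[MISSING, 1], [0, 1]]

    def test_multiallelic_split_on_read(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_text_vcf(p, "chr1\t100\t.\tA\tC,G\t.\t.\t.\tGT\t1/2\t2/2\n")
        matrix, _ = read_vcf(p)
        assert [v.alt for v in matrix.variants] == ["C", "G"]
        assert matrix.calls.tolist() == [[1, 0], [1, 2]]

    def test_sheet_sample_missing_from_vcf_errors(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_text_vcf(p, "chr1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t0/0\n")
        sheet = SampleSheet([Sample("s1", "case"), Sample("nope", "control")])
        with pytest.raises(VariantIOError, match="nope"):
            read_vcf(p, sheet)

    def test_record_without_gt_errors(self, tmp_path):
        p = tmp_path / "a.vcf"
        body = "chr1\t100\t.\tA\tG\t.\t.\t.\tDP\t4\t7\n"
        path_text = VCF_HEADER + '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
        p.write_text(
            path_text + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n" + body
        )
        with pytest.raises(VariantIOError, match="chr1:100"):
            read_vcf(p)

    def test_haploid_genotype_rejected(self, tmp_path):
        p = tmp_path / "h.vcf"
        write_text_vcf(p, "chr1\t100\t.\tA\tG\t.\t.\t.\tGT\t1\t0/1\n")
        with pytest.raises(VariantIOError, match="non-diploid"):
            read_vcf(p)

    def test_pass_only_flag_drops_failed_records(self, tmp_path):
        p = tmp_path / "f.vcf"
        body = (
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\n"
            "chr1\t200\t.\tC\tT\t.\tLowQual\t.\tGT\t0/1\t0/0\n"
            "chr1\t300\t.\tG\tA\t.\t.\t.\tGT\t0/1\t0/0\n"
        )
        header = VCF_HEADER + '##FILTER=<ID=LowQual,Description="low">\n'
        p.write_text(
            header + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n" + body
        )
        default, _ = read_vcf(p)
        assert default.n_variants == 3
        strict, _ = read_vcf(p, pass_only=True)
        assert [v.pos for v in strict.variants] == [100, 300]

    def test_matches_hand_parser_on_random_records(self, tmp_path):
        """20 random records x 5 samples equal a line-by-line text parse."""
        rng = np.random.default_rng(42)
        samples = [f"s{i}" for i in range(5)]
        lines = []
        for i in range(20):
            pos = 10 * (i + 1)
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            gts = rng.choice(["0/0", "0/1", "1/1", "./.", "1|0"], size=5)
            lines.append(
                f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
            )
        p = tmp_path / "r.vcf"
        write_text_vcf(p, "\n".join(lines) + "\n", samples=samples)

        matrix, _ = read_vcf(p)
        oracle_samples, oracle_rows = parse_vcf_text(p)
        assert matrix.samples == oracle_samples
        got = [
            (v.contig, v.pos, v.ref, v.alt, tuple(int(c) for c in row))
            for v, row in zip(matrix.variants, matrix.calls)
        ]
        assert got == oracle_rows


class TestWriteVcf:
    def test_empty_matrix_header_only(self, tmp_path):
        matrix = GenotypeMatrix([], ["s1"], np.empty((0, 1), dtype=np.int8))
        out = tmp_path / "e.vcf"
        write_vcf(matrix, None, out)
        data_lines = [
            l for l in out.read_text().splitlines() if not l.startswith("#")
        ]
        assert data_lines == []

    def test_missing_emitted_as_dot_slash_dot(self, tmp_path):
        matrix = GenotypeMatrix(
            [VariantRecord("chr1", 5, "A", "T")], ["s1"],
            np.array([[MISSING]], dtype=np.int8),
        )
        out = tmp_path / "m.vcf"
        write_vcf(matrix, None, out)
        assert "./." in out.read_text()

    def test_round_trip_identity(self, tmp_path):
        """write_vcf then read_vcf is the identity on sorted matrices."""
        rng = np.random.default_rng(7)
        variants = []
        for i in range(30):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            variants.append(VariantRecord(f"chr{1 + i % 2}", 10 + 7 * i, ref, alt))
        variants.sort(key=lambda v: v.key)
        calls = rng.choice(
            np.array([0, 1, 2, MISSING], dtype=np.int8), size=(30, 4)
        )
        matrix = GenotypeMatrix(variants, [f"s{i}" for i in range(4)], calls)
        out = tmp_path / "rt.vcf"
        write_vcf(matrix, None, out)
        back, _ = read_vcf(out)
        assert back.equals(matrix)

    def test_unsorted_input_sorted_on_write(self, tmp_path):
        variants = [
            VariantRecord("chr1", 500, "A", "G"),
            VariantRecord("chr1", 100, "C", "T"),
        ]
        matrix = GenotypeMatrix(variants, ["s1"], np.zeros((2, 1), dtype=np.int8))
        out = tmp_path / "s.vcf"
        write_vcf(matrix, None, out)
        back, _ = read_vcf(out)
        assert [v.pos for v in back.variants] == [100, 500]


class TestSplitMultiallelic:
    def test_biallelic_unchanged(self):
        site = MultiallelicSite("chr1", 10, "A", ("G",), (((0, 1)), (1, 1)))
        [(rec, calls)] = split_multiallelic(site)
        assert rec == VariantRecord("chr1", 10, "A", "G")
        assert calls.tolist() == [1, 2]

    def test_per_allele_counting(self):
        site = MultiallelicSite("chr1", 10, "A", ("C", "G"), ((1, 2),))
        recs = split_multiallelic(site)
        assert [(r.alt, c.tolist()) for r, c in recs] == [("C", [1]), ("G", [1])]

    def test_random_gts_match_exhaustive_tally(self):
        """Per-allele counts equal a direct tally; total alt count conserved."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = int(rng.integers(1, 4))
            alts = tuple("CGT"[:k])
            gts = tuple(
                tuple(int(a) for a in rng.integers(0, k + 1, size=2))
                for _ in range(6)
            )
            site = MultiallelicSite("chr1", 10, "A", alts, gts)
            recs = split_multiallelic(site)
            for allele_idx, (_, calls) in enumerate(recs, start=1):
                expected = [sum(1 for a in g if a == allele_idx) for g in gts]
                assert calls.tolist() == expected
            totals = np.sum([c for _, c in recs], axis=0)
            expected_totals = [sum(1 for a in g if a > 0) for g in gts]
            assert totals.tolist() == expected_totals


class TestNormalize:
    REF = {"chr1": "GACGT" + "CATTTTGCA" * 30 + "ACGTG"}

    def test_minimal_snv_unchanged(self):
        seq = self.REF["chr1"]
        pos = 100
        ref = seq[pos - 1]
        alt = next(b for b in "ACGT" if b != ref)
        v = VariantRecord("chr1", pos, ref, alt)
        assert normalize_variant(v, self.REF) == v

    def test_shared_prefix_trimmed(self):
        ref = {"chr1": "NNNNNNNNNCAGGGGG"}
        v = VariantRecord("chr1", 10, "CA", "CG")
        n = normalize_variant(v, ref)
        assert (n.pos, n.ref, n.alt) == (11, "A", "G")

    def test_homopolymer_deletion_left_aligned(self):
        # TTTT homopolymer starting at pos 100
        seq = self.REF["chr1"][:99] + "TTTTG" + self.REF["chr1"][104:]
        ref = {"chr1": seq}
        v = VariantRecord("chr1", 102, "TT", "T")
        n = normalize_variant(v, ref)
        p, r, a = normalize_oracle(seq, 102, "TT", "T")
        assert (n.pos, n.ref, n.alt) == (p, r, a)
        assert n.pos < 102  # shifted left through the run

    def test_ref_mismatch_errors_with_both_strings(self):
        ref = {"chr1": "AAAA"}
        with pytest.raises(VariantIOError, match="'C'"):
            normalize_variant(VariantRecord("chr1", 2, "C", "G"), ref)

    def test_matches_brute_force_oracle_and_idempotent(self):
        """Random SNVs/indels: equals whole-sequence diff; idempotent."""
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        ref = {"chr1": seq}
        for _ in range(300):
            pos = int(rng.integers(5, 390))
            ref_len = int(rng.integers(1, 4))
            r = seq[pos - 1 : pos - 1 + ref_len]
            if rng.random() < 0.5:
                a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            else:
                a = r[0]  # deletion-style
            if a == r:
                continue
            v = VariantRecord("chr1", pos, r, a)
            n = normalize_variant(v, ref)
            assert (n.pos, n.ref, n.alt) == normalize_oracle(seq, pos, r, a)
            again = normalize_variant(n, ref)
            assert again == n
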