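"""Context-window extraction against hand-traced examples and the brute-force oracle."""

import pytest
from hypothesis import given, settings, strategies as st

from pathokg.errors import ParseError, RangeError, ReferenceAlleleError, WindowError
from pathokg.seq_context import (
    ChromSeq,
    VariantRecord,
    extract_context,
    extract_deletion,
    extract_indel,
    extract_insertion,
    extract_snv,
    read_fasta,
    read_variant_table,
    resolve_window,
    write_fasta,
    write_variant_table,
)

from oracles import clamp_window, oracle_deletion, oracle_indel, oracle_insertion, oracle_snv


def _rec(chrom="1", pos=5, ref="A", alt="T", var_class="snv", **kw):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         var_class=var_class, gene="G1", **kw)


class TestResolveWindow:
    @pytest.mark.parametrize(
        "center,W,L,expected",
        [
            (5, 5, 10, (3, 7)),
            (1, 5, 10, (1, 5)),   # left overflow 2, shifted right
            (10, 1, 10, (10, 10)),
            (10, 5, 10, (6, 10)),  # right overflow, shifted left
            (3, 6, 10, (1, 6)),    # even W: center at 0-based offset 3
        ],
    )
    def test_examples(self, center, W, L, expected):
        assert resolve_window(center, W, L) == expected

    def test_window_longer_than_chromosome_rejected(self):
        with pytest.raises(WindowError):
            resolve_window(1, 11, 10)

    def test_center_outside_rejected(self):
        with pytest.raises(RangeError):
            resolve_window(0, 3, 10)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(1, 200), st.integers(1, 200))
    def test_matches_clamp_oracle_and_stays_inside(self, center, W):
        L = 200
        s, e = resolve_window(center, W, L)
        assert (s, e) == clamp_window(center, W, L)
        assert 1 <= s <= e <= L and e - s + 1 == W


class TestSNV:
    def test_centered_substitution(self):
        chrom = ChromSeq("1", "ACGTACGTAC")
        assert extract_snv(chrom, _rec(pos=5, ref="A", alt="T"), 5) == "GTTCG"

    def test_shifted_at_chromosome_start(self):
        chrom = ChromSeq("1", "ACGTACGT")
        assert extract_snv(chrom, _rec(pos=1, ref="A", alt="C"), 5) == "CCGTA"

    def test_degenerate_window_is_alt_base(self, toy_chrom):
        v = _rec(pos=42, ref=toy_chrom.base(42), alt="T")
        assert extract_snv(toy_chrom, v, 1) == "T"

    def test_ref_mismatch_names_position(self, toy_chrom):
        wrong = "A" if toy_chrom.base(10) != "A" else "C"
        with pytest.raises(ReferenceAlleleError, match="position 10"):
            extract_snv(toy_chrom, _rec(pos=10, ref=wrong, alt="G"), 5)

    def test_alt_equal_ref_is_reference_window(self, toy_chrom):
        ref = toy_chrom.base(50)
        v = _rec(pos=50, ref=ref, alt=ref)
        s, e = resolve_window(50, 9, len(toy_chrom))
        assert extract_snv(toy_chrom, v, 9) == toy_chrom.slice(s, e)


class TestInsertion:
    def test_even_payload_hand_trace(self):
        chrom = ChromSeq("1", "ACGTACGT")
        v = _rec(pos=4, ref="", alt="GG", var_class="insertion")
        assert extract_insertion(chrom, v, 4) == "GGGT"

    def test_odd_payload_truncates_extra_from_right(self):
        chrom = ChromSeq("1", "ACGTACGT")
        v = _rec(pos=4, ref="", alt="G", var_class="insertion")
        # window (2,5)="CGTA"; insert at midpoint -> "CG G TA"; drop 0 left, 1 right
        assert extract_insertion(chrom, v, 4) == "CGGT"

    def test_vcf_anchored_dialect_normalized(self):
        chrom = ChromSeq("1", "ACGTACGT")
        plain = _rec(pos=4, ref="", alt="GG", var_class="insertion")
        anchored = _rec(pos=4, ref="T", alt="TGG", var_class="insertion")
        assert extract_insertion(chrom, anchored, 4) == extract_insertion(chrom, plain, 4)

    def test_empty_payload_rejected(self):
        chrom = ChromSeq("1", "ACGTACGT")
        with pytest.raises(ReferenceAlleleError):
            extract_insertion(chrom, _rec(pos=4, ref="", alt="", var_class="insertion"), 4)


class TestDeletion:
    def test_hand_trace(self):
        chrom = ChromSeq("1", "ACGTACGTAC")
        v = _rec(pos=5, ref="AC", alt="", var_class="deletion")
        assert extract_deletion(chrom, v, 4) == "CGTG"

    def test_single_base_full_width(self):
        chrom = ChromSeq("1", "ACGTACGTAC")
        v = _rec(pos=5, ref="A", alt="", var_class="deletion")
        assert extract_deletion(chrom, v, 9) == "ACGTCGTAC"

    def test_edge_deletion_keeps_length(self, toy_chrom):
        v = _rec(pos=1, ref=toy_chrom.base(1), alt="", var_class="deletion")
        out = extract_deletion(toy_chrom, v, 50)
        assert len(out) == 50


class TestIndel:
    @pytest.mark.parametrize("W", [1, 2, 3, 4, 5, 8, 9])
    @pytest.mark.parametrize("pos", [1, 2, 50, 100, 199, 200])
    def test_one_for_one_indel_equals_snv(self, toy_chrom, pos, W):
        ref = toy_chrom.base(pos)
        alt = "A" if ref != "A" else "C"
        as_indel = _rec(pos=pos, ref=ref, alt=alt, var_class="indel")
        as_snv = _rec(pos=pos, ref=ref, alt=alt, var_class="snv")
        assert extract_indel(toy_chrom, as_indel, W) == extract_snv(toy_chrom, as_snv, W)

    def test_empty_alt_equals_deletion(self, toy_chrom):
        ref = toy_chrom.slice(60, 61)
        as_indel = _rec(pos=60, ref=ref, alt="", var_class="indel")
        as_del = _rec(pos=60, ref=ref, alt="", var_class="deletion")
        assert extract_indel(toy_chrom, as_indel, 10) == extract_deletion(toy_chrom, as_del, 10)

    def test_matches_two_step_oracle(self):
        chrom = ChromSeq("1", "ACGTACGTAC")
        v = _rec(pos=5, ref="AC", alt="G", var_class="indel")
        assert extract_indel(chrom, v, 4) == oracle_indel(chrom.seq, 5, 6, "G", 4)


class TestOracleEquivalence:
    """Spot equivalence against the splice-the-whole-chromosome oracle."""

    @pytest.mark.parametrize("W", [1, 3, 8, 21])
    @pytest.mark.parametrize("pos", [1, 3, 97, 195, 200])
    def test_snv(self, toy_chrom, pos, W):
        v = _rec(pos=pos, ref=toy_chrom.base(pos), alt="T", var_class="snv")
        assert extract_snv(toy_chrom, v, W) == oracle_snv(toy_chrom.seq, pos, "T", W)

    @pytest.mark.parametrize("W", [2, 7, 16])
    @pytest.mark.parametrize("pos", [1, 5, 101, 200])
    @pytest.mark.parametrize("payload", ["G", "CA", "TTT"])
    def test_insertion(self, toy_chrom, pos, W, payload):
        v = _rec(pos=pos, ref="", alt=payload, var_class="insertion")
        assert extract_insertion(toy_chrom, v, W) == oracle_insertion(
            toy_chrom.seq, pos, payload, W
        )

    @pytest.mark.parametrize("W", [2, 9, 30])
    @pytest.mark.parametrize("pos", [1, 60, 197])
    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_deletion(self, toy_chrom, pos, W, d):
        if pos + d - 1 > len(toy_chrom):
            pytest.skip("segment escapes chromosome")
        v = _rec(pos=pos, ref=toy_chrom.slice(pos, pos + d - 1), alt="", var_class="deletion")
        assert extract_deletion(toy_chrom, v, W) == oracle_deletion(
            toy_chrom.seq, pos, pos + d - 1, W
        )


def test_extractions_are_pure(toy_chrom):
    v = _rec(pos=77, ref=toy_chrom.base(77), alt="G")
    assert extract_context(toy_chrom, v, 13) == extract_context(toy_chrom, v, 13)


def test_chromseq_rejects_non_dna():
    with pytest.raises(ParseError):
        ChromSeq("1", "ACGU")


class TestIO:
    def test_fasta_round_trip_with_wrapping(self, tmp_path, toy_chrom):
        path = tmp_path / "genome.fasta"
        write_fasta({"toy": toy_chrom}, path, width=21)
        back = read_fasta(path)
        assert back["toy"].seq == toy_chrom.seq

    def test_variant_table_round_trip(self, tmp_path):
        recs = [
            _rec(pos=5, clinical_label="pathogenic", diseases=["x disease", "y disease"],
                 submission_date="2021-04-01", review_status="practice guideline"),
            _rec(pos=9, ref="", alt="GG", var_class="insertion", clinical_label="benign"),
        ]
        path = tmp_path / "variants.tsv"
        write_variant_table(recs, path)
        back = read_variant_table(path)
        assert back == recs

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_variant_table([_rec()], path)
        with open(path, "a") as fh:
            fh.write("1\tnot_an_int\tA\tT\tsnv\tG1\tbenign\t\tgermline\tGRCh38\t\t\n")
        with pytest.raises(ParseError, match="line 3"):
            read_variant_table(path)
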