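"""Aligner behaviour: exact placement, indel recovery, MAPQ semantics, SAM IO."""

import numpy as np
import pytest

from caspec import (RegionAligner, export_sam, filter_by_mapq, import_sam,
                    make_test_region, semiglobal_score)
from caspec.align import ReadAlignment, left_align_ops

from _oracles import gotoh_score_oracle


class TestAlignRead:
    def test_exact_substring_is_all_match_mapq60(self, region, aligner):
        read = region.sequence[30:180]
        a = aligner.align_read("r1", read)
        assert a.ops == (("=", 150),)
        assert a.start == 30
        assert a.mapq_proxy == 60
        assert a.score == 2 * 150

    def test_three_bp_deletion_recovered_at_true_position(self, region, aligner):
        s = region.sequence
        cc = region.cleavage_coord
        read = s[20:cc + 1] + s[cc + 4:cc + 4 + (150 - (cc + 1 - 20))]
        a = aligner.align_read("r2", read)
        dels = [(k, n) for k, n in a.ops if k == "D"]
        assert dels == [("D", 3)]
        # expected score: 150 matched read bases + one open + two extends
        assert a.score == 2 * 150 - 6 - 1 - 1

    def test_read_in_two_identical_regions_gets_mapq0(self, region):
        twin = make_test_region(name="twin", seed=1)
        assert twin.sequence == region.sequence
        al = RegionAligner({region.name: region, "twin": twin})
        a = al.align_read("r3", region.sequence[10:160])
        assert a.mapq_proxy == 0
        assert not filter_by_mapq([a], 30)

    def test_garbage_read_is_unmapped(self, aligner):
        assert aligner.align_read("junk", "AC" * 75) is None

    def test_empty_or_non_acgtn_rejected(self, aligner):
        with pytest.raises(ValueError):
            aligner.align_read("e", "")
        with pytest.raises(ValueError):
            aligner.align_read("e", "ACGU")


class TestBandedVsOracle:
    def test_banded_score_equals_plain_dp_oracle_on_random_pairs(self, region):
        rng = np.random.default_rng(42)
        al = RegionAligner({region.name: region})
        ref = region.sequence
        for _ in range(60):
            start = int(rng.integers(0, 80))
            read = list(ref[start:start + 120])
            # random indel up to 8 bp plus up to 3 substitutions
            size = int(rng.integers(1, 9))
            pos = int(rng.integers(20, 90))
            if rng.random() < 0.5:
                del read[pos:pos + size]
            else:
                read[pos:pos] = ["ACGT"[i] for i in rng.integers(0, 4, size)]
            for _ in range(int(rng.integers(0, 4))):
                p = int(rng.integers(0, len(read)))
                read[p] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            a = al.align_read("r", read)
            assert a is not None
            assert a.score == gotoh_score_oracle(read, ref)

    def test_score_only_helper_matches_oracle_without_seed(self):
        # a read unrelated to the reference exercises the unbanded fallback
        rng = np.random.default_rng(0)
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        assert semiglobal_score(read, ref) == gotoh_score_oracle(read, ref)


class TestLeftAlignment:
    def test_deletion_shifts_left_within_homopolymer(self):
        #        0123456789
        ref = "ACGTTTTTACGT"
        read = ref[:6] + ref[8:]  # delete two of the T run (positions 6,7)
        ops = left_align_ops((("=", 6), ("D", 2), ("=", 4)), 0, read, ref)
        assert ops == (("=", 3), ("D", 2), ("=", 7))

    def test_insertion_shifts_left_when_content_repeats(self):
        ref = "ACGAAACGT"
        read = ref[:5] + "AA" + ref[5:]  # insert AA inside the A run
        ops = left_align_ops((("=", 5), ("I", 2), ("=", 4)), 0, read, ref)
        assert ops == (("=", 3), ("I", 2), ("=", 6))

    def test_non_repetitive_indel_unchanged(self):
        ref = "ACGTACGTAC"
        read = ref[:5] + ref[7:]
        ops = (("=", 5), ("D", 2), ("=", 3))
        assert left_align_ops(ops, 0, read, ref) == ops


class TestFilterByMapq:
    def test_threshold_boundaries(self):
        mk = lambda q: ReadAlignment("r", "x", 0, (("=", 1),), 2, q, "A")
        assert filter_by_mapq([mk(30)], 30)          # 30 at >=30 retained
        assert not filter_by_mapq([mk(49)], 50)      # 49 below 50 discarded
        assert filter_by_mapq([], 30) == []

    def test_idempotent_and_order_preserving(self):
        alns = [ReadAlignment(f"r{i}", "x", 0, (("=", 1),), 2, q, "A")
                for i, q in enumerate([60, 10, 45, 30, 0])]
        once = filter_by_mapq(alns, 30)
        assert [a.read_id for a in once] == ["r0", "r2", "r3"]
        assert filter_by_mapq(once, 30) == once


class TestSamRoundTrip:
    def test_export_import_preserves_ops(self, region, aligner, tmp_path):
        s = region.sequence
        cc = region.cleavage_coord
        reads = [
            ("exact", s[10:160]),
            ("del", s[5:cc + 1] + s[cc + 3:cc + 3 + 150 - (cc - 4)]),
            ("ins", s[40:cc + 1] + "TT" + s[cc + 1:cc + 1 + 148 - (cc - 39)]),
        ]
        alns = [aligner.align_read(rid, seq) for rid, seq in reads]
        path = tmp_path / "out.sam"
        export_sam(alns, {region.name: region}, path)
        back = import_sam(path, {region.name: region})
        assert [(b.read_id, b.start, b.ops) for b in back] == \
               [(a.read_id, a.start, a.ops) for a in alns]
        assert [b.mapq_proxy for b in back] == [a.mapq_proxy for a in alns]

    def test_cigar_m_is_split_against_reference(self, region, tmp_path):
        s = region.sequence
        seq = s[0:75] + s[76:151]  # 1 bp deletion at 75
        sam = tmp_path / "m.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            f"@SQ\tSN:{region.name}\tLN:{len(s)}\n"
            f"m\t0\t{region.name}\t1\t17\t75M1D75M\t*\t0\t0\t{seq}\t*\n")
        (a,) = import_sam(sam, {region.name: region})
        assert a.ops == (("=", 75), ("D", 1), ("=", 75))
        assert a.mapq_proxy == 17  # file MAPQ verbatim

    def test_unknown_reference_and_unsupported_cigar_error(self, region,
                                                           tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ghost\tLN:100\n"
            "r\t0\tghost\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n")
        with pytest.raises(ValueError, match="ghost"):
            import_sam(sam, {region.name: region})
        sam2 = tmp_path / "bad2.sam"
        sam2.write_text(
            "@HD\tVN:1.6\n"
            f"@SQ\tSN:{region.name}\tLN:{len(region.sequence)}\n"
            f"r\t0\t{region.name}\t1\t60\t5M100N5M\t*\t0\t0\t"
            f"{region.sequence[:10]}\t*\n")
        with pytest.raises(ValueError, match="unsupported CIGAR"):
            import_sam(sam2, {region.name: region})
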