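"""GUIDE-seq site calling: consolidation, clustering, target matching,
background subtraction, and the brute-force off-target scanner."""

import numpy as np
import pytest

from caspec import (GuideSeqSimSpec, call_guideseq_sites,
                    consolidate_duplicates, detect_integration_sites,
                    make_mini_genome, match_target, revcomp, scan_offtargets,
                    simulate_guideseq_sample, subtract_background)
from caspec.guideseq import GuideSeqSite, Junction, map_junctions

from _oracles import naive_offtarget_scan

PROTO = "ACGTACGTACGTACGTACGT"


class TestConsolidate:
    def test_half_duplicates_collapse(self):
        uniq = [("r%d" % i, "ACGT" + format(i, "04b").replace("1", "T")
                 .replace("0", "A")) for i in range(50)]
        reads = uniq + [("dup%d" % i, seq) for i, (_, seq) in enumerate(uniq)]
        cons = consolidate_duplicates(reads)
        assert len(cons) == 50
        assert all(c.multiplicity == 2 for c in cons)

    def test_all_unique_unchanged_and_sorted(self):
        reads = [("a", "TTTT"), ("b", "AAAA"), ("c", "CCCC")]
        cons = consolidate_duplicates(reads)
        assert [c.seq for c in cons] == ["AAAA", "CCCC", "TTTT"]
        assert all(c.multiplicity == 1 for c in cons)


def _mk_site(contig, pos, reads=5):
    return GuideSeqSite(contig=contig, position=pos, strand=".",
                        consolidated_read_count=reads, target_alignment=None)


class TestDetectSites:
    def test_min_reads_threshold(self):
        js = [Junction("r1", "chr1", 100, 60, 1)]
        assert detect_integration_sites(js, min_reads=2) == []
        js.append(Junction("r2", "chr1", 101, 60, 1))
        (site,) = detect_integration_sites(js, min_reads=2)
        assert site.consolidated_read_count == 2

    def test_low_mapq_junctions_ignored(self):
        js = [Junction(f"r{i}", "chr1", 100, 0, 1) for i in range(5)]
        assert detect_integration_sites(js, min_mapq=50, min_reads=2) == []

    def test_clusters_4bp_apart_merge_within_window(self):
        js = [Junction(f"a{i}", "chr1", 200, 60, 1) for i in range(3)]
        js += [Junction(f"b{i}", "chr1", 204, 60, 1) for i in range(2)]
        (site,) = detect_integration_sites(js, min_reads=2)
        assert site.position == 200  # most-supported coordinate wins
        assert site.consolidated_read_count == 5

    def test_distant_clusters_stay_separate(self):
        js = [Junction(f"a{i}", "chr1", 200, 60, 1) for i in range(2)]
        js += [Junction(f"b{i}", "chr1", 400, 60, 1) for i in range(2)]
        sites = detect_integration_sites(js, min_reads=2)
        assert [s.position for s in sites] == [200, 400]


class TestMatchTarget:
    def _genome_with_site(self, mm, seed=0, strand="+"):
        genome = make_mini_genome(1, 4000, seed=seed)
        rng = np.random.default_rng(seed + 99)
        proto = list(PROTO)
        for p in rng.choice(20, size=mm, replace=False):
            proto[p] = [b for b in "ACGT" if b != proto[p]][rng.integers(0, 3)]
        site = "".join(proto) + "AGG"
        s = list(genome["chr1"])
        if strand == "+":
            s[2000 - 17:2000 + 6] = site  # cut at 2000
        else:
            s[2000 - 6:2000 + 17] = revcomp(site)
        return {"chr1": "".join(s)}

    def test_perfect_on_target_zero_mismatches(self):
        genome = self._genome_with_site(0)
        ta = match_target(_mk_site("chr1", 2000), PROTO, "NGG", genome)
        assert ta.mismatch_count == 0
        assert ta.strand == "+"

    def test_eight_mismatches_retained_nine_rejected(self):
        ta8 = match_target(_mk_site("chr1", 2000),
                           PROTO, "NGG", self._genome_with_site(8))
        assert ta8 is not None and ta8.mismatch_count == 8
        assert match_target(_mk_site("chr1", 2000), PROTO, "NGG",
                            self._genome_with_site(9)) is None

    def test_minus_strand_site_found(self):
        genome = self._genome_with_site(2, seed=5, strand="-")
        ta = match_target(_mk_site("chr1", 2000), PROTO, "NGG", genome)
        assert ta.strand == "-"
        assert ta.mismatch_count == 2

    def test_tie_breaks_to_lower_coordinate_then_plus_strand(self):
        # an exhaustive mini-search over a palindromic planting: two equal-mm
        # placements, the lower-coordinate one must win
        genome = make_mini_genome(1, 2000, seed=1)
        s = list(genome["chr1"])
        site = PROTO + "AGG"
        s[960:983] = site
        s[1000:1023] = site
        genome = {"chr1": "".join(s)}
        ta = match_target(_mk_site("chr1", 985), PROTO, "NGG", genome,
                          search_window=40)
        assert ta.start == 960
        assert ta.strand == "+"


class TestSubtractBackground:
    def test_site_present_in_both_removed(self):
        sites = [_mk_site("chr1", 100), _mk_site("chr1", 500)]
        bkg = [_mk_site("chr1", 495)]
        out = subtract_background(sites, bkg)
        assert [s.position for s in out] == [100]

    def test_empty_background_is_identity(self):
        sites = [_mk_site("chr1", 100)]
        assert subtract_background(sites, []) == sites

    def test_idempotent(self):
        sites = [_mk_site("chr1", 100), _mk_site("chr2", 100)]
        bkg = [_mk_site("chr1", 105)]
        once = subtract_background(sites, bkg)
        assert subtract_background(once, bkg) == once


class TestEndToEnd:
    def test_called_sites_equal_truth_with_background_removed(self):
        genome = make_mini_genome(2, 8000, seed=21)
        spec = GuideSeqSimSpec(
            genome=genome, protospacer=PROTO,
            true_sites=[("chr1", 2000, "+", 0), ("chr1", 5500, "-", 4),
                        ("chr2", 3000, "+", 8), ("chr2", 6000, "+", 9)],
            background_insertion_sites=[("chr1", 7000)],
            reads_per_site=15, duplicate_rate=0.3,
            substitution_error_rate=0.001, seed=22)
        trt, bkg, truth, g = simulate_guideseq_sample(spec)
        sites = call_guideseq_sites(trt, bkg, g, PROTO)
        called = {(s.contig, s.position) for s in sites}
        expected = {(t["contig"], t["position"]) for t in truth
                    if t["expected_surviving"]}
        assert called == expected

    def test_tagless_sample_warns(self, caplog):
        genome = make_mini_genome(1, 3000, seed=1)
        reads = consolidate_duplicates([("r", genome["chr1"][100:250])])
        import logging
        with caplog.at_level(logging.WARNING):
            assert map_junctions(reads, "GTTTAATTGAGTTGTCATATGTTAATAACGGTAT",
                                 genome) == []
        assert "sample swap" in caplog.text


class TestScanOfftargets:
    def test_unique_exact_site_found_once_at_max_mm_0(self):
        genome = make_mini_genome(1, 5000, seed=31)
        s = list(genome["chr1"])
        s[1200:1223] = PROTO + "TGG"
        genome = {"chr1": "".join(s)}
        cands = scan_offtargets(genome, PROTO, "NGG", max_mm=0)
        assert len(cands) == 1
        assert (cands[0].position, cands[0].strand) == (1200, "+")

    def test_planted_mismatch_counts_filtered_by_max_mm(self):
        genome = make_mini_genome(1, 9000, seed=32)
        s = list(genome["chr1"])
        for pos, mm in [(1000, 0), (3000, 2), (6000, 4)]:
            proto = list(PROTO)
            for p in range(mm):
                proto[2 * p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[proto[2 * p]]
            s[pos:pos + 23] = "".join(proto) + "AGG"
        genome = {"chr1": "".join(s)}
        cands = scan_offtargets(genome, PROTO, "NGG", max_mm=3)
        planted = [c for c in cands if c.position in (1000, 3000, 6000)]
        assert len(planted) == 2
        assert {c.mismatch_count for c in planted} == {0, 2}

    def test_reverse_complement_site_found_on_minus(self):
        genome = make_mini_genome(1, 5000, seed=33)
        s = list(genome["chr1"])
        s[2500:2523] = revcomp(PROTO + "CGG")
        genome = {"chr1": "".join(s)}
        cands = scan_offtargets(genome, PROTO, "NGG", max_mm=0)
        hit = [c for c in cands if c.position == 2500]
        assert hit and hit[0].strand == "-"
        assert hit[0].site_sequence == PROTO + "CGG"

    def test_agrees_with_naive_hamming_scan(self):
        genome = make_mini_genome(2, 3000, seed=34)
        cands = scan_offtargets(genome, PROTO, "NGG", max_mm=8)
        got = {(c.contig, c.position, c.strand, c.mismatch_count)
               for c in cands}
        assert got == naive_offtarget_scan(genome, PROTO, "NGG", 8)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            scan_offtargets({}, PROTO)
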