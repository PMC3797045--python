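"""Alignment loading, end pileups, tRNA boundary calling, cleavage-site
calling, and strand coverage."""

import numpy as np
import pysam
import pytest

from mitomap.genome import GenomeSequence, revcomp
from mitomap.reads import (StrandLibrary, AlignedReadView, load_alignments,
                           build_end_pileup, call_trna_3prime, infer_trna_5prime,
                           call_cleavage_sites, strand_coverage, EndPileup)
from mitomap.genome import FeatureRecord


def write_sam(path, records, ref_len=1000, ref_name="ref"):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": ref_name, "LN": ref_len}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for name, flag, pos0, cigar, seq in records:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            fh.write(a)
    return path


class TestLoadAlignments:
    def test_plus_strand_views_and_softclip(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam",
                        [("r1", 0, 9, "8M3S", "ACGTACGTCCA")])
        (v,) = load_alignments(sam)
        assert (v.reference_low, v.reference_high) == (10, 17)
        assert v.strand == "+"
        assert v.three_prime_softclip == "CCA"

    def test_minus_strand_clip_is_transcript_oriented(self, tmp_path):
        # minus-strand RNA: SAM stores the reverse complement, so a CCA tail
        # appears as a leading TGG soft-clip
        sam = write_sam(tmp_path / "b.sam",
                        [("r1", 16, 9, "3S8M", "TGGACGTACGT")])
        (v,) = load_alignments(sam)
        assert v.strand == "-"
        assert v.three_prime_softclip == "CCA"

    def test_only_five_prime_mate_retained(self, tmp_path):
        # a proper pair: read1 (flag 99) and read2 (flag 147)
        sam = write_sam(tmp_path / "c.sam", [
            ("p", 99, 9, "10M", "ACGTACGTAC"),
            ("p", 147, 59, "10M", "ACGTACGTAC"),
        ])
        views = load_alignments(sam)
        assert len(views) == 1
        assert views[0].reference_low == 10

    def test_unmapped_only_file_rejected(self, tmp_path):
        sam = write_sam(tmp_path / "d.sam", [("r1", 4, -1, None, "ACGT")])
        with pytest.raises(ValueError):
            load_alignments(sam)

    def test_library_reverse_flips_strand(self, tmp_path):
        sam = write_sam(tmp_path / "e.sam", [("r1", 0, 9, "8M", "ACGTACGT")])
        (v,) = load_alignments(sam, StrandLibrary(reverse=True))
        assert v.strand == "-"


def _view(lo, hi, strand="+", clip=""):
    return AlignedReadView("r", lo, hi, strand, three_prime_softclip=clip)


class TestEndPileup:
    def test_single_read(self):
        p = build_end_pileup([_view(10, 20)], 100)
        assert p.start_count["+"][10] == 1
        assert p.end_count["+"][20] == 1
        assert p.coverage["+"][15] == 1
        assert p.coverage["+"][21] == 0

    def test_stacked_ends(self):
        views = [_view(1, 50) for _ in range(50)] + \
                [_view(51, 90) for _ in range(50)]
        p = build_end_pileup(views, 100)
        assert p.end_count["+"][50] == 50
        assert p.start_count["+"][51] == 50

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(31)
        views = []
        for _ in range(300):
            lo = int(rng.integers(1, 900))
            hi = lo + int(rng.integers(0, 100))
            views.append(_view(lo, hi, rng.choice(["+", "-"])))
        p = build_end_pileup(views, 1000)
        for s in "+-":
            starts = np.zeros(1001, dtype=int)
            ends = np.zeros(1001, dtype=int)
            cov = np.zeros(1001, dtype=int)
            for v in views:
                if v.strand != s:
                    continue
                starts[v.transcript_start()] += 1
                ends[v.transcript_end()] += 1
                cov[v.reference_low : v.reference_high + 1] += 1
            assert np.array_equal(p.start_count[s], starts)
            assert np.array_equal(p.end_count[s], ends)
            assert np.array_equal(p.coverage[s], cov)

    def test_conservation(self, views_clean):
        p = build_end_pileup(views_clean, 30000)
        for s in "+-":
            n = sum(1 for v in views_clean if v.strand == s)
            assert p.start_count[s].sum() == n
            assert p.end_count[s].sum() == n


class TestTrna3Prime:
    GENOME = GenomeSequence("g", "T" * 801 + "G" + "TT" + "T" * 196, circular=False)
    REGION = [FeatureRecord("t", "tRNA", "+", 731, 802)]

    def test_planted_cca_reads_called(self):
        views = [_view(740, 802, clip="CCA") for _ in range(8)]
        (c,) = call_trna_3prime(views, self.GENOME, self.REGION)
        assert c.three_prime == 802
        assert c.cca_support == 8

    def test_partial_tails_count_but_full_cca_required(self):
        views = [_view(740, 802, clip="CA") for _ in range(8)]
        assert call_trna_3prime(views, self.GENOME, self.REGION) == []
        views.append(_view(741, 802, clip="CCA"))
        (c,) = call_trna_3prime(views, self.GENOME, self.REGION)
        assert c.cca_support == 9 and c.full_cca_reads == 1

    def test_templated_cca_gives_no_evidence(self):
        genome = GenomeSequence("g", "T" * 802 + "CCA" + "T" * 195, circular=False)
        views = [_view(740, 802, clip="CCA") for _ in range(20)]
        assert call_trna_3prime(views, genome, self.REGION) == []

    def test_min_support_threshold(self):
        views = [_view(740, 802, clip="CCA") for _ in range(4)]
        assert call_trna_3prime(views, self.GENOME, self.REGION,
                                min_support=5) == []


class TestTrna5Prime:
    def test_perfect_stem_recovered(self):
        rng = np.random.default_rng(37)
        arm = "GATCCGT"
        body = "".join(rng.choice(list("ACGT"), size=57))
        trna = arm + body + revcomp(arm) + "A"   # 72 nt
        seq = "T" * 100 + trna + "TT" + "T" * 100
        g = GenomeSequence("g", seq, circular=False)
        three = 100 + 72
        assert infer_trna_5prime(g, three, "+") == 101

    def test_minus_strand_recovery(self):
        rng = np.random.default_rng(41)
        arm = "GATCCGT"
        body = "".join(rng.choice(list("ACGT"), size=57))
        trna = arm + body + revcomp(arm) + "A"
        seq = "T" * 100 + revcomp(trna) + "TT" + "T" * 100
        g = GenomeSequence("g", seq, circular=False)
        # minus strand: 3' end is the genomic low end of the planted span
        assert infer_trna_5prime(g, 101, "-") == 172

    def test_no_stem_flagged_as_no_call(self):
        g = GenomeSequence("g", "A" * 300, circular=False)
        assert infer_trna_5prime(g, 200, "+") is None


def _spiked_pileup(end_n=100, start_n=100, bg=3, p=500, L=1000):
    pile = EndPileup(L)
    pile.end_count["+"][:] = bg
    pile.start_count["+"][:] = bg
    pile.end_count["+"][p] = end_n
    pile.start_count["+"][p + 1] = start_n
    pile.coverage["+"][:] = 50
    return pile


class TestCleavage:
    def test_constructed_stack_enrichment(self):
        calls = call_cleavage_sites(_spiked_pileup())
        (c,) = calls
        assert c.cut_after == 500
        assert c.local_background == 3
        assert c.enrichment == pytest.approx(100 / 3, rel=1e-6)

    def test_uniform_ends_no_calls(self):
        pile = EndPileup(1000)
        pile.end_count["+"][:] = 30
        pile.start_count["+"][:] = 30
        pile.coverage["+"][:] = 300
        assert call_cleavage_sites(pile) == []

    def test_threshold_monotonicity(self):
        pile = _spiked_pileup(end_n=60, start_n=45, bg=2)
        base = call_cleavage_sites(pile, min_reads=20, min_enrichment=5)
        for mr, me in [(30, 5), (20, 12), (50, 25)]:
            tighter = call_cleavage_sites(pile, min_reads=mr, min_enrichment=me)
            assert {c.cut_after for c in tighter} <= {c.cut_after for c in base}

    def test_motif_linking(self):
        calls = call_cleavage_sites(_spiked_pileup(),
                                    motif_cuts=[("hepta@490", "+", 500)])
        assert calls[0].motif_id == "hepta@490"

    def test_minus_strand_orientation(self):
        pile = EndPileup(1000)
        pile.end_count["-"][500] = 100
        pile.start_count["-"][499] = 100
        (c,) = call_cleavage_sites(pile)
        assert (c.cut_after, c.strand) == (500, "-")


class TestStrandCoverage:
    def test_fractions(self):
        pile = EndPileup(10)
        pile.coverage["+"][1:4] = 5
        cov = strand_coverage(pile)
        assert cov["+"] == pytest.approx(0.3)
        assert cov["-"] == 0.0
        pile.coverage["-"][1:] = 1
        assert strand_coverage(pile)["-"] == 1.0

    def test_min_depth(self):
        pile = EndPileup(10)
        pile.coverage["+"][1:6] = 2
        assert strand_coverage(pile, min_depth=3)["+"] == 0.0
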