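"""Degenerate motif scanning against brute-force oracles, consensus
derivation, inverted repeats, and composition windows."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitomap.genome import GenomeSequence, revcomp
from mitomap.motifs import (IUPAC, IUPACPattern, scan, scan_mismatch,
                            derive_consensus, find_inverted_repeats,
                            composition_fraction)
from conftest import random_genome


def brute_force_scan(pattern: IUPACPattern, genome: GenomeSequence, strands):
    """Independent per-window matcher: enumerate every window (wrapping on
    circular genomes) and test symbol-by-symbol."""
    m = len(pattern)
    L = len(genome)
    n_windows = L if genome.circular else L - m + 1
    hits = []
    for start in range(n_windows):
        window = genome.subseq(start + 1, m)
        for strand in strands:
            probe = window if strand == "+" else revcomp(window)
            if all(b in IUPAC[s] for s, b in zip(pattern.symbols, probe)):
                hits.append((start + 1, strand, probe))
    hits.sort(key=lambda h: (h[0], h[1] != "+"))
    return hits


def brute_force_mismatch(pattern, genome, k, strands):
    m = len(pattern)
    L = len(genome)
    n_windows = L if genome.circular else L - m + 1
    hits = []
    for start in range(n_windows):
        window = genome.subseq(start + 1, m)
        for strand in strands:
            probe = window if strand == "+" else revcomp(window)
            mm = sum(b not in IUPAC[s] for s, b in zip(pattern.symbols, probe))
            if mm <= k:
                hits.append((start + 1, strand, mm))
    hits.sort(key=lambda h: (h[0], h[1] != "+"))
    return hits


class TestScan:
    def test_ww_on_linear_atcg_both_strands(self, toy_genome):
        hits = scan(IUPACPattern("WW"), toy_genome, strands=("+", "-"))
        assert [(h.low, h.strand, h.matched_sequence) for h in hits] == \
            [(1, "+", "AT"), (1, "-", "AT")]

    def test_planted_motif_recovered_once(self):
        rng = np.random.default_rng(5)
        g = random_genome(rng, 2000, at=0.5)
        motif = "ATATAAGTA"
        seq = g.sequence[:500] + motif + g.sequence[500 + len(motif):]
        g2 = GenomeSequence("g", seq, circular=True)
        hits = [h for h in scan(IUPACPattern(motif), g2) if h.low == 501]
        assert len(hits) == 1 and hits[0].matched_sequence == motif

    def test_circular_wrap_hit(self):
        g = GenomeSequence("g", "GTAC", circular=True)
        hits = scan(IUPACPattern("CG"), g)
        assert [(h.low, h.high, h.wraps) for h in hits] == [(4, 1, True)]

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            IUPACPattern("")

    @pytest.mark.parametrize("circular", [True, False])
    def test_matches_brute_force_on_random_instances(self, circular):
        rng = np.random.default_rng(11)
        symbols = list(IUPAC)
        for _ in range(30):
            g = random_genome(rng, int(rng.integers(50, 2000)), circular=circular)
            pat = IUPACPattern("".join(rng.choice(symbols,
                                                  size=int(rng.integers(2, 12)))))
            got = [(h.low, h.strand, h.matched_sequence)
                   for h in scan(pat, g, strands=("+", "-"))]
            assert got == brute_force_scan(pat, g, ("+", "-"))

    def test_mismatch_scan_matches_brute_force(self):
        rng = np.random.default_rng(13)
        pat = IUPACPattern("ATATAAGTA")
        for k in (0, 1, 2):
            g = random_genome(rng, 2000, at=0.7)
            got = [(h.low, h.strand, h.mismatches)
                   for h in scan_mismatch(pat, g, k, strands=("+", "-"))]
            assert got == brute_force_mismatch(pat, g, k, ("+", "-"))

    def test_strand_symmetry(self):
        # minus-strand hits of P coincide with plus-strand hits of revcomp(P)
        rng = np.random.default_rng(17)
        g = random_genome(rng, 1500)
        pat = IUPACPattern("RYWSAT")
        minus = {(h.low, h.high) for h in scan(pat, g, strands=("-",))}
        plus_rc = {(h.low, h.high)
                   for h in scan(pat.reverse_complement(), g, strands=("+",))}
        assert minus == plus_rc


@settings(derandomize=True, max_examples=50, deadline=None)
@given(seq=st.text(alphabet="ACGT", min_size=2, max_size=200),
       pat=st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=8),
       circular=st.booleans())
def test_scan_property_matches_brute_force(seq, pat, circular):
    if len(pat) > len(seq):
        return
    g = GenomeSequence("g", seq, circular=circular)
    p = IUPACPattern(pat)
    got = [(h.low, h.strand, h.matched_sequence)
           for h in scan(p, g, strands=("+", "-"))]
    assert got == brute_force_scan(p, g, ("+", "-"))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(seqs=st.lists(st.text(alphabet="ACGT", min_size=12, max_size=12),
                     min_size=2, max_size=10))
def test_consensus_property_minimal_cover(seqs):
    pat = derive_consensus(seqs)
    assert all(pat.matches(s) for s in seqs)
    for col, sym in enumerate(pat.symbols):
        assert IUPAC[sym] == frozenset(s[col] for s in seqs)


class TestDeriveConsensus:
    def test_forced_symbols(self):
        pat = derive_consensus(["AAA", "ATG", "AAT"])
        # columns observe {A}, {A,T}, {A,G,T}
        assert pat.symbols == "AWD"

    def test_consensus_matches_every_input_and_is_minimal(self):
        rng = np.random.default_rng(23)
        seqs = ["".join(rng.choice(list("ACGT"), size=15)) for _ in range(8)]
        pat = derive_consensus(seqs)
        assert all(pat.matches(s) for s in seqs)
        # minimality: dropping any observed base from a column breaks a match
        for col, sym in enumerate(pat.symbols):
            observed = {s[col] for s in seqs}
            assert IUPAC[sym] == frozenset(observed)

    def test_idempotence(self):
        seqs = ["ATA", "TTA", "ATG"]
        pat = derive_consensus(seqs)
        again = derive_consensus([s for s in seqs if pat.matches(s)])
        assert all(again.matches(s) for s in seqs)

    def test_errors(self):
        with pytest.raises(ValueError):
            derive_consensus(["AT"])
        with pytest.raises(ValueError):
            derive_consensus(["AT", "ATG"])


class TestInvertedRepeats:
    def test_minimal_example(self):
        g = GenomeSequence("g", "AAATTT", circular=False)
        assert find_inverted_repeats(g, 3, 0) == [((1, 3), (4, 6))]

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(29)
        g = random_genome(rng, 1000, circular=False, at=0.5)
        got = find_inverted_repeats(g, 5, 10)
        expected = []
        for a1 in range(1, 1000 - (2 * 5 + 10) + 2):
            a2 = a1 + 5 + 10
            if g.subseq(a2, 5) == revcomp(g.subseq(a1, 5)):
                expected.append(((a1, a1 + 4), (a2, a2 + 4)))
        assert got == expected

    def test_planted_ori_arms_recovered(self):
        rng = np.random.default_rng(31)
        arm = "GACGTCC"
        spacer = "".join(rng.choice(list("AT"), size=29))
        g = GenomeSequence("g", "A" * 100 + arm + spacer + revcomp(arm) + "T" * 100,
                           circular=False)
        pairs = find_inverted_repeats(g, 7, 29, region=(50, 200))
        assert ((101, 107), (137, 143)) in pairs

    def test_region_too_small(self):
        g = GenomeSequence("g", "ACGTACGT", circular=False)
        with pytest.raises(ValueError):
            find_inverted_repeats(g, 3, 10)


class TestCompositionFraction:
    @pytest.mark.parametrize("seq,span,bases,expected", [
        ("ATAT", (1, 4), "AT", 1.0),
        ("ATGC", (1, 4), "AT", 0.5),
        ("G" * 17, (1, 17), "G", 1.0),
    ])
    def test_fractions(self, seq, span, bases, expected):
        g = GenomeSequence("g", seq, circular=False)
        assert composition_fraction(g, span, bases) == expected

    def test_wrap_aware(self):
        g = GenomeSequence("g", "GGAA", circular=True)
        assert composition_fraction(g, (4, 1), "AG") == 1.0
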