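"""Promoter and origin-of-replication models.

The promoter model is a 20-base degenerate consensus spanning -12..+8 around
the transcription start, whose core -8..+1 is the nonanucleotide ATATAAGTA.
The +1 initiating nucleotide is enforced to be adenosine (invariant in vivo)
on top of the degenerate consensus.

The ori model is a five-part structure on one strand: the 20-bp promoter, a
17-bp G-rich element starting within a few bases of the promoter end, an
A/T-rich spacer of roughly 200 bp, and two complementary 7-bp arms separated
by a 29-bp A/T tract (a hairpin).  Inactive ori carry one contiguous insert
inside the promoter window; they are detected by a single-gap alignment of
the consensus (one insertion allowed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genome import GenomeSequence, FeatureRecord, revcomp
from .motifs import IUPACPattern, IUPAC, MotifHit, scan, scan_mismatch, _encode, _symbol_mask
from .s288c import NONANUCLEOTIDE, CONSENSUS_PROMOTER

__all__ = [
    "PromoterHit",
    "NonanucleotideHit",
    "OriParams",
    "OriCall",
    "scan_promoters",
    "scan_nonanucleotides",
    "detect_ori",
    "assign_promoters",
    "DEFAULT_CONSENSUS",
]

DEFAULT_CONSENSUS = IUPACPattern(CONSENSUS_PROMOTER, name="consensus_promoter")

#: 1-based offset of the +1 transcription start within the 20-nt window.
PLUS_ONE_OFFSET = 13


@dataclass
class PromoterHit:
    """A consensus-promoter match; ``tss`` is the +1 adenosine position."""

    tss: int
    strand: str
    window_low: int
    window_high: int
    window_sequence: str
    nonanucleotide_ok: bool
    serving: str = "unassigned"  # gene | ori | unassigned
    wraps: bool = False


@dataclass(frozen=True)
class NonanucleotideHit:
    """A nonanucleotide occurrence, annotated with whether its surrounding
    20-nt window extends to a full consensus-promoter match."""

    hit: MotifHit
    extends_to_consensus: bool


@dataclass(frozen=True)
class OriParams:
    """Tunable parameters of the five-part ori model."""

    g_rich_literal: Optional[str] = None     # exact 17-mer; None -> fraction rule
    g_min_count: int = 15                    # min G's of 17 when no literal
    g_len: int = 17
    g_offset_range: tuple = (-4, 4)          # G-rich start rel. promoter end + 1
    spacer_range: tuple = (150, 260)         # A/T spacer length window, nt
    spacer_at_fraction: float = 0.80
    arm_len: int = 7
    arm_gap: int = 29
    insert_range: tuple = (10, 60)           # detectable promoter-insert lengths
    insert_split_range: tuple = (2, 18)      # allowed split columns in window
    require_downstream_for_inactive: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.spacer_range, self.insert_range, self.insert_split_range):
            if lo > hi or lo < 0:
                raise ValueError("inconsistent params: negative or inverted window")


@dataclass
class OriCall:
    """An origin-of-replication call anchored on a promoter.

    Spans are 1-based inclusive genomic ``(low, high)``; for inactive calls
    without downstream structure they may be None.
    """

    promoter: PromoterHit
    status: str                              # active | inactive
    g_rich: Optional[tuple] = None
    spacer: Optional[tuple] = None
    arm1: Optional[tuple] = None
    arm_gap_span: Optional[tuple] = None
    arm2: Optional[tuple] = None
    insert_length: Optional[int] = None
    insert_offset_in_promoter: Optional[int] = None


def scan_promoters(genome: GenomeSequence,
                   consensus: IUPACPattern = DEFAULT_CONSENSUS,
                   strands: tuple = ("+",),
                   require_plus1_a: bool = True) -> list[PromoterHit]:
    """Every consensus-promoter match, with the transcription start resolved.

    ``consensus`` must be 20 nt with the +1 at offset 13.  Matches whose +1
    base is not A are discarded when ``require_plus1_a`` (the default; the
    initiating nucleotide is invariably adenosine in vivo).
    """
    if len(consensus) != 20:
        raise ValueError("consensus must be 20 nt (-12..+8)")
    L = len(genome)
    hits = []
    for h in scan(consensus, genome, strands=strands):
        if h.strand == "+":
            tss = h.low + PLUS_ONE_OFFSET - 1
        else:
            # window read on minus strand: motif offset k sits at high-(k-1)
            high_lin = h.low + 19
            tss = high_lin - (PLUS_ONE_OFFSET - 1)
        if genome.circular:
            tss = (tss - 1) % L + 1
        window = h.matched_sequence
        if require_plus1_a and window[PLUS_ONE_OFFSET - 1] != "A":
            continue
        hits.append(
            PromoterHit(
                tss=tss,
                strand=h.strand,
                window_low=h.low,
                window_high=h.high,
                window_sequence=window,
                nonanucleotide_ok=window[4:13] == NONANUCLEOTIDE,
                wraps=h.wraps,
            )
        )
    return hits


def scan_nonanucleotides(genome: GenomeSequence, max_mismatch: int = 0,
                         consensus: IUPACPattern = DEFAULT_CONSENSUS,
                         strands: tuple = ("+",)) -> list[NonanucleotideHit]:
    """Nonanucleotide occurrences with <= ``max_mismatch`` mismatches.

    Each hit is annotated with whether the 20-nt window placing the
    nonanucleotide at -8..+1 matches the full consensus promoter.
    """
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    nona = IUPACPattern(NONANUCLEOTIDE, name="nonanucleotide")
    L = len(genome)
    out = []
    for h in scan_mismatch(nona, genome, max_mismatch, strands=strands):
        # window start such that the nonanucleotide occupies offsets 5..13
        if h.strand == "+":
            wstart = h.low - 4
        else:
            wstart = (h.low + len(nona) - 1) - 19 + 4
        extends = False
        if genome.circular or 1 <= wstart <= L - 19:
            wstart_n = (wstart - 1) % L + 1 if genome.circular else wstart
            window = genome.subseq(wstart_n, 20)
            if h.strand == "-":
                window = revcomp(window)
            extends = consensus.matches(window)
        out.append(NonanucleotideHit(hit=h, extends_to_consensus=extends))
    return out


def _norm(p: int, L: int) -> int:
    return (p - 1) % L + 1


def _oriented(genome: GenomeSequence, start_t: int, length: int, strand: str):
    """Sequence of ``length`` nt beginning at transcript-orientation position
    ``start_t`` and reading downstream; returns (seq, (low, high)) in genomic
    coordinates."""
    L = len(genome)
    if strand == "+":
        low = _norm(start_t, L) if genome.circular else start_t
        seq = genome.subseq(low, length)
        high = _norm(low + length - 1, L) if genome.circular else low + length - 1
        return seq, (low, high)
    high = _norm(start_t, L) if genome.circular else start_t
    low_lin = high - length + 1
    low = _norm(low_lin, L) if genome.circular else low_lin
    seq = revcomp(genome.subseq(low, length))
    return seq, (low, high)


def _g_rich_ok(seq: str, params: OriParams) -> bool:
    if params.g_rich_literal is not None:
        return seq == params.g_rich_literal
    return seq.count("G") >= params.g_min_count


def _downstream_structure(genome: GenomeSequence, after_t: int, strand: str,
                          params: OriParams):
    """Search for G-rich + spacer + hairpin arms downstream of a promoter
    whose last transcript-orientation position is ``after_t``.

    Returns (g_rich, spacer, arm1, gap, arm2) spans or None.
    """
    step = 1 if strand == "+" else -1
    for off in range(params.g_offset_range[0], params.g_offset_range[1] + 1):
        g_start_t = after_t + step * (1 + off)
        g_seq, g_span = _oriented(genome, g_start_t, params.g_len, strand)
        if not _g_rich_ok(g_seq, params):
            continue
        g_end_t = g_start_t + step * (params.g_len - 1)
        for sp_len in range(params.spacer_range[0], params.spacer_range[1] + 1):
            sp_start_t = g_end_t + step
            arm1_start_t = g_end_t + step * (sp_len + 1)
            arm1_seq, arm1_span = _oriented(genome, arm1_start_t, params.arm_len, strand)
            gap_start_t = arm1_start_t + step * params.arm_len
            arm2_start_t = gap_start_t + step * params.arm_gap
            arm2_seq, arm2_span = _oriented(genome, arm2_start_t, params.arm_len, strand)
            if arm2_seq != revcomp(arm1_seq):
                continue
            sp_seq, sp_span = _oriented(genome, sp_start_t, sp_len, strand)
            at = (sp_seq.count("A") + sp_seq.count("T")) / sp_len
            if at < params.spacer_at_fraction:
                continue
            _, gap_span = _oriented(genome, gap_start_t, params.arm_gap, strand)
            return g_span, sp_span, arm1_span, gap_span, arm2_span
    return None


def _gapped_consensus_matches(genome: GenomeSequence, consensus: IUPACPattern,
                              params: OriParams) -> list[tuple]:
    """Single-insertion consensus alignments: positions where the first ``s``
    consensus columns match, then after an insert of ``L`` bases the
    remaining columns match.  Returns (window_start_0based, split, insert_len)
    with the smallest split and its insert length per position."""
    m = len(consensus)
    seq = genome.sequence
    Lmax = params.insert_range[1]
    ext = seq + (seq[: m + Lmax] if genome.circular else "")
    codes = _encode(ext)
    n = len(seq) if genome.circular else max(0, len(seq) - m - params.insert_range[0] + 1)
    if n == 0:
        return []
    # A[c][q]: consensus column c matches extended-sequence base at q
    A = [
        _symbol_mask(sym)[codes] for sym in consensus.symbols
    ]
    # G[c][q]: columns c..m-1 match starting at q (column c aligned at q)
    Gmat = [None] * m
    acc = A[m - 1].copy()
    Gmat[m - 1] = acc
    for c in range(m - 2, -1, -1):
        nxt = np.zeros_like(A[c])
        nxt[:-1] = Gmat[c + 1][1:]
        Gmat[c] = A[c] & nxt
    # prefix length per window start
    pref_len = np.zeros(n, dtype=np.int32)
    ok = np.ones(n, dtype=bool)
    for c in range(m):
        col = A[c][c : c + n]
        if len(col) < n:
            col = np.pad(col, (0, n - len(col)), constant_values=False)
        ok &= col
        pref_len[ok] = c + 1
    found: dict[int, tuple] = {}
    s_lo, s_hi = params.insert_split_range
    for s in range(s_lo, s_hi + 1):
        Gs = Gmat[s]
        for ins in range(params.insert_range[0], params.insert_range[1] + 1):
            idx = np.arange(n) + s + ins
            valid = idx < len(Gs)
            cand = np.zeros(n, dtype=bool)
            cand[valid] = Gs[idx[valid]]
            cand &= pref_len >= s
            for p in np.nonzero(cand)[0]:
                p = int(p)
                if p not in found:
                    found[p] = (p, s, ins)
    return sorted(found.values())


def detect_ori(genome: GenomeSequence, promoters: list[PromoterHit],
               params: OriParams = OriParams(),
               consensus: IUPACPattern = DEFAULT_CONSENSUS) -> list[OriCall]:
    """Five-part ori calls: active (all parts downstream of an intact
    promoter) and inactive (consensus promoter disrupted by one insert).

    Active and inactive calls partition: a promoter anchoring an active call
    is never re-reported as insert-disrupted.
    """
    L = len(genome)
    calls: list[OriCall] = []
    active_windows = []
    for ph in promoters:
        after_t = ph.window_high if ph.strand == "+" else ph.window_low
        parts = _downstream_structure(genome, after_t, ph.strand, params)
        if parts is None:
            continue
        g_span, sp_span, arm1_span, gap_span, arm2_span = parts
        calls.append(OriCall(promoter=ph, status="active", g_rich=g_span,
                             spacer=sp_span, arm1=arm1_span,
                             arm_gap_span=gap_span, arm2=arm2_span))
        active_windows.append((ph.window_low, ph.window_high))

    # One planted insert can align several ways when the upstream background
    # happens to match leading consensus columns (those variants start
    # earlier and report a longer insert).  All variants share the window
    # end, and only the most parsimonious one — the smallest insert — has
    # every flanking column genuinely aligned, so keep that one per cluster.
    by_end: dict[int, tuple] = {}
    for p0, split, ins in _gapped_consensus_matches(genome, consensus, params):
        end = p0 + 20 + ins
        if end not in by_end or ins < by_end[end][2]:
            by_end[end] = (p0, split, ins)
    for p0, split, ins in sorted(by_end.values()):
        wlow = p0 + 1
        whigh_lin = wlow + 20 + ins - 1
        # skip anything overlapping an intact active-promoter window
        if any(not (whigh_lin < alow or wlow > ahigh)
               for alow, ahigh in active_windows):
            continue
        tss_lin = wlow + (PLUS_ONE_OFFSET - 1) + (ins if split <= PLUS_ONE_OFFSET - 1 else 0)
        whigh = _norm(whigh_lin, L) if genome.circular else whigh_lin
        ph = PromoterHit(
            tss=_norm(tss_lin, L) if genome.circular else tss_lin,
            strand="+",
            window_low=wlow,
            window_high=whigh,
            window_sequence=genome.subseq(wlow, 20 + ins),
            nonanucleotide_ok=False,
            wraps=genome.circular and whigh_lin > L,
        )
        call = OriCall(promoter=ph, status="inactive", insert_length=ins,
                       insert_offset_in_promoter=split)
        if params.require_downstream_for_inactive:
            parts = _downstream_structure(genome, whigh_lin, "+", params)
            if parts is None:
                continue
            (call.g_rich, call.spacer, call.arm1,
             call.arm_gap_span, call.arm2) = parts
        calls.append(call)
    return calls


def assign_promoters(promoters: list[PromoterHit],
                     features: list[FeatureRecord],
                     ori_calls: list[OriCall],
                     genome_length: int) -> list[PromoterHit]:
    """Classify promoters as ori-serving, gene-serving, or unassigned.

    A promoter serves an ori when an active OriCall anchors on it; otherwise
    it serves genes when at least one gene-class feature lies downstream on
    the same strand before the next promoter (circular-aware).
    """
    L = genome_length
    active_tss = {(c.promoter.tss, c.promoter.strand)
                  for c in ori_calls if c.status == "active"}
    gene_types = {"gene", "tRNA", "rRNA", "orf"}
    genes = [f for f in features if f.ftype in gene_types and f.located]

    def downstream_dist(tss: int, strand: str, pos: int) -> int:
        return (pos - tss) % L if strand == "+" else (tss - pos) % L

    for ph in promoters:
        if (ph.tss, ph.strand) in active_tss:
            ph.serving = "ori"
            continue
        others = [q for q in promoters
                  if q is not ph and q.strand == ph.strand]
        next_prom = min(
            (downstream_dist(ph.tss, ph.strand, q.tss) for q in others
             if downstream_dist(ph.tss, ph.strand, q.tss) > 0),
            default=L,
        )
        served = any(
            f.strand == ph.strand
            and 0 <= downstream_dist(ph.tss, ph.strand, f.five_prime()) < next_prom
            for f in genes
        )
        ph.serving = "gene" if served else "unassigned"
    return promoters
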