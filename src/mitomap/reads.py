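"""Read-evidence calling from strand-specific alignments.

Alignments are reduced to :class:`AlignedReadView` objects (one per retained
record, 3'-mates dropped to avoid double counting), then to per-position
strand-resolved end pileups.  The pileups drive three callers:

* tRNA 3' ends from non-genome-templated CCA soft-clips: the mature 3' end
  is the last templated base, pinpointed by reads whose alignment stops there
  with a clipped tail beginning C/CA/CCA;
* tRNA 5' ends from an acceptor-stem heuristic: the candidate start whose
  first 7 bases best reverse-complement-pair (G·U allowed at half weight)
  with the 7 bases preceding the discriminator;
* endonucleolytic cleavage sites from read-end co-enrichment: many reads
  ending exactly at the 5'-side nucleotide and many starting exactly at the
  3'-side nucleotide, well above local background coverage.

Cleavage coordinates are reported as "cut after p" in transcript orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pysam

from .genome import GenomeSequence, FeatureRecord, revcomp

__all__ = [
    "StrandLibrary",
    "AlignedReadView",
    "EndPileup",
    "TrnaBoundaryCall",
    "CleavageSiteCall",
    "load_alignments",
    "build_end_pileup",
    "call_trna_3prime",
    "infer_trna_5prime",
    "call_cleavage_sites",
    "strand_coverage",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StrandLibrary:
    """How SAM flags map to RNA strand for a directional library.

    ``five_prime_mate`` names the mate carrying the fragment's 5' end
    ("read1" or "read2"); only that mate is retained.  ``reverse`` is True
    when the retained mate aligns opposite the RNA strand.
    """

    five_prime_mate: str = "read1"
    reverse: bool = False

    def __post_init__(self) -> None:
        if self.five_prime_mate not in ("read1", "read2"):
            raise ValueError("five_prime_mate must be 'read1' or 'read2'")


@dataclass(frozen=True)
class AlignedReadView:
    """A retained alignment reduced to what the callers need.

    ``reference_low/high`` are 1-based inclusive; ``strand`` is the strand of
    the originating RNA; ``three_prime_softclip`` is the clipped tail at the
    read's transcript-orientation 3' end, read 5'->3' in transcript
    orientation (taken from the alignment record, never the reference).
    """

    read_id: str
    reference_low: int
    reference_high: int
    strand: str
    three_prime_softclip: str = ""
    mate_role: str = "five_prime_mate"

    def transcript_start(self) -> int:
        return self.reference_low if self.strand == "+" else self.reference_high

    def transcript_end(self) -> int:
        return self.reference_high if self.strand == "+" else self.reference_low


def load_alignments(path, library: StrandLibrary = StrandLibrary()) -> list[AlignedReadView]:
    """Read a SAM/BAM file into :class:`AlignedReadView` objects.

    Secondary/supplementary records are skipped; for paired data only the
    configured 5' mate is kept (the 3' mate would double-count short
    inserts).  Raises if the file holds only unmapped records.
    """
    views: list[AlignedReadView] = []
    n_records = 0
    want_read1 = library.five_prime_mate == "read1"
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            n_records += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_paired and (rec.is_read1 != want_read1):
                continue
            strand = "-" if (rec.is_reverse != library.reverse) else "+"
            clip = ""
            ct = rec.cigartuples or []
            seq = rec.query_sequence or ""
            if strand == "+":
                if ct and ct[-1][0] == 4:
                    clip = seq[len(seq) - ct[-1][1]:]
            else:
                if ct and ct[0][0] == 4:
                    clip = revcomp(seq[: ct[0][1]])
            views.append(
                AlignedReadView(
                    read_id=rec.query_name,
                    reference_low=rec.reference_start + 1,
                    reference_high=rec.reference_end,
                    strand=strand,
                    three_prime_softclip=clip,
                )
            )
    if n_records and not views:
        raise ValueError(f"{path}: no mapped records retained")
    return views


@dataclass
class EndPileup:
    """Per-position, per-strand counts of transcript 5' starts, 3' ends, and
    base coverage.  Arrays are indexed 1..genome_length (index 0 unused)."""

    genome_length: int
    start_count: dict = field(default_factory=dict)
    end_count: dict = field(default_factory=dict)
    coverage: dict = field(default_factory=dict)
    n_reads: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in "+-":
            self.start_count.setdefault(s, np.zeros(self.genome_length + 1, dtype=np.int64))
            self.end_count.setdefault(s, np.zeros(self.genome_length + 1, dtype=np.int64))
            self.coverage.setdefault(s, np.zeros(self.genome_length + 1, dtype=np.int64))
            self.n_reads.setdefault(s, 0)


def build_end_pileup(views: Iterable[AlignedReadView], genome_length: int) -> EndPileup:
    """Accumulate start/end/coverage counts from read views."""
    p = EndPileup(genome_length)
    cov_diff = {s: np.zeros(genome_length + 2, dtype=np.int64) for s in "+-"}
    for v in views:
        s = v.strand
        p.start_count[s][v.transcript_start()] += 1
        p.end_count[s][v.transcript_end()] += 1
        cov_diff[s][v.reference_low] += 1
        cov_diff[s][v.reference_high + 1] -= 1
        p.n_reads[s] += 1
    for s in "+-":
        p.coverage[s][1:] = np.cumsum(cov_diff[s][1:-1])
    return p


@dataclass
class TrnaBoundaryCall:
    """A read-evidence tRNA boundary: 3' end from CCA soft-clips, 5' end
    inferred from the acceptor stem (or taken from annotation)."""

    trna_id: str
    strand: str
    three_prime: int
    cca_support: int
    full_cca_reads: int
    five_prime: Optional[int] = None
    five_prime_method: str = "acceptor_stem"


def _templated_cca(genome: GenomeSequence, p: int, strand: str) -> bool:
    """True when the genome itself reads CCA immediately downstream of p in
    transcript orientation (such positions give no CCA evidence)."""
    L = len(genome)
    try:
        if strand == "+":
            if not genome.circular and p + 3 > L:
                return False
            return genome.subseq((p % L) + 1 if genome.circular else p + 1, 3) == "CCA"
        if not genome.circular and p - 3 < 1:
            return False
        low = ((p - 4) % L) + 1 if genome.circular else p - 3
        return revcomp(genome.subseq(low, 3)) == "CCA"
    except IndexError:
        return False


def call_trna_3prime(views: Iterable[AlignedReadView], genome: GenomeSequence,
                     regions: list[FeatureRecord],
                     min_support: int = 5) -> list[TrnaBoundaryCall]:
    """Call the mature tRNA 3' end in each candidate region.

    Evidence reads end at a position p with a soft-clip beginning C, CA or
    CCA (partial tails tolerated — fragmentation truncates them), provided
    the clip is non-templated: if the genome itself continues CCA after p the
    reads are discounted.  A call needs ``min_support`` evidence reads, at
    least one with the full CCA, and takes the best-supported p (ties to the
    downstream-most position, logged).
    """
    support: dict[tuple, int] = {}
    full: dict[tuple, int] = {}
    for v in views:
        clip = v.three_prime_softclip
        if not clip.startswith("C"):
            continue
        key = (v.strand, v.transcript_end())
        if _templated_cca(genome, key[1], v.strand):
            continue
        support[key] = support.get(key, 0) + 1
        if clip.startswith("CCA"):
            full[key] = full.get(key, 0) + 1

    calls = []
    for region in regions:
        lo, hi = region.low, region.high
        cands = [
            (n, p) for (s, p), n in support.items()
            if s == region.strand and lo <= p <= hi and full.get((s, p), 0) >= 1
            and n >= min_support
        ]
        if not cands:
            continue
        best_n = max(n for n, _ in cands)
        at_best = [p for n, p in cands if n == best_n]
        if len(at_best) > 1:
            logger.warning("tRNA %s: 3'-end support tie at %s; taking downstream-most",
                           region.feature_id, at_best)
        p = max(at_best) if region.strand == "+" else min(at_best)
        calls.append(
            TrnaBoundaryCall(
                trna_id=region.feature_id,
                strand=region.strand,
                three_prime=p,
                cca_support=best_n,
                full_cca_reads=full[(region.strand, p)],
            )
        )
    return calls


_PAIR_SCORE = {("A", "T"): 1.0, ("T", "A"): 1.0, ("G", "C"): 1.0, ("C", "G"): 1.0,
               ("G", "T"): 0.5, ("T", "G"): 0.5}


def infer_trna_5prime(genome: GenomeSequence, three_prime: int, strand: str,
                      length_range: tuple = (60, 95),
                      min_score: float = 5.0) -> Optional[int]:
    """Infer the tRNA 5' end by acceptor-stem pairing.

    Scores every candidate tRNA length in ``length_range``: the first 7
    bases must pair (antiparallel, Watson-Crick 1.0, G·U 0.5) with the 7
    bases immediately 5' of the discriminator (the base preceding the
    non-templated CCA, i.e. at ``three_prime``).  Best score wins; ties go to
    the length closest to the canonical 72 nt.  Returns None (no call) when
    no stem reaches ``min_score``.
    """
    L = len(genome)
    step = 1 if strand == "+" else -1

    def base_at(t: int) -> str:
        pos = ((t - 1) % L) + 1 if genome.circular else t
        if not genome.circular and not 1 <= pos <= L:
            return "N"
        b = genome.base(pos)
        return b if strand == "+" else revcomp(b)

    # 3' side of the acceptor stem, transcript order (7 bases before discriminator)
    arm3 = [base_at(three_prime - step * k) for k in range(7, 0, -1)]
    best = None  # (score, -|len-72|, 5' coordinate)
    for tlen in range(length_range[0], length_range[1] + 1):
        start_t = three_prime - step * (tlen - 1)
        arm5 = [base_at(start_t + step * k) for k in range(7)]
        score = sum(_PAIR_SCORE.get((a, b), 0.0) for a, b in zip(arm5, arm3[::-1]))
        key = (score, -abs(tlen - 72))
        if best is None or key > best[:2]:
            pos = ((start_t - 1) % L) + 1 if genome.circular else start_t
            best = (score, -abs(tlen - 72), pos)
    if best is None or best[0] < min_score:
        logger.warning("no acceptor stem with score >= %.1f near 3'=%d (%s strand)",
                       min_score, three_prime, strand)
        return None
    return best[2]


@dataclass
class CleavageSiteCall:
    """A cleavage site: cut between p and p+1 in transcript orientation,
    supported by read ends stacking on both sides of the cut."""

    cut_after: int
    strand: str
    end_support: int
    start_support: int
    local_background: float
    enrichment: float
    motif_id: Optional[str] = None


def call_cleavage_sites(pileup: EndPileup, min_reads: int = 20,
                        min_enrichment: float = 10.0,
                        motif_cuts: Optional[list[tuple]] = None,
                        background_window: int = 101) -> list[CleavageSiteCall]:
    """Positions where >= ``min_reads`` reads end at p and >= ``min_reads``
    start at the next transcript position, enriched over the local
    scattered-end rate.

    ``local_background`` is the median, over a 101-nt window centred on p, of
    the per-position read-end event rate (mean of start and end counts on the
    same strand).  Random fragmentation scatters read ends roughly uniformly,
    so genuine processing sites stand out as sharp stacks against that rate;
    base coverage would not work as the denominator, since a stack of read
    ends can never exceed the coverage it sits under.  ``motif_cuts`` is an
    optional list of ``(motif_id, strand, cut_after)`` to link calls to
    motif-annotated cuts.

    Raising either threshold never adds calls (monotone).
    """
    half = background_window // 2
    cut_lookup = {}
    for mid, s, p in motif_cuts or []:
        cut_lookup[(s, p)] = mid
    calls = []
    Lg = pileup.genome_length
    for s in "+-":
        nxt = 1 if s == "+" else -1
        ends = pileup.end_count[s]
        starts = pileup.start_count[s]
        cand = np.nonzero(ends >= min_reads)[0]
        for p in cand:
            q = p + nxt
            if not 1 <= q <= Lg or starts[q] < min_reads:
                continue
            lo, hi = max(1, p - half), min(Lg, p + half)
            window_rate = 0.5 * (ends[lo : hi + 1] + starts[lo : hi + 1])
            bg = float(np.median(window_rate))
            enr = min(ends[p], starts[q]) / max(bg, 1.0)
            if enr < min_enrichment:
                continue
            calls.append(
                CleavageSiteCall(
                    cut_after=int(p),
                    strand=s,
                    end_support=int(ends[p]),
                    start_support=int(starts[q]),
                    local_background=bg,
                    enrichment=float(enr),
                    motif_id=cut_lookup.get((s, int(p))),
                )
            )
    calls.sort(key=lambda c: (c.cut_after, c.strand != "+"))
    return calls


def strand_coverage(pileup: EndPileup, min_depth: int = 1) -> dict:
    """Fraction of genome positions with coverage >= ``min_depth``, per strand."""
    return {
        s: float(np.count_nonzero(pileup.coverage[s][1:] >= min_depth))
        / pileup.genome_length
        for s in "+-"
    }
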