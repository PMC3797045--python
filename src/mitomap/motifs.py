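"""Degenerate IUPAC motif compilation and circular, strand-aware scanning.

Scanning is exact-set matching: an IUPAC symbol matches a genome base iff the
base is in the symbol's set.  N in the *genome* matches no symbol (unknown
sequence never produces a hit).  Minus-strand hits are windows whose reverse
complement matches the pattern; they are reported on the same low/high span
with strand '-'.  On circular genomes windows may wrap the origin.

Overlapping matches are all reported.  A self-complementary window scanned on
both strands yields two hits with different strand labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeSequence, revcomp

__all__ = [
    "IUPAC",
    "IUPACPattern",
    "MotifHit",
    "scan",
    "scan_mismatch",
    "derive_consensus",
    "find_inverted_repeats",
    "composition_fraction",
    "DODECAMER",
    "HEPTAKAIDECAMER",
]

#: Standard IUPAC nucleotide code -> base set.
IUPAC: dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_SYMBOL = {v: k for k, v in IUPAC.items()}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Canonical yeast mitochondrial mRNA 3'-UTR dodecamer (DNA, non-template
#: strand).  Cleavage produces the mature 3' end 2 nt downstream of its end.
DODECAMER = "AATAATATTCTT"

#: Default 17-base RNA-cleavage element literal.  The published element's
#: sequence is figure-only and not machine-recoverable here, so this default
#: is a synthetic stand-in with the element's length and internal cut site;
#: override it in the motif config for real-genome work.
HEPTAKAIDECAMER = "TAGTCGGTTCGAACCGA"

#: Offset of the internal cleavage site within the 17-mer: the cut falls
#: after this many motif bases (transcript orientation).
HEPTAKAIDECAMER_CUT_OFFSET = 9


@dataclass(frozen=True)
class IUPACPattern:
    """A degenerate nucleotide pattern over the 15 IUPAC codes."""

    symbols: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("empty pattern")
        bad = sorted(set(self.symbols) - set(IUPAC))
        if bad:
            raise ValueError(f"non-IUPAC symbols in pattern: {bad}")

    def __len__(self) -> int:
        return len(self.symbols)

    def reverse_complement(self) -> "IUPACPattern":
        return IUPACPattern(self.symbols.translate(_IUPAC_COMPLEMENT)[::-1],
                            name=f"{self.name}_rc" if self.name else "")

    def matches(self, seq: str) -> bool:
        """Symbol-by-symbol exact-set match against an equal-length string."""
        if len(seq) != len(self.symbols):
            return False
        return all(b in IUPAC[s] for s, b in zip(self.symbols, seq))


@dataclass(frozen=True)
class MotifHit:
    """One genome occurrence of a pattern.

    ``low``/``high`` are the 1-based inclusive match span on the plus-strand
    coordinate frame (``wraps`` marks origin-spanning hits, where ``high``
    re-enters from 1).  ``matched_sequence`` reads in motif orientation: for
    minus-strand hits it is the reverse complement of the genomic window.
    """

    pattern_name: str
    strand: str
    low: int
    high: int
    matched_sequence: str
    wraps: bool = False
    mismatches: int = 0


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.translate(str.maketrans("ACGTN", "\0\1\2\3\4")).encode("latin1"),
                         dtype=np.uint8)


def _symbol_mask(symbol: str) -> np.ndarray:
    """Length-5 bool LUT over codes A,C,G,T,N; N never matches."""
    lut = np.zeros(5, dtype=bool)
    for b in IUPAC[symbol]:
        lut[_BASE_CODE[b]] = True
    return lut


def _window_mismatches(pattern: IUPACPattern, genome: GenomeSequence) -> np.ndarray:
    """Per-window mismatch counts for every window start on the plus strand.

    Windows start at 1..L on circular genomes (wrapping past the origin) and
    at 1..L-m+1 on linear ones.
    """
    m = len(pattern)
    seq = genome.sequence
    if genome.circular:
        if m > len(seq):
            raise ValueError("pattern longer than circular genome")
        ext = seq + seq[: m - 1]
        n_windows = len(seq)
    else:
        if m > len(seq):
            raise ValueError("pattern longer than genome")
        ext = seq
        n_windows = len(seq) - m + 1
    codes = _encode(ext)
    mism = np.zeros(n_windows, dtype=np.int32)
    for c, sym in enumerate(pattern.symbols):
        mism += ~_symbol_mask(sym)[codes[c : c + n_windows]]
    return mism


def _hits_from_starts(pattern, genome, starts, strand, mismatch_counts=None):
    m = len(pattern)
    L = len(genome)
    out = []
    for s in starts:
        low = int(s) + 1
        high_lin = low + m - 1
        wraps = genome.circular and high_lin > L
        high = high_lin if not wraps else high_lin - L
        window = genome.subseq(low, m)
        matched = window if strand == "+" else revcomp(window)
        out.append(
            MotifHit(
                pattern_name=pattern.name or pattern.symbols,
                strand=strand,
                low=low,
                high=high,
                matched_sequence=matched,
                wraps=wraps,
                mismatches=0 if mismatch_counts is None else int(mismatch_counts[s]),
            )
        )
    return out


def scan(pattern: IUPACPattern, genome: GenomeSequence,
         strands: tuple = ("+",)) -> list[MotifHit]:
    """All occurrences of ``pattern`` in ``genome`` on the requested strands.

    Plus-strand-only by default (promoter and ori models are defined on the
    non-template strand); pass ``("+", "-")`` for both.  Hits are sorted by
    ascending ``low`` with '+' before '-' at ties.
    """
    hits: list[MotifHit] = []
    if "+" in strands:
        mism = _window_mismatches(pattern, genome)
        hits += _hits_from_starts(pattern, genome, np.nonzero(mism == 0)[0], "+")
    if "-" in strands:
        mism = _window_mismatches(pattern.reverse_complement(), genome)
        hits += _hits_from_starts(pattern, genome, np.nonzero(mism == 0)[0], "-")
    hits.sort(key=lambda h: (h.low, h.strand != "+"))
    return hits


def scan_mismatch(pattern: IUPACPattern, genome: GenomeSequence,
                  max_mismatch: int, strands: tuple = ("+",)) -> list[MotifHit]:
    """Occurrences with up to ``max_mismatch`` symbol mismatches."""
    hits: list[MotifHit] = []
    if "+" in strands:
        mism = _window_mismatches(pattern, genome)
        starts = np.nonzero(mism <= max_mismatch)[0]
        hits += _hits_from_starts(pattern, genome, starts, "+", mism)
    if "-" in strands:
        mism = _window_mismatches(pattern.reverse_complement(), genome)
        starts = np.nonzero(mism <= max_mismatch)[0]
        hits += _hits_from_starts(pattern, genome, starts, "-", mism)
    hits.sort(key=lambda h: (h.low, h.strand != "+"))
    return hits


def derive_consensus(aligned: list[str], name: str = "consensus") -> IUPACPattern:
    """Per-column minimal IUPAC consensus of equal-length ungapped sequences.

    Each output symbol covers exactly the set of bases observed in its column,
    so the consensus matches every input and no proper-subset replacement
    would.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(aligned[0])
    if length == 0:
        raise ValueError("empty sequences")
    symbols = []
    for col in range(length):
        observed = set()
        for seq in aligned:
            if len(seq) != length:
                raise ValueError("sequences differ in length")
            b = seq[col]
            if b not in "ACGT":
                raise ValueError(f"non-ACGT character {b!r} in alignment")
            observed.add(b)
        symbols.append(_SET_TO_SYMBOL[frozenset(observed)])
    return IUPACPattern("".join(symbols), name=name)


def find_inverted_repeats(genome: GenomeSequence, arm_len: int, gap_len: int,
                          region: tuple | None = None) -> list[tuple]:
    """All arm pairs where a window of ``arm_len`` is the reverse complement
    of the window starting ``gap_len`` bases after it.

    Returns ``((arm1_low, arm1_high), (arm2_low, arm2_high))`` pairs, 1-based
    inclusive, within ``region`` (default: whole genome, non-wrapping).
    """
    if arm_len < 3:
        raise ValueError("arm_len must be >= 3")
    L = len(genome)
    lo, hi = region if region is not None else (1, L)
    span = hi - lo + 1
    need = 2 * arm_len + gap_len
    if span < need:
        raise ValueError(f"region of {span} nt too small for 2*{arm_len}+{gap_len}")
    out = []
    for a1 in range(lo, hi - need + 2):
        arm1 = genome.subseq(a1, arm_len)
        a2 = a1 + arm_len + gap_len
        arm2 = genome.subseq(a2, arm_len)
        if "N" in arm1 or "N" in arm2:
            continue
        if arm2 == revcomp(arm1):
            out.append(((a1, a1 + arm_len - 1), (a2, a2 + arm_len - 1)))
    return out


def composition_fraction(genome: GenomeSequence, span: tuple, bases) -> float:
    """Fraction of positions in ``span`` (1-based inclusive, wrap-aware)
    whose base is in ``bases``."""
    low, high = span
    L = len(genome)
    length = high - low + 1 if high >= low else (L - low + 1) + high
    if length <= 0:
        raise ValueError("empty span")
    window = genome.subseq(low, length)
    allowed = set(bases)
    return sum(1 for b in window if b in allowed) / length


def hits_to_bed(hits: list[MotifHit]) -> str:
    """BED-like TSV of hits (0-based half-open, as stated in the header)."""
    lines = ["# chrom\tstart\tend\tname\tmismatches\tstrand  (0-based half-open)"]
    for h in hits:
        lines.append(f"genome\t{h.low - 1}\t{h.high if not h.wraps else h.high}\t"
                     f"{h.pattern_name}\t{h.mismatches}\t{h.strand}")
    return "\n".join(lines) + "\n"
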