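"""Coordinate system, feature model, and FASTA/GFF3 I/O for small circular genomes.

All coordinates are 1-based inclusive, matching the convention of printed
mitochondrial annotation tables.  Conversion to 0-based half-open happens only
inside the SAM adapters (:mod:`mitomap.reads`) and on BED-style export.

A feature may wrap the circular origin; wrapping is an explicit ``wraps`` flag
rather than being inferred from ``low > high``, so malformed input stays
detectable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
import gffutils
from gffutils.iterators import DataIterator

__all__ = [
    "GenomeSequence",
    "FeatureRecord",
    "TranscriptModel",
    "FEATURE_TYPES",
    "read_fasta",
    "read_gff3",
    "write_gff3",
    "feature_length",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Feature classes understood by the pipeline (GFF3 column 3).
FEATURE_TYPES = frozenset(
    {
        "gene",
        "tRNA",
        "rRNA",
        "intron",
        "orf",
        "promoter",
        "ori",
        "dodecamer",
        "heptakaidecamer",
        "primary_transcript",
        "mirror",
    }
)

_VALID_SEQ = re.compile(r"^[ACGTN]+$")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A nucleotide sequence, optionally circular.

    Positions are 1-based.  On a circular genome any integer position is
    meaningful through modular arithmetic, so windows may span the origin.
    """

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty genome sequence")
        if not _VALID_SEQ.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"non-nucleotide characters in sequence: {bad}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos`` (modular on circular genomes)."""
        n = len(self.sequence)
        if self.circular:
            return self.sequence[(pos - 1) % n]
        if not 1 <= pos <= n:
            raise IndexError(f"position {pos} outside linear genome of length {n}")
        return self.sequence[pos - 1]

    def subseq(self, low: int, length: int) -> str:
        """``length`` bases starting at 1-based ``low``, wrapping if circular."""
        n = len(self.sequence)
        if length < 0:
            raise ValueError("negative length")
        if self.circular:
            start = (low - 1) % n
            doubled = self.sequence + self.sequence
            if length > n:
                raise ValueError("window longer than circular genome")
            return doubled[start : start + length]
        if low < 1 or low + length - 1 > n:
            raise IndexError(f"window {low}+{length} outside linear genome")
        return self.sequence[low - 1 : low - 1 + length]


@dataclass
class FeatureRecord:
    """A located, stranded genomic feature.

    ``low``/``high`` are 1-based inclusive.  Catalog entries whose coordinates
    are unknown (e.g. bundled reference genes without printed positions) carry
    ``low = high = None``.  ``wraps`` marks features spanning the circular
    origin, in which case ``low > high`` is permitted.
    """

    feature_id: str
    ftype: str
    strand: str
    low: Optional[int] = None
    high: Optional[int] = None
    wraps: bool = False
    parent_id: Optional[str] = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if (self.low is None) != (self.high is None):
            raise ValueError("low and high must both be set or both be None")
        if self.low is not None:
            if self.low < 1 or self.high < 1:
                raise ValueError("coordinates are 1-based; must be >= 1")
            if self.low > self.high and not self.wraps:
                raise ValueError(
                    f"{self.feature_id}: low {self.low} > high {self.high} "
                    "without wrap flag"
                )

    @property
    def located(self) -> bool:
        return self.low is not None

    def five_prime(self) -> int:
        """Transcript-orientation 5' end (for strand '-', this is ``high``)."""
        if not self.located:
            raise ValueError(f"{self.feature_id} has no coordinates")
        return self.low if self.strand == "+" else self.high

    def three_prime(self) -> int:
        """Transcript-orientation 3' end (for strand '-', this is ``low``)."""
        if not self.located:
            raise ValueError(f"{self.feature_id} has no coordinates")
        return self.high if self.strand == "+" else self.low


@dataclass
class TranscriptModel:
    """A primary transcript: a promoter, its +1, and ordered member features."""

    transcript_id: str
    promoter_id: str
    tss: int
    strand: str
    member_feature_ids: list
    mature_end_rule: str = "open"  # dodecamer_plus2 | terminal_tRNA | heptakaidecamer | open


def feature_length(f: FeatureRecord, genome: GenomeSequence) -> int:
    """Feature length in nt; wrap-aware on circular genomes."""
    if not f.located:
        raise ValueError(f"{f.feature_id} has no coordinates")
    if not f.wraps:
        return f.high - f.low + 1
    if not genome.circular:
        raise ValueError("wrapping feature on a linear genome")
    return (len(genome) - f.low + 1) + f.high


def read_fasta(path, record_id: Optional[str] = None, circular: bool = True) -> GenomeSequence:
    """Read one record from a FASTA file as a :class:`GenomeSequence`.

    ``record_id`` selects one record from a multi-FASTA; by default the first
    record is used.  Sequence is uppercased; characters outside ACGTN raise.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is None:
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ValueError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    return GenomeSequence(id=rec.id, sequence=str(rec.seq).upper(), circular=circular)


_GFF_SOURCE = "mitomap"


def write_gff3(features: Iterable[FeatureRecord], path, seqid: str = "genome") -> None:
    """Write features as GFF3 (1-based inclusive, as GFF3 mandates).

    Wrapping features are written with their literal low/high plus a
    ``wraps=true`` attribute; coordinate-less catalog entries are rejected.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            if not f.located:
                raise ValueError(f"cannot write coordinate-less feature {f.feature_id}")
            attrs = {"ID": [f.feature_id]}
            if f.parent_id:
                attrs["Parent"] = [f.parent_id]
            if f.wraps:
                attrs["wraps"] = ["true"]
            for k, v in f.attributes.items():
                attrs[k] = [str(v)]
            # GFF3 requires start <= end; a wrapping feature stores low/high
            # verbatim in attributes and low..low in columns to stay parseable.
            start, end = (f.low, f.high) if not f.wraps else (f.low, f.low)
            if f.wraps:
                attrs["wrap_low"] = [str(f.low)]
                attrs["wrap_high"] = [str(f.high)]
            gf = gffutils.Feature(
                seqid=seqid,
                source=_GFF_SOURCE,
                featuretype=f.ftype,
                start=start,
                end=end,
                strand=f.strand,
                frame=".",
                attributes=attrs,
            )
            fh.write(str(gf) + "\n")


def read_gff3(path, genome_length: Optional[int] = None) -> list[FeatureRecord]:
    """Read a GFF3 file into :class:`FeatureRecord` objects.

    Round-trips everything :func:`write_gff3` emits.  ``genome_length``, when
    given, bounds-checks coordinates.
    """
    out: list[FeatureRecord] = []
    for gf in DataIterator(str(path)):
        if gf.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {gf.strand!r} in {path}")
        attrs = {k: v[0] for k, v in gf.attributes.items()}
        fid = attrs.pop("ID", f"{gf.featuretype}:{gf.start}-{gf.end}")
        parent = attrs.pop("Parent", None)
        wraps = attrs.pop("wraps", "false") == "true"
        if wraps:
            low = int(attrs.pop("wrap_low"))
            high = int(attrs.pop("wrap_high"))
        else:
            low, high = gf.start, gf.end
        if genome_length is not None:
            for c in (low, high):
                if not 1 <= c <= genome_length:
                    raise ValueError(
                        f"coordinate {c} outside genome of length {genome_length}"
                    )
        out.append(
            FeatureRecord(
                feature_id=fid,
                ftype=gf.featuretype,
                strand=gf.strand,
                low=low,
                high=high,
                wraps=wraps,
                parent_id=parent,
                attributes=attrs,
            )
        )
    return out
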