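"""Synthetic circular genomes with planted features, and directional
processed-RNA read simulation with known truth.

The generator emulates the architecture of a small, A/T-rich organelle
genome: consensus promoters with an adenosine +1, five-part origins of
replication (active, and inactive with a GC insert disrupting the promoter),
tRNA genes with perfect 7-bp acceptor stems and no genome-templated CCA,
ORFs ending UAA with a dodecamer 2 nt upstream of the mature 3' end, an
RNase-P-like non-coding transcript cut internally at a heptakaidecamer, one
intron-containing gene with a minor alternative splice form, and low-level
antisense "mirror" transcripts.

Reads are written as alignments directly from provenance (no aligner): each
simulated RNA molecule is fragmented into consecutive pieces of 30-300 nt,
and only the 5' mate of each fragment is emitted as a 101-nt directional
read.  Non-genomic CCA tails and junction overhangs appear as soft-clips.
Because every molecule copy yields one piece starting at its 5' terminus and
one ending at its 3' terminus, processing sites show the read-end stacking
that the callers look for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeSequence, FeatureRecord, revcomp, write_gff3
from .motifs import (DODECAMER, HEPTAKAIDECAMER, HEPTAKAIDECAMER_CUT_OFFSET,
                     IUPACPattern, scan)
from .promoters import scan_promoters, DEFAULT_CONSENSUS
from .s288c import PROMOTER_TABLE

__all__ = ["SimConfig", "TranscriptSpec", "Molecule", "SyntheticTruth",
           "build_genome", "transcribe_and_process", "simulate_reads",
           "simulate_sample", "SIM_G_RICH"]

#: Synthetic G-rich ori element used by the generator (16/17 G).
SIM_G_RICH = "GGGGGGGGTGGGGGGGG"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome and read simulation."""

    seed: int = 0
    genome_length: int = 30000
    # transcription units: mRNA genes plus one rRNA, one ncRNA, and one
    # tRNA-cluster unit (libraries are rRNA-dominated: no rRNA subtraction)
    n_gene_promoters: int = 6
    n_ori_active: int = 2
    n_ori_inactive: int = 2
    n_trnas: int = 6
    n_introns: int = 1
    intron_length: int = 800       # group I/II introns are kilobase-scale
    n_unexpressed_heptakaidecamers: int = 3
    dodecamer: str = DODECAMER
    heptakaidecamer: str = HEPTAKAIDECAMER
    heptakaidecamer_cut_offset: int = HEPTAKAIDECAMER_CUT_OFFSET
    g_rich: str = SIM_G_RICH
    ori_insert_length: int = 35
    ori_insert_offset: int = 8     # promoter column after which the insert sits
    read_length: int = 101
    insert_range: tuple = (30, 300)
    depth: float = 1000.0          # mean reads per expressed kilobase (abundance 1)
    noise: float = 0.005           # per-base substitution rate
    antisense_fraction: float = 0.02
    alt_splice_fraction: float = 0.2
    condition_b_multipliers: dict = field(
        default_factory=lambda: {"intron": 4.0, "mirror": 4.0})
    at_fraction: float = 0.80      # background A+T composition


@dataclass
class TranscriptSpec:
    """A mature RNA species with known provenance and base abundance.

    ``blocks`` are genomic (low, high) spans in transcript order; ``tail`` is
    a non-genomic 3' extension (the tRNA CCA).
    """

    transcript_id: str
    strand: str
    blocks: list
    abundance: float
    category: str          # mRNA | tRNA | intron | mirror | ncRNA | fragment | ori_rna
    tail: str = ""

    def length(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.blocks) + len(self.tail)


Molecule = TranscriptSpec  # a condition-resolved transcript is the same shape


@dataclass
class SyntheticTruth:
    """Everything the simulator planted, for closure testing."""

    genome: GenomeSequence
    features: list
    transcripts: list
    cleavage_sites: list            # (strand, cut_after) genomic
    trna_ends: dict                 # trna_id -> (five_prime, three_prime)
    promoter_tss: list              # (tss, strand) of every intact planted promoter
    config: SimConfig = None

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fasta"
        SeqIO.write([SeqRecord(Seq(self.genome.sequence), id=self.genome.id,
                               description="synthetic circular genome")],
                    str(fasta), "fasta")
        gff = outdir / "features.gff3"
        write_gff3(self.features, gff, seqid=self.genome.id)
        return {"fasta": fasta, "gff3": gff}


def _background(rng, n: int, at: float) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class _Unit:
    """A transcription unit assembled in transcript space, then planted on
    either strand.  Records named anchors (points) and spans as unit-local
    offsets (0-based) and converts them to genomic coordinates."""

    def __init__(self) -> None:
        self.seq = ""
        self.anchors: dict[str, int] = {}
        self.spans: dict[str, tuple] = {}

    def add(self, seq: str, name: Optional[str] = None) -> tuple:
        start = len(self.seq)
        self.seq += seq
        if name:
            self.spans[name] = (start, len(self.seq) - 1)
        return start, len(self.seq) - 1

    def mark(self, name: str, offset: int) -> None:
        self.anchors[name] = offset

    def genomic_pos(self, offset: int, g0: int, strand: str) -> int:
        return g0 + offset if strand == "+" else g0 + (len(self.seq) - 1 - offset)

    def genomic_span(self, span: tuple, g0: int, strand: str) -> tuple:
        a = self.genomic_pos(span[0], g0, strand)
        b = self.genomic_pos(span[1], g0, strand)
        return (a, b) if a <= b else (b, a)

    def planted_seq(self, strand: str) -> str:
        return self.seq if strand == "+" else revcomp(self.seq)


_GENE_WINDOWS = [w for _, w, s in PROMOTER_TABLE if s == "gene"]
_ORI_WINDOWS = [w for _, w, s in PROMOTER_TABLE if s == "ori"]


def _promoter_unit(window: str) -> _Unit:
    u = _Unit()
    u.add(window, "promoter_window")
    u.mark("tss", 12)  # +1 is window offset 13 (1-based)
    return u


def _mrna_unit(rng, cfg: SimConfig, window: str, orf_len: int,
               intron_len: int = 0) -> _Unit:
    """Promoter + 5'UTR + ORF (optionally intron-containing) + 3'UTR +
    dodecamer + 2 nt; the mature 3' end is dodecamer end + 2."""
    u = _promoter_unit(window)
    u.add(_background(rng, 25, cfg.at_fraction))          # 5' UTR beyond +8
    u.add("ATG")
    body_len = orf_len - 6
    if intron_len:
        half = body_len // 2
        u.add(_background(rng, half, cfg.at_fraction))
        ist, ien = u.add(_background(rng, intron_len, cfg.at_fraction), "intron")
        # first exon-2 base must not be C (junction overhang clips must not
        # mimic CCA evidence)
        u.add("A" + _background(rng, body_len - half - 1, cfg.at_fraction))
    else:
        u.add(_background(rng, body_len, cfg.at_fraction))
    u.add("TAA")
    u.add(_background(rng, 20, cfg.at_fraction))          # 3' UTR
    u.add(cfg.dodecamer, "dodecamer")
    u.add(_background(rng, 2, cfg.at_fraction))
    u.mark("mature_end", len(u.seq) - 1)
    u.add(_background(rng, 15, cfg.at_fraction))          # read-through, unstable
    return u


def _trna_cluster_unit(rng, cfg: SimConfig, window: str, n_trnas: int) -> _Unit:
    u = _promoter_unit(window)
    u.add(_background(rng, 30, cfg.at_fraction))
    for i in range(n_trnas):
        arm5 = "".join(rng.choice(list("ACGT"), size=7))
        body = _background(rng, 57, cfg.at_fraction)
        trna = arm5 + body + revcomp(arm5) + "A"          # discriminator A, 72 nt
        u.add(trna, f"trna_{i}")
        u.add("TT" + _background(rng, 28, cfg.at_fraction))  # no templated CCA
    return u


def _rrna_unit(rng, cfg: SimConfig, window: str, length: int = 1500) -> _Unit:
    """A highly expressed rRNA-style transcript; it dominates the library the
    way unsubtracted rRNA dominates real directional libraries."""
    u = _promoter_unit(window)
    tss = u.anchors["tss"]
    u.add(_background(rng, length - (len(u.seq) - tss), cfg.at_fraction))
    u.mark("transcript_end", len(u.seq) - 1)
    u.add(_background(rng, 15, cfg.at_fraction))
    return u


def _ncrna_unit(rng, cfg: SimConfig, window: str) -> _Unit:
    """An RNase-P-like 483-nt transcript with an internal heptakaidecamer;
    the cut separates a 5' fragment from the 3' remainder."""
    u = _promoter_unit(window)
    tss = u.anchors["tss"]
    u.add(_background(rng, 80 - (len(u.seq) - tss), cfg.at_fraction))
    hst, hen = u.add(cfg.heptakaidecamer, "heptakaidecamer")
    u.mark("cut", hst + cfg.heptakaidecamer_cut_offset - 1)
    u.add(_background(rng, 483 - (len(u.seq) - tss), cfg.at_fraction))
    u.mark("transcript_end", len(u.seq) - 1)
    u.add(_background(rng, 15, cfg.at_fraction))
    return u


def _ori_unit(rng, cfg: SimConfig, window: str, insert_len: int = 0,
              insert_offset: int = 8) -> _Unit:
    u = _Unit()
    if insert_len:
        gc = "".join(rng.choice(list("GC"), size=insert_len))
        u.add(window[:insert_offset])
        u.add(gc, "insert")
        u.add(window[insert_offset:])
        u.spans["promoter_window"] = (0, 20 + insert_len - 1)
    else:
        u.add(window, "promoter_window")
        u.mark("tss", 12)
    u.add(_background(rng, 4, cfg.at_fraction))
    u.add(cfg.g_rich, "g_rich")
    spacer = "".join(rng.choice(list("AT"), size=200))
    u.add(spacer, "spacer")
    arm1 = "".join(rng.choice(list("GC"), size=7))
    u.add(arm1, "arm1")
    u.add("".join(rng.choice(list("AT"), size=29)), "arm_gap")
    u.add(revcomp(arm1), "arm2")
    if not insert_len:
        u.add(_background(rng, 80, cfg.at_fraction))
        u.mark("transcript_end", len(u.seq) - 1)
    return u


def _ori_unit_clean(rng, cfg, window, insert_len=0, insert_offset=8,
                    max_tries: int = 50) -> _Unit:
    """Rejection-sample the ori unit so the planted hairpin is the unique
    arm pair in the searched spacer-length window (150-260 nt)."""
    for _ in range(max_tries):
        u = _ori_unit(rng, cfg, window, insert_len, insert_offset)
        g_end = u.spans["g_rich"][1]
        true_sp = u.spans["arm1"][0] - g_end - 1
        ok = True
        for sp in range(150, 261):
            if sp == true_sp:
                continue
            a1 = g_end + 1 + sp
            a2 = a1 + 7 + 29
            if a2 + 7 <= len(u.seq) and u.seq[a2:a2 + 7] == revcomp(u.seq[a1:a1 + 7]):
                ok = False
                break
        if ok:
            return u
    raise RuntimeError("could not build a clean ori unit")


def build_genome(config: SimConfig = SimConfig()) -> SyntheticTruth:
    """Assemble the synthetic genome and its complete truth record.

    Units are separated by random A/T-biased background.  After assembly the
    genome is validated: planted promoters are the only consensus matches and
    planted heptakaidecamers the only occurrences of that literal; otherwise
    the build retries with a derived seed (bounded).
    """
    for attempt in range(20):
        rng = np.random.default_rng((config.seed + 7919 * attempt) % 2**31)
        try:
            truth = _build_once(rng, config)
        except _Spurious:
            continue
        return truth
    raise RuntimeError("placement failed after bounded retries")


class _Spurious(Exception):
    pass


def _build_once(rng, cfg: SimConfig) -> SyntheticTruth:
    n_special = min(3, cfg.n_gene_promoters)
    n_mrna = max(0, cfg.n_gene_promoters - n_special)
    if cfg.n_introns > max(1, n_mrna):
        raise ValueError("more introns than intron-capable genes supported")

    parts: list[tuple] = []   # (unit, strand, kind, index)
    for i in range(n_mrna):
        window = _GENE_WINDOWS[i % len(_GENE_WINDOWS)]
        strand = "-" if i == 1 and n_mrna > 1 else "+"
        intron = cfg.intron_length if i < cfg.n_introns else 0
        orf = int(rng.integers(420, 900)) // 3 * 3
        parts.append((_mrna_unit(rng, cfg, window, orf, intron), strand, "mrna", i))
    special = ["trna_cluster", "ncrna", "rrna"][:n_special]
    for j, kind in enumerate(special):
        window = _GENE_WINDOWS[(n_mrna + j) % len(_GENE_WINDOWS)]
        if kind == "trna_cluster":
            parts.append((_trna_cluster_unit(rng, cfg, window, cfg.n_trnas),
                          "+", kind, 0))
        elif kind == "ncrna":
            parts.append((_ncrna_unit(rng, cfg, window), "+", kind, 0))
        else:
            parts.append((_rrna_unit(rng, cfg, window), "+", kind, 0))
    for i in range(cfg.n_ori_active):
        parts.append((_ori_unit_clean(rng, cfg, _ORI_WINDOWS[i % len(_ORI_WINDOWS)]),
                      "+", "ori_active", i))
    for i in range(cfg.n_ori_inactive):
        parts.append((_ori_unit_clean(rng, cfg, _ORI_WINDOWS[(i + 1) % len(_ORI_WINDOWS)],
                                      cfg.ori_insert_length, cfg.ori_insert_offset),
                      "+", "ori_inactive", i))
    for i in range(cfg.n_unexpressed_heptakaidecamers):
        u = _Unit()
        u.add(cfg.heptakaidecamer, "heptakaidecamer")
        parts.append((u, "+", "hepta_unexpressed", i))

    order = rng.permutation(len(parts))
    seq_chunks = []
    pos = 0
    placements = []   # (g0, unit, strand, kind, index)
    for k in order:
        unit, strand, kind, idx = parts[k]
        gap = int(rng.integers(200, 500))
        seq_chunks.append(_background(rng, gap, cfg.at_fraction))
        pos += gap
        g0 = pos + 1   # 1-based genomic start of the planted unit
        seq_chunks.append(unit.planted_seq(strand))
        placements.append((g0, unit, strand, kind, idx))
        pos += len(unit.seq)
    if pos > cfg.genome_length - 200:
        raise RuntimeError(f"planted content ({pos} nt) exceeds genome_length")
    seq_chunks.append(_background(rng, cfg.genome_length - pos, cfg.at_fraction))
    genome = GenomeSequence("synthetic_mt", "".join(seq_chunks), circular=True)

    features: list[FeatureRecord] = []
    transcripts: list[TranscriptSpec] = []
    cleavage_sites: list[tuple] = []
    trna_ends: dict = {}
    promoter_tss: list[tuple] = []
    n_hepta_planted = 0

    def gpos(u, name, g0, strand):
        return u.genomic_pos(u.anchors[name], g0, strand)

    def gspan(u, name, g0, strand):
        return u.genomic_span(u.spans[name], g0, strand)

    for g0, u, strand, kind, idx in placements:
        if kind in ("mrna", "ncrna", "trna_cluster", "rrna"):
            wlo, whi = gspan(u, "promoter_window", g0, strand)
            tss = gpos(u, "tss", g0, strand)
            promoter_tss.append((tss, strand))
            features.append(FeatureRecord(
                f"promoter_{kind}_{idx}", "promoter", strand, wlo, whi,
                attributes={"tss": str(tss), "serves": "gene"}))
        if kind == "mrna":
            mend = gpos(u, "mature_end", g0, strand)
            tss = gpos(u, "tss", g0, strand)
            glo, ghi = (tss, mend) if strand == "+" else (mend, tss)
            gid = f"gene_{idx}"
            features.append(FeatureRecord(gid, "gene", strand, glo, ghi))
            features.append(FeatureRecord(f"mirror_{gid}", "mirror",
                                          "-" if strand == "+" else "+",
                                          glo, ghi, parent_id=gid))
            dlo, dhi = gspan(u, "dodecamer", g0, strand)
            features.append(FeatureRecord(f"dodecamer_{gid}", "dodecamer", strand,
                                          dlo, dhi, parent_id=gid))
            ab = 1.0
            if "intron" in u.spans:
                ilo, ihi = gspan(u, "intron", g0, strand)
                features.append(FeatureRecord(f"intron_{gid}", "intron", strand,
                                              ilo, ihi, parent_id=gid))
                if strand == "+":
                    blocks = [(tss, ilo - 1), (ihi + 1, mend)]
                    alt_blocks = [(tss, ilo + 29), (ihi + 1, mend)]
                else:
                    blocks = [(ihi + 1, tss), (mend, ilo - 1)]
                    alt_blocks = [(ihi - 29, tss), (mend, ilo - 1)]
                f = cfg.alt_splice_fraction
                transcripts.append(TranscriptSpec(gid, strand, blocks, ab * (1 - f), "mRNA"))
                transcripts.append(TranscriptSpec(f"{gid}_alt", strand, alt_blocks,
                                                  ab * f, "mRNA"))
                # free introns decay fast; steady state sits below the host
                transcripts.append(TranscriptSpec(f"intron_{gid}", strand,
                                                  [(ilo, ihi)], 0.5, "intron"))
                # intron excision creates processing boundaries on both sides
                if strand == "+":
                    cleavage_sites.extend([(strand, ilo - 1), (strand, ihi)])
                else:
                    cleavage_sites.extend([(strand, ihi + 1), (strand, ilo)])
                features.append(FeatureRecord(f"mirror_intron_{gid}", "mirror",
                                              "-" if strand == "+" else "+",
                                              ilo, ihi, parent_id=f"intron_{gid}"))
            else:
                transcripts.append(TranscriptSpec(gid, strand, [(glo, ghi)] if strand == "+"
                                                  else [(glo, ghi)], ab, "mRNA"))
            transcripts.append(TranscriptSpec(f"mirror_{gid}",
                                              "-" if strand == "+" else "+",
                                              [(glo, ghi)], cfg.antisense_fraction, "mirror"))
        elif kind == "rrna":
            tss = gpos(u, "tss", g0, strand)
            tend = gpos(u, "transcript_end", g0, strand)
            features.append(FeatureRecord("rRNA", "rRNA", strand, tss, tend))
            transcripts.append(TranscriptSpec("rRNA", strand, [(tss, tend)],
                                              8.0, "rRNA"))
        elif kind == "ncrna":
            tss = gpos(u, "tss", g0, strand)
            cut = gpos(u, "cut", g0, strand)
            tend = gpos(u, "transcript_end", g0, strand)
            hlo, hhi = gspan(u, "heptakaidecamer", g0, strand)
            n_hepta_planted += 1
            features.append(FeatureRecord("ncRNA", "gene", strand, tss, tend))
            features.append(FeatureRecord("hepta_ncRNA", "heptakaidecamer", strand,
                                          hlo, hhi,
                                          attributes={"expressed": "true",
                                                      "cut_after": str(cut)}))
            cleavage_sites.append((strand, cut))
            transcripts.append(TranscriptSpec("ncRNA_precursor", strand,
                                              [(tss, tend)], 0.1, "ncRNA"))
            transcripts.append(TranscriptSpec("ncRNA_frag5", strand,
                                              [(tss, cut)], 1.0, "fragment"))
            transcripts.append(TranscriptSpec("ncRNA_frag3", strand,
                                              [(cut + 1, tend)], 1.0, "fragment"))
        elif kind == "trna_cluster":
            for i in range(cfg.n_trnas):
                tlo, thi = gspan(u, f"trna_{i}", g0, strand)
                tid = f"trna_{i}"
                features.append(FeatureRecord(tid, "tRNA", strand, tlo, thi))
                features.append(FeatureRecord(f"mirror_{tid}", "mirror",
                                              "-" if strand == "+" else "+",
                                              tlo, thi, parent_id=tid))
                five = tlo if strand == "+" else thi
                three = thi if strand == "+" else tlo
                trna_ends[tid] = (five, three)
                transcripts.append(TranscriptSpec(tid, strand, [(tlo, thi)], 3.0,
                                                  "tRNA", tail="CCA"))
                transcripts.append(TranscriptSpec(f"mirror_{tid}",
                                                  "-" if strand == "+" else "+",
                                                  [(tlo, thi)],
                                                  cfg.antisense_fraction, "mirror"))
        elif kind in ("ori_active", "ori_inactive"):
            wlo, whi = gspan(u, "promoter_window", g0, strand)
            a2lo, a2hi = gspan(u, "arm2", g0, strand)
            status = "active" if kind == "ori_active" else "inactive"
            attrs = {"status": status}
            if status == "inactive":
                attrs["insert_length"] = str(cfg.ori_insert_length)
                attrs["insert_offset"] = str(cfg.ori_insert_offset)
            else:
                tss = gpos(u, "tss", g0, strand)
                attrs["tss"] = str(tss)
                promoter_tss.append((tss, strand))
                tend = gpos(u, "transcript_end", g0, strand)
                transcripts.append(TranscriptSpec(f"ori_rna_{idx}", strand,
                                                  [(tss, tend)], 0.5, "ori_rna"))
            features.append(FeatureRecord(f"ori_{status}_{idx}", "ori", strand,
                                          min(wlo, a2lo), max(whi, a2hi),
                                          attributes=attrs))
        elif kind == "hepta_unexpressed":
            hlo, hhi = gspan(u, "heptakaidecamer", g0, strand)
            n_hepta_planted += 1
            features.append(FeatureRecord(f"hepta_bg_{idx}", "heptakaidecamer",
                                          strand, hlo, hhi,
                                          attributes={"expressed": "false"}))

    # validation: planted promoters are the only consensus matches
    hits = scan_promoters(genome, strands=("+", "-"))
    found = {(h.tss, h.strand) for h in hits}
    if found != set(promoter_tss):
        raise _Spurious
    hepta = scan(IUPACPattern(cfg.heptakaidecamer, "heptakaidecamer"), genome,
                 strands=("+",))
    if len(hepta) != n_hepta_planted:
        raise _Spurious

    return SyntheticTruth(genome=genome, features=features, transcripts=transcripts,
                          cleavage_sites=cleavage_sites, trna_ends=trna_ends,
                          promoter_tss=sorted(promoter_tss), config=cfg)


def transcribe_and_process(truth: SyntheticTruth, condition: str = "a") -> list[Molecule]:
    """Condition-resolved mature RNA molecules.

    Condition "b" multiplies the abundance of intron and mirror species by
    the configured factors; everything else is unchanged.
    """
    if condition not in ("a", "b"):
        raise ValueError("condition must be 'a' or 'b'")
    mult = truth.config.condition_b_multipliers if condition == "b" else {}
    out = []
    for t in truth.transcripts:
        m = mult.get(t.category, 1.0) if condition == "b" else 1.0
        out.append(replace(t, abundance=t.abundance * m))
    return out


def _molecule_sequence(mol: Molecule, genome: GenomeSequence) -> str:
    seq = []
    for lo, hi in mol.blocks:
        s = genome.subseq(lo, hi - lo + 1)
        seq.append(s if mol.strand == "+" else revcomp(s))
    return "".join(seq) + mol.tail


#: mean fragment length under uniform 30-300 fragmentation of long molecules
_MEAN_PIECE = 165.0
_MIN_PIECE = 15


def simulate_reads(molecules: list[Molecule], genome: GenomeSequence,
                   config: SimConfig, outdir, sample_name: str = "sample",
                   rng=None) -> dict:
    """Fragment molecules and write 5'-mate reads as SAM + FASTQ + truth TSV.

    Each molecule copy is cut into consecutive pieces with lengths uniform in
    ``insert_range``; the 5' mate read covers the first ``read_length`` bases
    of each piece.  Alignments are emitted from provenance: non-genomic tails
    and splice-junction overhangs are soft-clipped.  Copy numbers are Poisson
    with mean ``depth x abundance x (mean piece length)/1000`` so that read
    output matches ``depth`` reads per expressed kilobase at unit abundance.
    """
    if not molecules:
        raise ValueError("no molecules to sequence")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sam_path = outdir / f"{sample_name}.sam"
    fastq_path = outdir / f"{sample_name}.fastq"
    truth_path = outdir / f"{sample_name}.truth.tsv"

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": genome.id, "LN": len(genome)}]}
    lo_ins, hi_ins = config.insert_range
    fastq_records = []
    truth_rows = ["read_id\tmolecule_id\tcategory"]
    n_read = 0
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:
        for mol in molecules:
            # transcript-oriented sequence per block; the non-genomic tail
            # rides on the last block.  Fragmentation is per block, so no
            # read spans a splice junction (keeps alignments gap-free).
            block_seqs = []
            for k, (lo, hi) in enumerate(mol.blocks):
                s = genome.subseq(lo, hi - lo + 1)
                if mol.strand == "-":
                    s = revcomp(s)
                if k == len(mol.blocks) - 1:
                    s += mol.tail
                block_seqs.append(s)
            n_copies = rng.poisson(config.depth * mol.abundance * _MEAN_PIECE / 1000.0)
            for _ in range(n_copies):
                for bi, bseq in enumerate(block_seqs):
                    lo, hi = mol.blocks[bi]
                    block_len = hi - lo + 1          # genomic part only
                    blen = len(bseq)
                    cuts = [0]
                    while cuts[-1] < blen:
                        cuts.append(min(blen, cuts[-1] + int(rng.integers(lo_ins, hi_ins + 1))))
                    for ps, pe in zip(cuts[:-1], cuts[1:]):
                        plen = pe - ps
                        if plen < _MIN_PIECE:
                            continue
                        rlen = min(config.read_length, plen)
                        read = list(bseq[ps : ps + rlen])
                        if config.noise > 0:
                            errs = np.nonzero(rng.random(rlen) < config.noise)[0]
                            for e in errs:
                                read[e] = rng.choice([b for b in "ACGT" if b != read[e]])
                        read = "".join(read)
                        off = ps
                        if off >= block_len:
                            continue  # piece entirely inside the non-genomic tail
                        m = min(rlen, block_len - off)
                        clip = rlen - m
                        if mol.strand == "+":
                            ref_low = lo + off
                        else:
                            ref_high = hi - off
                            ref_low = ref_high - m + 1
                        n_read += 1
                        qname = f"{sample_name}_r{n_read}"
                        a = pysam.AlignedSegment()
                        a.query_name = qname
                        a.reference_id = 0
                        a.reference_start = ref_low - 1
                        a.mapping_quality = 60
                        if mol.strand == "+":
                            a.flag = 0
                            a.query_sequence = read
                            a.cigarstring = f"{m}M{clip}S" if clip else f"{m}M"
                        else:
                            a.flag = 16
                            a.query_sequence = revcomp(read)
                            a.cigarstring = f"{clip}S{m}M" if clip else f"{m}M"
                        a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
                        sam.write(a)
                        fastq_records.append(
                            SeqRecord(Seq(read), id=qname, description="",
                                      letter_annotations={"phred_quality": [40] * rlen}))
                        truth_rows.append(f"{qname}\t{mol.transcript_id}\t{mol.category}")
    SeqIO.write(fastq_records, str(fastq_path), "fastq")
    truth_path.write_text("\n".join(truth_rows) + "\n")
    return {"sam": sam_path, "fastq": fastq_path, "truth": truth_path,
            "n_reads": n_read}


def simulate_sample(truth: SyntheticTruth, condition: str, outdir,
                    sample_name: str, seed: int) -> dict:
    """Convenience: transcribe under a condition and sequence one sample."""
    mols = transcribe_and_process(truth, condition)
    rng = np.random.default_rng(seed % 2**31)
    return simulate_reads(mols, truth.genome, truth.config, outdir,
                          sample_name=sample_name, rng=rng)
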