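"""End-to-end orchestration: genome in, transcriptome-map tables out.

A run scans promoters and ori, scans the configured 3'-end motifs, builds
end pileups from each sample's alignments, calls tRNA boundaries and
cleavage sites, quantifies sense/antisense RPKM per feature, and (with two
conditions) runs the permutation comparison.  Every threshold that affects
output is recorded in the run manifest, and identical config + inputs +
seed give identical report contents.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from . import __version__
from .genome import GenomeSequence, read_fasta, read_gff3, write_gff3, FeatureRecord
from .motifs import (IUPACPattern, scan, DODECAMER, HEPTAKAIDECAMER,
                     HEPTAKAIDECAMER_CUT_OFFSET)
from .promoters import (scan_promoters, detect_ori, assign_promoters, OriParams,
                        DEFAULT_CONSENSUS)
from .reads import (StrandLibrary, load_alignments, build_end_pileup,
                    call_trna_3prime, infer_trna_5prime, call_cleavage_sites,
                    strand_coverage)
from .quantify import quantify, compare, report_map

__all__ = ["SampleConfig", "PipelineConfig", "run_map"]

logger = logging.getLogger(__name__)


@dataclass
class SampleConfig:
    name: str
    condition: str            # "a" or "b"
    alignments: str           # SAM/BAM path


@dataclass
class PipelineConfig:
    """Declarative run configuration (JSON-serialisable)."""

    genome: str
    annotation: Optional[str] = None
    samples: list = field(default_factory=list)      # SampleConfig or dicts
    output_dir: str = "mitomap_out"
    seed: int = 0
    circular: bool = True
    scan_strands: tuple = ("+",)
    dodecamer: str = DODECAMER
    heptakaidecamer: str = HEPTAKAIDECAMER
    heptakaidecamer_cut_offset: int = HEPTAKAIDECAMER_CUT_OFFSET
    g_rich_literal: Optional[str] = None
    trna_min_support: int = 5
    cleavage_min_reads: int = 20
    cleavage_min_enrichment: float = 10.0
    min_overlap: int = 1
    n_permutations: Optional[int] = None
    library_reverse: bool = False

    def __post_init__(self) -> None:
        self.samples = [SampleConfig(**s) if isinstance(s, dict) else s
                        for s in self.samples]

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        if not Path(self.genome).exists():
            raise FileNotFoundError(f"genome FASTA not found: {self.genome}")
        if self.annotation and not Path(self.annotation).exists():
            raise FileNotFoundError(f"annotation not found: {self.annotation}")
        for s in self.samples:
            if not Path(s.alignments).exists():
                raise FileNotFoundError(f"alignments not found: {s.alignments}")
        if not 0 <= self.cleavage_min_enrichment:
            raise ValueError("cleavage_min_enrichment must be >= 0")


def _motif_cuts(cfg: PipelineConfig, genome: GenomeSequence) -> tuple:
    """Scan the two 3'-end motifs and annotate their cut positions."""
    hits = []
    cuts = []
    dod = IUPACPattern(cfg.dodecamer, name="dodecamer")
    for h in scan(dod, genome, strands=("+", "-")):
        hits.append(h)
        cut = h.high + 2 if h.strand == "+" else h.low - 2
        cuts.append((f"dodecamer@{h.low}", h.strand, cut))
    hep = IUPACPattern(cfg.heptakaidecamer, name="heptakaidecamer")
    for h in scan(hep, genome, strands=("+", "-")):
        hits.append(h)
        off = cfg.heptakaidecamer_cut_offset
        cut = h.low + off - 1 if h.strand == "+" else h.high - off + 1
        cuts.append((f"heptakaidecamer@{h.low}", h.strand, cut))
    return hits, cuts


def run_map(config: PipelineConfig) -> Path:
    """Execute all stages and write reports plus a run manifest.

    Returns the output directory.  A stage failure aborts with an error
    naming the stage.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "trna_min_support": config.trna_min_support,
            "cleavage_min_reads": config.cleavage_min_reads,
            "cleavage_min_enrichment": config.cleavage_min_enrichment,
            "min_overlap": config.min_overlap,
            "n_permutations": config.n_permutations,
            "heptakaidecamer_cut_offset": config.heptakaidecamer_cut_offset,
            "scan_strands": list(config.scan_strands),
            "dodecamer": config.dodecamer,
            "heptakaidecamer": config.heptakaidecamer,
            "g_rich_literal": config.g_rich_literal,
            "library_reverse": config.library_reverse,
        },
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    try:
        st = stage("load_genome")
        genome = read_fasta(config.genome, circular=config.circular)
        st["genome_length"] = len(genome)

        features: list[FeatureRecord] = []
        if config.annotation:
            st = stage("load_annotation")
            features = read_gff3(config.annotation, genome_length=len(genome))
            st["n_features"] = len(features)

        st = stage("scan_promoters")
        promoters = scan_promoters(genome, strands=config.scan_strands)
        st["n_hits"] = len(promoters)

        st = stage("detect_ori")
        ori_params = OriParams(g_rich_literal=config.g_rich_literal)
        ori_calls = detect_ori(genome, promoters, ori_params)
        st["n_active"] = sum(1 for c in ori_calls if c.status == "active")
        st["n_inactive"] = sum(1 for c in ori_calls if c.status == "inactive")

        assign_promoters(promoters, features, ori_calls, len(genome))

        st = stage("scan_motifs")
        motif_hits, motif_cuts = _motif_cuts(config, genome)
        st["n_motif_hits"] = len(motif_hits)

        library = StrandLibrary(reverse=config.library_reverse)
        trna_regions = [f for f in features if f.ftype == "tRNA" and f.located]
        per_sample = {}
        for s in config.samples:
            st = stage(f"sample:{s.name}")
            views = load_alignments(s.alignments, library)
            st["n_reads"] = len(views)
            pileup = build_end_pileup(views, len(genome))
            trna_calls = call_trna_3prime(views, genome, trna_regions,
                                          min_support=config.trna_min_support)
            for c in trna_calls:
                c.five_prime = infer_trna_5prime(genome, c.three_prime, c.strand)
            cleavage = call_cleavage_sites(
                pileup, min_reads=config.cleavage_min_reads,
                min_enrichment=config.cleavage_min_enrichment,
                motif_cuts=motif_cuts)
            st["n_trna_calls"] = len(trna_calls)
            st["n_cleavage_calls"] = len(cleavage)
            coverage = strand_coverage(pileup)
            st["strand_coverage"] = coverage
            expression = quantify(views, features, genome,
                                  min_overlap=config.min_overlap)
            per_sample[s.name] = {
                "condition": s.condition,
                "views": views,
                "trna_calls": trna_calls,
                "cleavage": cleavage,
                "coverage": coverage,
                "expression": expression,
            }

        comparisons = []
        reps_a = [d["expression"] for d in per_sample.values() if d["condition"] == "a"]
        reps_b = [d["expression"] for d in per_sample.values() if d["condition"] == "b"]
        if reps_a and reps_b:
            st = stage("compare")
            comparisons = compare(reps_a, reps_b,
                                  n_permutations=config.n_permutations,
                                  seed=config.seed)
            st["n_features"] = len(comparisons)

        st = stage("report")
        first = next(iter(per_sample.values()), None)
        promoter_rows = [
            {"tss": p.tss, "strand": p.strand, "window_low": p.window_low,
             "window_high": p.window_high, "window_sequence": p.window_sequence,
             "nonanucleotide_ok": p.nonanucleotide_ok, "serving": p.serving}
            for p in promoters
        ]
        report_map(
            outdir,
            features=features,
            expression=first["expression"] if first else [],
            trna_calls=first["trna_calls"] if first else [],
            cleavage_calls=first["cleavage"] if first else [],
            comparisons=comparisons,
            promoter_rows=promoter_rows,
        )
        ori_feats = []
        for i, c in enumerate(ori_calls):
            lo = c.promoter.window_low
            hi = c.arm2[1] if c.arm2 else c.promoter.window_high
            attrs = {"status": c.status}
            if c.insert_length is not None:
                attrs["insert_length"] = str(c.insert_length)
            ori_feats.append(FeatureRecord(f"ori_call_{i}", "ori",
                                           c.promoter.strand, min(lo, hi),
                                           max(lo, hi), attributes=attrs))
        write_gff3(ori_feats, outdir / "ori_calls.gff3", seqid=genome.id)
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    except Exception:
        logger.exception("pipeline aborted")
        raise
    return outdir
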