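"""Strand-aware counting, RPKM, and two-condition comparison.

Expression is measured in RPKM: reads mapped to a feature, divided by the
transcript size in kilobases times the total mappable reads in millions.
Counting is strand-resolved: a read is *sense* for a feature when its RNA
strand equals the feature strand and *antisense* ("mirror") otherwise.  A
read overlapping two same-strand features counts for both — introns and
exons of one gene are quantified separately.

The two-condition comparison reports the fold change of replicate-mean RPKM
with a label-permutation p-value.  This is deliberately not a
negative-binomial (DESeq-style) test; the permutation test is the documented
substitute and its p-values are floor-bounded by 1/(number of label
assignments).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import FeatureRecord, GenomeSequence, feature_length
from .reads import AlignedReadView, TrnaBoundaryCall, CleavageSiteCall

__all__ = [
    "ExpressionRecord",
    "ComparisonRecord",
    "count_reads",
    "rpkm",
    "quantify",
    "compare",
    "report_map",
]


@dataclass
class ExpressionRecord:
    """Sense/antisense read counts and RPKM for one feature."""

    feature_id: str
    sense_reads: int
    antisense_reads: int
    length_kb: float
    total_mappable_millions: float
    rpkm_sense: float
    rpkm_antisense: float


@dataclass
class ComparisonRecord:
    """Two-condition fold change (condition b over a) with permutation p."""

    feature_id: str
    rpkm_a: float
    rpkm_b: float
    fold_change: float
    log2_fc: float
    p_value: float
    n_replicates_a: int
    n_replicates_b: int


def rpkm(reads: int, length: int, total_mappable: int) -> float:
    """reads / ((length/1000) * (total_mappable/1e6))."""
    if length <= 0:
        raise ValueError("zero or negative feature length")
    if total_mappable <= 0:
        raise ValueError("zero library size")
    return reads / ((length / 1000.0) * (total_mappable / 1e6))


def count_reads(views: Sequence[AlignedReadView], features: Sequence[FeatureRecord],
                genome: GenomeSequence, min_overlap: int = 1) -> dict:
    """Per-feature (sense, antisense) read counts.

    A read counts when its aligned span overlaps the feature by at least
    ``min_overlap`` nt (wrap-aware for wrapping features).
    """
    lows = np.array([v.reference_low for v in views], dtype=np.int64)
    highs = np.array([v.reference_high for v in views], dtype=np.int64)
    strands = np.array([v.strand == "+" for v in views])
    L = len(genome)
    out = {}
    for f in features:
        if not f.located:
            continue
        spans = [(f.low, f.high)] if not f.wraps else [(f.low, L), (1, f.high)]
        ov = np.zeros(len(views), dtype=np.int64)
        for lo, hi in spans:
            ov += np.maximum(0, np.minimum(highs, hi) - np.maximum(lows, lo) + 1)
        hit = ov >= min_overlap
        sense = int(np.count_nonzero(hit & (strands == (f.strand == "+"))))
        anti = int(np.count_nonzero(hit & (strands != (f.strand == "+"))))
        out[f.feature_id] = (sense, anti)
    return out


def quantify(views: Sequence[AlignedReadView], features: Sequence[FeatureRecord],
             genome: GenomeSequence, min_overlap: int = 1,
             total_mappable: Optional[int] = None) -> list[ExpressionRecord]:
    """Expression records for every located feature.

    ``total_mappable`` defaults to the number of retained read views in this
    sample (the library size the RPKM denominator uses).
    """
    total = total_mappable if total_mappable is not None else len(views)
    counts = count_reads(views, features, genome, min_overlap=min_overlap)
    records = []
    for f in features:
        if f.feature_id not in counts:
            continue
        sense, anti = counts[f.feature_id]
        length = feature_length(f, genome)
        records.append(
            ExpressionRecord(
                feature_id=f.feature_id,
                sense_reads=sense,
                antisense_reads=anti,
                length_kb=length / 1000.0,
                total_mappable_millions=total / 1e6,
                rpkm_sense=rpkm(sense, length, total),
                rpkm_antisense=rpkm(anti, length, total),
            )
        )
    return records


def _mean_rpkm(rows: Sequence[ExpressionRecord], antisense: bool) -> float:
    vals = [r.rpkm_antisense if antisense else r.rpkm_sense for r in rows]
    return float(np.mean(vals))


def compare(condition_a: Sequence[Sequence[ExpressionRecord]],
            condition_b: Sequence[Sequence[ExpressionRecord]],
            n_permutations: Optional[int] = None,
            seed: int = 0,
            antisense: bool = False,
            pseudo_rpkm: Optional[float] = None) -> list[ComparisonRecord]:
    """Fold change (b over a) of replicate-mean RPKM, with permutation p.

    The p-value is the fraction of replicate-label assignments (the observed
    one included) whose |log2 fold change| is at least the observed one;
    with few replicates all C(na+nb, na) assignments are enumerated,
    otherwise ``n_permutations`` are subsampled deterministically from
    ``seed``.  Fold changes with a zero denominator are infinite unless
    ``pseudo_rpkm`` is given, in which case it is added to both means.
    """
    ids_a = [tuple(r.feature_id for r in rep) for rep in condition_a]
    ids_b = [tuple(r.feature_id for r in rep) for rep in condition_b]
    if len(set(ids_a + ids_b)) != 1:
        raise ValueError("feature universes differ between replicates/conditions")
    feature_ids = ids_a[0]
    na, nb = len(condition_a), len(condition_b)

    # matrix: replicates x features, condition a rows first
    def val(r):
        return r.rpkm_antisense if antisense else r.rpkm_sense

    mat = np.array([[val(r) for r in rep] for rep in list(condition_a) + list(condition_b)])

    def log2fc(rows_a, rows_b):
        ma = mat[rows_a].mean(axis=0)
        mb = mat[rows_b].mean(axis=0)
        if pseudo_rpkm is not None:
            ma = ma + pseudo_rpkm
            mb = mb + pseudo_rpkm
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(mb) - np.log2(ma), ma, mb

    obs_idx_a = list(range(na))
    obs_idx_b = list(range(na, na + nb))
    obs_l2, mean_a, mean_b = log2fc(obs_idx_a, obs_idx_b)

    all_rows = list(range(na + nb))
    combos = list(itertools.combinations(all_rows, na))
    if n_permutations is not None and len(combos) > n_permutations:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(combos), size=n_permutations, replace=False)
        identity = tuple(obs_idx_a)
        chosen = {combos[i] for i in pick}
        chosen.add(identity)
        combos = sorted(chosen)

    obs_abs = np.abs(obs_l2)
    exceed = np.zeros(len(feature_ids), dtype=np.int64)
    for rows_a in combos:
        rows_b = [r for r in all_rows if r not in rows_a]
        l2, _, _ = log2fc(list(rows_a), rows_b)
        with np.errstate(invalid="ignore"):
            ge = np.abs(l2) >= obs_abs - 1e-12
        exceed += ge.astype(np.int64)
    pvals = exceed / len(combos)
    # features with no defined fold change (both means zero) are null: p = 1
    pvals[np.isnan(obs_l2)] = 1.0

    out = []
    for i, fid in enumerate(feature_ids):
        ma, mb = float(mean_a[i]), float(mean_b[i])
        if ma > 0:
            fc = mb / ma
        else:
            fc = math.inf if mb > 0 else math.nan
        out.append(
            ComparisonRecord(
                feature_id=fid,
                rpkm_a=ma,
                rpkm_b=mb,
                fold_change=fc,
                log2_fc=float(obs_l2[i]),
                p_value=float(max(pvals[i], 1.0 / len(combos))),
                n_replicates_a=na,
                n_replicates_b=nb,
            )
        )
    return out


def report_map(outdir, features: Sequence[FeatureRecord] = (),
               expression: Sequence[ExpressionRecord] = (),
               trna_calls: Sequence[TrnaBoundaryCall] = (),
               cleavage_calls: Sequence[CleavageSiteCall] = (),
               comparisons: Sequence[ComparisonRecord] = (),
               promoter_rows: Sequence[dict] = (),
               external_trna_predictions: Optional[pd.DataFrame] = None,
               library_note: str = "total mappable reads = retained 5'-mate alignments per sample") -> dict:
    """Write the map tables as TSVs; returns the DataFrames by name.

    The tRNA table gains per-tRNA agreement columns when an external
    prediction table (columns: trna_id, pred_5prime, pred_3prime) is given;
    a tRNA agrees on a bound when the external prediction is present and
    equal.  Empty inputs yield headers-only files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {}

    expr = pd.DataFrame(
        [vars(r) for r in expression],
        columns=["feature_id", "sense_reads", "antisense_reads", "length_kb",
                 "total_mappable_millions", "rpkm_sense", "rpkm_antisense"],
    )
    tables["expression"] = expr

    trna = pd.DataFrame(
        [vars(c) for c in trna_calls],
        columns=["trna_id", "strand", "three_prime", "cca_support",
                 "full_cca_reads", "five_prime", "five_prime_method"],
    )
    if external_trna_predictions is not None and len(trna):
        ext = external_trna_predictions.set_index("trna_id")
        agree5, agree3 = [], []
        for _, row in trna.iterrows():
            if row["trna_id"] in ext.index:
                e = ext.loc[row["trna_id"]]
                agree5.append(bool(pd.notna(e["pred_5prime"]) and e["pred_5prime"] == row["five_prime"]))
                agree3.append(bool(pd.notna(e["pred_3prime"]) and e["pred_3prime"] == row["three_prime"]))
            else:
                agree5.append(False)
                agree3.append(False)
        trna["external_5prime_agrees"] = agree5
        trna["external_3prime_agrees"] = agree3
        trna["external_both_agree"] = [a and b for a, b in zip(agree5, agree3)]
    tables["trna_boundaries"] = trna

    tables["cleavage_sites"] = pd.DataFrame(
        [vars(c) for c in cleavage_calls],
        columns=["cut_after", "strand", "end_support", "start_support",
                 "local_background", "enrichment", "motif_id"],
    )
    tables["promoters"] = pd.DataFrame(
        list(promoter_rows),
        columns=["tss", "strand", "window_low", "window_high", "window_sequence",
                 "nonanucleotide_ok", "serving"],
    )
    tables["fold_changes"] = pd.DataFrame(
        [vars(c) for c in comparisons],
        columns=["feature_id", "rpkm_a", "rpkm_b", "fold_change", "log2_fc",
                 "p_value", "n_replicates_a", "n_replicates_b"],
    )

    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        with path.open("w") as fh:
            fh.write(f"# {library_note}\n")
            df.to_csv(fh, sep="\t", index=False)
    return tables
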