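"""Bundled reference map of the S288C mitochondrial transcriptome.

The data here are the published tabular annotations of the S288C
mitochondrial genome: the 24 tRNA genes with RNA-seq-derived boundaries and
the tRNAscan-SE comparison columns; the minimal set of 14 promoters (11
serving genes, 3 serving origins of replication) as aligned 20-nt
non-template-strand windows; the five nonanucleotide windows not associated
with a consensus promoter; and the gene/intron catalog (8 polypeptide genes,
2 rRNAs, RPM1, 13 group I/II introns).

Coordinates are recorded verbatim from the source tables (1-based inclusive,
S288C chrM frame); entries without printed coordinates are catalog entries
with ``low = high = None``.
"""

from __future__ import annotations

import pandas as pd

from .genome import FeatureRecord

__all__ = [
    "TRNA_TABLE",
    "PROMOTER_TABLE",
    "NONANUCLEOTIDE_ONLY",
    "NONANUCLEOTIDE",
    "CONSENSUS_PROMOTER",
    "build_s288c_reference",
    "reference_tallies",
    "trna_table",
    "promoter_alignment",
]

#: The 9-base core promoter, ending at the +1 transcription start (an A).
NONANUCLEOTIDE = "ATATAAGTA"

#: The 20-base degenerate consensus promoter, positions -12..+8.
CONSENSUS_PROMOTER = "DDWDWTAWAAGTARTADDDD"

# (systematic name, isotype, strand, 5', 3', mispredicted 5', mispredicted 3',
#  tRNAscan-SE rank or None for "Not Predicted")
TRNA_TABLE = [
    ("tP(UGG)Q", "Pro", "+", 731, 802, None, None, None),
    ("tW(UCA)Q", "Trp", "+", 9374, 9444, None, 9447, 1),
    ("tE(UUC)Q", "Glu", "+", 35373, 35444, None, 35447, 2),
    ("tS(UGA)Q2", "Ser", "+", 48201, 48287, None, 48290, 3),
    ("tT(UGU)Q1", "Thr", "+", 63862, 63934, None, 63937, 4),
    ("tC(GCA)Q", "Cys", "+", 64415, 64487, None, 64490, None),
    ("tH(GUG)Q", "His", "+", 64597, 64667, 64596, 64670, 5),
    ("tL(UAA)Q", "Leu", "+", 66095, 66176, None, 66179, 6),
    ("tQ(UUG)Q", "Gln", "+", 66210, 66282, None, 66285, 7),
    ("tK(UUU)Q", "Lys", "+", 67061, 67132, None, 67134, 8),
    ("tR(UCU)Q1", "Arg", "+", 67309, 67381, None, None, 9),
    ("tG(UCC)Q", "Gly", "+", 67468, 67539, None, 67542, 10),
    ("tD(GUC)Q", "Asp", "+", 68322, 68393, None, 68396, 11),
    ("tS(GCU)Q1", "Ser", "+", 69203, 69285, None, 69288, None),
    ("tR(ACG)Q2", "Arg", "+", 69289, 69359, None, 69362, 12),
    ("tA(UGC)Q", "Ala", "+", 69846, 69918, None, 69921, 13),
    ("tI(GAU)Q", "Ile", "+", 70162, 70234, None, 70237, 14),
    ("tY(GUA)Q", "Tyr", "+", 70824, 70908, None, 70907, None),
    ("tN(GUU)Q", "Asn", "+", 71433, 71504, None, 71503, 15),
    ("tM(CAU)Q1", "Met", "+", 72632, 72705, 72630, None, 16),
    ("tF(GAA)Q", "Phe", "+", 77431, 77502, None, 77505, 17),
    ("tT(UAG)Q2", "Thr", "-", 78162, 78091, None, 78089, 20),
    ("tV(UAC)Q", "Val", "+", 78533, 78605, None, 78608, 18),
    ("tM(CAU)Q2", "fMet", "+", 85035, 85107, None, 85112, 19),
]

# The minimal promoter set: (primary transcripts served, 20-nt window on the
# non-template strand, serves "gene" or "ori").  Windows span -12..+8 with the
# +1 adenosine at offset 13.
PROMOTER_TABLE = [
    ("15S_rRNA,Trp", "TATTATATAAGTAATAAATA", "gene"),
    ("COX1,ATP8,ATP6", "ATTGATATAAGTAATAGATA", "gene"),
    ("ori2", "AAATATATAAGTAATAAATT", "ori"),
    ("Glu,COB", "TATTATATAAGTAATATATA", "gene"),
    ("ATP9,Ser2,VAR1", "ATTAATATAAGTAATATATA", "gene"),
    ("ori3", "AGATATATAAGTAATAGGGG", "ori"),
    ("21S_rRNA,Thr,Cys,His", "ATATATATAAGTAGTAAAAA", "gene"),
    ("Leu,Gln,Lys,Arg,Gly,Asp,Ser,Arg2", "TGTTATATAAGTAATAATAT", "gene"),
    ("ori5", "AAATATATAAGTAATAGGGG", "ori"),
    ("Ala,Ile,Tyr,Asn,Met", "TTTATTATAAGTAATAATAT", "gene"),
    ("Phe,Val,COX3", "TATATTATAAGTAATAATAA", "gene"),
    ("Thr2", "ATTTTTATAAGTAGTATATA", "gene"),
    ("fMet,RPM1,Pro", "GATTTTATAAGTAATATAAT", "gene"),
    # The published row for this promoter is typographically ambiguous about
    # the exact column of its mid-nonanucleotide deviation; the window below
    # is the best reading and the record is flagged.
    ("COX2,Q0255", "TTAATTAAAAGTAGTATTAA", "gene"),
]

#: Canonical nonanucleotide windows not associated with a consensus promoter
#: (genome spans as printed; none extend to the 20-base consensus).
NONANUCLEOTIDE_ONLY = [
    (4810, 4829),
    (33825, 33844),
    (44443, 44462),
    (46145, 46164),
    (85010, 85029),
]

_POLYPEPTIDE_GENES = ["COX1", "COX2", "COX3", "COB", "ATP6", "ATP8", "ATP9", "VAR1"]
_RRNA_GENES = ["21S_rRNA", "15S_rRNA"]
_NCRNA_GENES = ["RPM1"]

# 13 group I/II introns: 7 in COX1, 5 in COB, 1 (omega) in 21S rRNA.
_INTRONS = [
    ("aI1", "COX1"), ("aI2", "COX1"), ("aI3", "COX1"), ("aI4", "COX1"),
    ("aI5alpha", "COX1"), ("aI5beta", "COX1"), ("aI5gamma", "COX1"),
    ("bI1", "COB"), ("bI2", "COB"), ("bI3", "COB"), ("bI4", "COB"), ("bI5", "COB"),
    ("omega", "21S_rRNA"),
]


def build_s288c_reference() -> list[FeatureRecord]:
    """The bundled S288C mitochondrial reference map as feature records.

    tRNAs carry their published boundaries plus the external-prediction
    comparison columns in ``attributes``; promoters carry their 20-nt window
    and the transcripts they serve; genes and introns without printed
    coordinates are coordinate-less catalog entries.
    """
    feats: list[FeatureRecord] = []
    for name, isotype, strand, p5, p3, mis5, mis3, rank in TRNA_TABLE:
        low, high = (p5, p3) if strand == "+" else (p3, p5)
        attrs = {"isotype": isotype, "oxphos": "true"}
        if mis5 is not None:
            attrs["mispredicted_5prime"] = str(mis5)
        if mis3 is not None:
            attrs["mispredicted_3prime"] = str(mis3)
        attrs["trnascan"] = str(rank) if rank is not None else "not_predicted"
        feats.append(FeatureRecord(name, "tRNA", strand, low, high, attributes=attrs))

    for i, (served, window, serving) in enumerate(PROMOTER_TABLE, start=1):
        attrs = {"window": window, "serves": serving, "primary_transcripts": served}
        if served == "COX2,Q0255":
            attrs["ambiguous_row"] = "true"
        feats.append(
            FeatureRecord(f"promoter_{served.split(',')[0]}", "promoter", "+",
                          attributes=attrs)
        )

    for g in _POLYPEPTIDE_GENES:
        feats.append(FeatureRecord(g, "gene", "+",
                                   attributes={"class": "polypeptide", "oxphos": "true"}))
    for g in _RRNA_GENES:
        feats.append(FeatureRecord(g, "rRNA", "+",
                                   attributes={"class": "rRNA", "oxphos": "true"}))
    for g in _NCRNA_GENES:
        feats.append(FeatureRecord(g, "gene", "+",
                                   attributes={"class": "ncRNA", "oxphos": "true"}))
    feats.append(FeatureRecord("Q0255", "orf", "+",
                               attributes={"class": "HEG-related"}))
    for name, host in _INTRONS:
        feats.append(FeatureRecord(name, "intron", "+", parent_id=host,
                                   attributes={"host_gene": host}))
    return feats


def reference_tallies(features: list[FeatureRecord] | None = None) -> dict:
    """Headline counts of the bundled reference map.

    Includes the external-prediction comparison: a tRNA's boundaries count as
    fully correct when no mispredicted bound is recorded for it.
    """
    feats = features if features is not None else build_s288c_reference()
    trnas = [f for f in feats if f.ftype == "tRNA"]
    promoters = [f for f in feats if f.ftype == "promoter"]
    scan_predicted = [f for f in trnas if f.attributes.get("trnascan") != "not_predicted"]
    correct_pairs = [
        f for f in trnas
        if "mispredicted_5prime" not in f.attributes
        and "mispredicted_3prime" not in f.attributes
    ]
    oxphos = [f for f in feats if f.attributes.get("oxphos") == "true"]
    return {
        "n_trnas": len(trnas),
        "n_trnascan_predicted": len(scan_predicted),
        "n_trnascan_correct_boundary_pairs": len(correct_pairs),
        "n_introns": sum(1 for f in feats if f.ftype == "intron"),
        "n_oxphos_genes": len(oxphos),
        "n_promoters": len(promoters),
        "n_gene_promoters": sum(1 for f in promoters if f.attributes["serves"] == "gene"),
        "n_ori_promoters": sum(1 for f in promoters if f.attributes["serves"] == "ori"),
        "n_nonanucleotide_only": len(NONANUCLEOTIDE_ONLY),
    }


def trna_table() -> pd.DataFrame:
    """The bundled tRNA boundary table as a DataFrame (export-ready)."""
    return pd.DataFrame(
        TRNA_TABLE,
        columns=[
            "systematic_name", "isotype", "strand",
            "rnaseq_5prime", "rnaseq_3prime",
            "mispredicted_5prime", "mispredicted_3prime", "trnascan_rank",
        ],
    )


def promoter_alignment() -> list[str]:
    """The 14 aligned 20-nt promoter windows (consensus-derivation input)."""
    return [window for _, window, _ in PROMOTER_TABLE]
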