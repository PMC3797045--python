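"""RPKM arithmetic, strand-aware counting, permutation comparison, and
report generation."""

import math

import numpy as np
import pandas as pd
import pytest

from mitomap.genome import GenomeSequence, FeatureRecord
from mitomap.reads import AlignedReadView
from mitomap.quantify import (ExpressionRecord, rpkm, count_reads, quantify,
                              compare, report_map)
from mitomap.reads import TrnaBoundaryCall
from mitomap.s288c import TRNA_TABLE


def _view(lo, hi, strand="+"):
    return AlignedReadView("r", lo, hi, strand)


GENOME = GenomeSequence("g", "A" * 5000, circular=True)


class TestRpkm:
    @pytest.mark.parametrize("reads,length,total,expected", [
        (10, 1000, 1_000_000, 10.0),
        (450, 500, 9_000_000, 100.0),
        (0, 1000, 1_000_000, 0.0),
    ])
    def test_values(self, reads, length, total, expected):
        assert rpkm(reads, length, total) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 1000)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)

    def test_linearity(self):
        base = rpkm(37, 1234, 5_000_000)
        assert rpkm(74, 1234, 5_000_000) == pytest.approx(2 * base)
        assert rpkm(74, 1234, 10_000_000) == pytest.approx(base)


class TestCountReads:
    def test_sense_and_antisense(self):
        gene = FeatureRecord("gene", "gene", "+", 100, 200)
        mirror = FeatureRecord("mir", "mirror", "-", 100, 200)
        views = [_view(120, 180) for _ in range(10)]
        counts = count_reads(views, [gene, mirror], GENOME)
        assert counts["gene"] == (10, 0)
        assert counts["mir"] == (0, 10)

    def test_min_overlap(self):
        gene = FeatureRecord("gene", "gene", "+", 100, 200)
        views = [_view(195, 260)]
        assert count_reads(views, [gene], GENOME, min_overlap=6)["gene"] == (1, 0)
        assert count_reads(views, [gene], GENOME, min_overlap=7)["gene"] == (0, 0)

    def test_wrap_feature(self):
        gene = FeatureRecord("gene", "gene", "+", 4990, 10, wraps=True)
        views = [_view(4995, 5000), _view(1, 5), _view(2000, 2100)]
        assert count_reads(views, [gene], GENOME)["gene"] == (2, 0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(43)
        feats = []
        for i in range(12):
            lo = int(rng.integers(1, 4500))
            feats.append(FeatureRecord(f"f{i}", "gene",
                                       rng.choice(["+", "-"]),
                                       lo, lo + int(rng.integers(20, 400))))
        views = []
        for _ in range(400):
            lo = int(rng.integers(1, 4900))
            views.append(_view(lo, lo + int(rng.integers(0, 100)),
                               rng.choice(["+", "-"])))
        counts = count_reads(views, feats, GENOME)
        for f in feats:
            sense = anti = 0
            for v in views:
                ov = min(v.reference_high, f.high) - max(v.reference_low, f.low) + 1
                if ov >= 1:
                    if v.strand == f.strand:
                        sense += 1
                    else:
                        anti += 1
            assert counts[f.feature_id] == (sense, anti)

    def test_conservation_bound(self):
        rng = np.random.default_rng(47)
        f = FeatureRecord("f", "gene", "+", 1000, 2000)
        views = [_view(int(lo), int(lo) + 50, rng.choice(["+", "-"]))
                 for lo in rng.integers(1, 4000, size=200)]
        sense, anti = count_reads(views, [f], GENOME)["f"]
        overlapping = sum(1 for v in views
                          if min(v.reference_high, 2000) - max(v.reference_low, 1000) >= 0)
        assert sense + anti == overlapping


def _expr(fid, sense_rpkm, anti_rpkm=0.0):
    return ExpressionRecord(fid, 0, 0, 1.0, 1.0, sense_rpkm, anti_rpkm)


class TestCompare:
    def test_identical_conditions_null(self):
        rep = [_expr("a", 5.0), _expr("b", 2.0)]
        res = compare([rep, rep], [rep, rep])
        assert all(r.fold_change == pytest.approx(1.0) for r in res)
        assert all(r.p_value == 1.0 for r in res)

    def test_two_vs_two_p_floor(self):
        rng = np.random.default_rng(53)
        reps = [[_expr("f", float(v))] for v in rng.uniform(1, 100, size=4)]
        res = compare(reps[:2], reps[2:])
        assert res[0].p_value >= 1 / 6 - 1e-12

    def test_feature_universe_mismatch(self):
        with pytest.raises(ValueError):
            compare([[_expr("a", 1.0)]], [[_expr("b", 1.0)]])

    def test_zero_denominator(self):
        res = compare([[_expr("f", 0.0)], [_expr("f", 0.0)]],
                      [[_expr("f", 4.0)], [_expr("f", 6.0)]])
        assert math.isinf(res[0].fold_change)
        res2 = compare([[_expr("f", 0.0)], [_expr("f", 0.0)]],
                       [[_expr("f", 4.0)], [_expr("f", 6.0)]],
                       pseudo_rpkm=0.1)
        assert math.isfinite(res2[0].fold_change)

    def test_null_pvalues_superuniform(self):
        # Poisson-count null: no feature differs between conditions; the
        # permutation p-values must satisfy P(p <= t) <= t (+MC slack)
        rng = np.random.default_rng(59)
        n_feat = 200
        lam = rng.uniform(20, 200, size=n_feat)
        reps = []
        for _ in range(4):
            reps.append([_expr(f"f{i}", float(rng.poisson(lam[i])))
                         for i in range(n_feat)])
        res = compare(reps[:2], reps[2:])
        pvals = np.array([r.p_value for r in res])
        for t in (1 / 6, 2 / 6, 3 / 6):
            assert (pvals <= t + 1e-12).mean() <= t + 0.08

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(61)
        reps = [[_expr(f"f{i}", float(v)) for i, v in
                 enumerate(rng.uniform(1, 50, size=30))] for _ in range(8)]
        r1 = compare(reps[:4], reps[4:], n_permutations=20, seed=5)
        r2 = compare(reps[:4], reps[4:], n_permutations=20, seed=5)
        assert [r.p_value for r in r1] == [r.p_value for r in r2]


class TestReportMap:
    def test_empty_inputs_give_header_only_files(self, tmp_path):
        tables = report_map(tmp_path)
        for name in ("expression", "trna_boundaries", "cleavage_sites",
                     "promoters", "fold_changes"):
            assert (tmp_path / f"{name}.tsv").exists()
            assert len(tables[name]) == 0

    def test_external_trna_agreement_tally(self, tmp_path):
        # calls = the published read-evidence bounds; external predictions =
        # the prior annotation (mispredicted where recorded).  Exactly two
        # tRNAs agree on both bounds.
        calls, ext_rows = [], []
        for name, _iso, strand, p5, p3, mis5, mis3, rank in TRNA_TABLE:
            calls.append(TrnaBoundaryCall(name, strand, three_prime=p3,
                                          cca_support=10, full_cca_reads=5,
                                          five_prime=p5))
            ext_rows.append({"trna_id": name,
                             "pred_5prime": mis5 if mis5 is not None else p5,
                             "pred_3prime": mis3 if mis3 is not None else p3})
        tables = report_map(tmp_path, trna_calls=calls,
                            external_trna_predictions=pd.DataFrame(ext_rows))
        trna = tables["trna_boundaries"]
        assert len(trna) == 24
        assert int(trna["external_both_agree"].sum()) == 2
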