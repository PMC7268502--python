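import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvmeta import (
    CnClass,
    ConsensusSegment,
    GeneCopyNumber,
    GeneRecord,
    PloidyModel,
    TruthTable,
    classify_gene,
    evaluate,
    map_segments_to_genes,
    mae,
    mcc_micro,
    mlre,
    mse,
    variance_of_residuals,
)
from cnvmeta.gene_metrics import confusion_micro


def seg(chrom, start, end, cn):
    return ConsensusSegment(chrom, start, end, cn, 0.0, "r")


def pairs(*xy):
    return [GeneCopyNumber(f"g{i}", x, y, 1000) for i, (x, y) in enumerate(xy)]


class TestGeneMapping:
    def test_length_weighted_mix(self):
        genes = [GeneRecord("G", "1", 0, 1000)]
        segments = [seg("1", 0, 600, 2.0), seg("1", 600, 1200, 4.0)]
        out = map_segments_to_genes(segments, genes)
        assert out["G"] == pytest.approx(0.6 * 2 + 0.4 * 4)  # 2.8

    def test_gene_inside_single_segment(self):
        genes = [GeneRecord("G", "1", 500, 800)]
        assert map_segments_to_genes([seg("1", 0, 10_000, 3.0)], genes)["G"] == pytest.approx(3.0)

    def test_uncovered_bases_filled_with_ploidy(self):
        genes = [GeneRecord("G", "1", 0, 1000)]
        out = map_segments_to_genes([seg("1", 0, 500, 4.0)], genes)
        assert out["G"] == pytest.approx(0.5 * 4 + 0.5 * 2)  # 3.0

    def test_gene_on_unpredicted_chromosome_gets_ploidy(self, caplog):
        genes = [GeneRecord("G", "9", 0, 1000)]
        with caplog.at_level("WARNING"):
            out = map_segments_to_genes([seg("1", 0, 100, 5.0)], genes)
        assert out["G"] == 2.0

    def test_male_x_gene_gap_fill_uses_ploidy_one(self):
        genes = [GeneRecord("G", "X", 0, 1000)]
        model = PloidyModel(sex="male")
        out = map_segments_to_genes([seg("X", 0, 500, 2.0)], genes, model)
        assert out["G"] == pytest.approx(0.5 * 2 + 0.5 * 1)

    def test_full_coverage_bounded_by_segment_cns(self):
        rng = random.Random(1)
        for _ in range(50):
            cns = [rng.uniform(0, 8) for _ in range(4)]
            segments = [seg("1", i * 250, (i + 1) * 250, c) for i, c in enumerate(cns)]
            out = map_segments_to_genes(segments, [GeneRecord("G", "1", 0, 1000)])
            assert min(cns) - 1e-9 <= out["G"] <= max(cns) + 1e-9


class TestErrorMetrics:
    def test_perfect_prediction_is_zero(self):
        p = pairs((2, 2), (4, 4), (0, 0))
        assert mse(p) == mae(p) == mlre(p) == 0.0

    def test_known_values(self):
        p = pairs((2, 1), (4, 6))
        assert mse(p) == pytest.approx(2.5)
        assert mae(p) == pytest.approx(1.5)

    def test_single_pair(self):
        p = pairs((0, 2))
        assert mse(p) == 4.0 and mae(p) == 2.0

    def test_mlre_log_ratio(self):
        assert mlre(pairs((3, 1))) == pytest.approx(math.log(2))
        assert mlre(pairs((0, 0))) == 0.0  # the +1 guards the log at zero

    def test_empty_input_errors(self):
        for fn in (mse, mae, mlre, variance_of_residuals):
            with pytest.raises(ValueError):
                fn([])


class TestVarianceOfResiduals:
    def test_identical_residuals_within_groups(self):
        p = pairs((2, 1.5), (2, 1.5), (4, 4.5), (4, 4.5))
        assert variance_of_residuals(p) == 0.0

    def test_single_group_population_variance(self):
        p = pairs((3, 2), (3, 4))  # residuals +1, -1 -> population variance 1
        assert variance_of_residuals(p) == pytest.approx(1.0)

    def test_mean_over_groups(self):
        # group CN 2: variance 0; group CN 5: residuals +2,-2 -> variance 4
        p = pairs((2, 2), (2, 2), (5, 3), (5, 7))
        assert variance_of_residuals(p) == pytest.approx(2.0)

    def test_singleton_group_contributes_zero(self):
        p = pairs((2, 1), (7, 3.5))
        assert variance_of_residuals(p) == 0.0

    def test_decimal_truth_rounds_to_integer_groups(self):
        # 1.9 and 2.1 share the integer group 2
        p = pairs((1.9, 1.0), (2.1, 3.2))
        assert variance_of_residuals(p) == pytest.approx(np.var([0.9, -1.1]))


class TestGeneClassification:
    @pytest.mark.parametrize(
        "cn, expected",
        [
            (2.8, CnClass.AMPLIFICATION),
            (2.75, CnClass.NORMAL),   # boundaries are normal
            (1.75, CnClass.NORMAL),
            (0.3, CnClass.DELETION),
            (2.0, CnClass.NORMAL),
        ],
    )
    def test_diploid_thresholds(self, cn, expected):
        assert classify_gene(cn, 2) is expected

    def test_thresholds_scale_with_ploidy(self):
        assert classify_gene(3.4, ploidy=4) is CnClass.DELETION    # < 3.5
        assert classify_gene(5.6, ploidy=4) is CnClass.AMPLIFICATION  # > 5.5
        assert classify_gene(4.0, ploidy=4) is CnClass.NORMAL


class TestMccMicro:
    def test_perfect_three_class_prediction(self):
        cls = [CnClass.DELETION, CnClass.NORMAL, CnClass.AMPLIFICATION] * 3
        assert mcc_micro(cls, cls) == pytest.approx(1.0)

    def test_worked_example(self):
        D, N, A = CnClass.DELETION, CnClass.NORMAL, CnClass.AMPLIFICATION
        true, pred = [D, D, N, A], [D, N, N, A]
        c = confusion_micro(true, pred)
        assert (c["tp"], c["fp"], c["fn"], c["tn"]) == (3, 1, 1, 7)
        assert mcc_micro(true, pred) == pytest.approx(0.625)

    def test_constant_prediction_on_balanced_classes(self):
        D, N, A = CnClass.DELETION, CnClass.NORMAL, CnClass.AMPLIFICATION
        true = [D] * 5 + [N] * 5 + [A] * 5
        pred = [N] * 15
        assert mcc_micro(true, pred) <= 0.25

    def test_zero_denominator_returns_zero(self, caplog):
        # every gene in every one-vs-rest split predicted positive never happens;
        # force the degenerate case with a single class and wrong prediction
        with caplog.at_level("WARNING"):
            assert mcc_micro([], []) == 0.0

    @given(st.lists(st.sampled_from(list(CnClass)), min_size=2, max_size=40),
           st.randoms(use_true_random=False))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_invariant_under_class_relabelling(self, true, rnd):
        pred = [rnd.choice(list(CnClass)) for _ in true]
        perm = list(CnClass)
        rnd.shuffle(perm)
        mapping = dict(zip(list(CnClass), perm))
        before = mcc_micro(true, pred)
        after = mcc_micro([mapping[t] for t in true], [mapping[p] for p in pred])
        assert before == pytest.approx(after)


class TestEvaluate:
    def test_truth_equal_to_prediction(self):
        genes = [GeneRecord(f"G{i}", "1", i * 1000, (i + 1) * 1000) for i in range(6)]
        cns = [2, 2, 4, 1, 2, 6]
        segments = [seg("1", i * 1000, (i + 1) * 1000, float(c)) for i, c in enumerate(cns)]
        truth = TruthTable({f"G{i}": float(c) for i, c in enumerate(cns)})
        report = evaluate(segments, genes, truth)
        assert report.mse == report.mae == report.mlre == 0.0
        assert report.mcc == pytest.approx(1.0)
        assert report.n_genes == 6

    def test_truth_genes_missing_from_gene_set_are_reported(self):
        genes = [GeneRecord("G0", "1", 0, 1000)]
        truth = TruthTable({"G0": 2.0, "GHOST": 4.0})
        report = evaluate([seg("1", 0, 1000, 2.0)], genes, truth)
        assert report.missing_genes == ["GHOST"]
        assert report.n_genes == 1

    def test_empty_intersection_errors(self):
        genes = [GeneRecord("G0", "1", 0, 1000)]
        with pytest.raises(ValueError):
            evaluate([seg("1", 0, 1000, 2.0)], genes, TruthTable({"OTHER": 1.0}))
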