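import warnings
from itertools import product

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import ismvar as iv
from ismvar.errors import IngestionError, InvalidInputError

from .oracles import fisher_enumeration_p, mwu_enumeration_p


class TestMannWhitney:
    def test_fully_separated_triplets(self):
        u, p = iv.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 of the 20 equally likely orderings

    def test_identical_multisets_give_p_one(self):
        _, p = iv.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            iv.mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n1,n2", list(product(range(2, 6), repeat=2)))
    def test_exact_p_matches_enumeration(self, n1, n2, rng):
        values = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        a, b = values[:n1], values[n1:]
        _, p = iv.mann_whitney_u(a, b, method="exact")
        assert p == pytest.approx(mwu_enumeration_p(a, b), rel=1e-9)

    def test_u_is_min_of_both_group_statistics(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=5)
        u_ab, _ = iv.mann_whitney_u(a, b)
        u_ba, _ = iv.mann_whitney_u(b, a)
        assert u_ab == u_ba
        assert u_ab <= 8 * 5 / 2

    def test_auto_switches_to_asymptotic_on_ties(self):
        # tied data must not go through the exact path
        a = [1.0, 2.0, 2.0, 3.0]
        b = [2.0, 4.0, 5.0, 6.0]
        _, p_auto = iv.mann_whitney_u(a, b)
        _, p_asym = iv.mann_whitney_u(a, b, method="asymptotic")
        assert p_auto == p_asym

    def test_shift_equivariance_of_ranks(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=7)
        _, p = iv.mann_whitney_u(a, b)
        _, p_shift = iv.mann_whitney_u(a + 5.0, b + 5.0)
        assert p == pytest.approx(p_shift)


class TestFisherExact:
    def test_diagonal_five_table(self):
        assert iv.fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_uniform_table_is_p_one(self):
        assert iv.fisher_exact([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert iv.fisher_exact([[0, 0], [3, 4]]) == 1.0

    @pytest.mark.parametrize(
        "table",
        [[[2, 3], [4, 1]], [[8, 1], [2, 7]], [[0, 5], [5, 0]], [[1, 7], [6, 2]]],
    )
    def test_matches_hypergeometric_enumeration(self, table):
        assert iv.fisher_exact(table) == pytest.approx(
            fisher_enumeration_p(table), rel=1e-8)

    def test_invariant_to_transpose_and_row_column_swap(self):
        table = np.array([[2, 5], [6, 1]])
        p = iv.fisher_exact(table)
        assert iv.fisher_exact(table.T) == pytest.approx(p)
        assert iv.fisher_exact(table[::-1, ::-1]) == pytest.approx(p)


class TestConfusionMetrics:
    def test_forced_arithmetic(self):
        report = iv.confusion_metrics(iv.ConfusionCounts(tp=2, tn=3, fp=1, fn=1))
        assert report.accuracy == pytest.approx(5 / 7)
        assert report.precision == pytest.approx(2 / 3)
        assert report.sensitivity == pytest.approx(2 / 3)
        assert report.specificity == pytest.approx(3 / 4)
        assert report.npv == pytest.approx(3 / 4)

    def test_perfect_classifier(self):
        report = iv.confusion_metrics(iv.ConfusionCounts(tp=4, tn=6, fp=0, fn=0))
        assert all(v == 1.0 for v in
                   (report.accuracy, report.precision, report.sensitivity,
                    report.specificity, report.npv))

    def test_undefined_precision_reported_as_missing(self):
        report = iv.confusion_metrics(iv.ConfusionCounts(tp=0, tn=3, fp=0, fn=2))
        assert report.precision is None
        assert report.specificity == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            iv.ConfusionCounts(tp=0, tn=0, fp=0, fn=0)

    def test_accuracy_is_prevalence_weighted_combination(self, rng):
        tp, tn, fp, fn = 7, 11, 3, 5
        r = iv.confusion_metrics(iv.ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        total = tp + tn + fp + fn
        prevalence = (tp + fn) / total
        assert r.accuracy == pytest.approx(
            prevalence * r.sensitivity + (1 - prevalence) * r.specificity)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = iv.roc_auc([0.9, 0.8, 0.2, 0.1],
                            [iv.MUT, iv.MUT, iv.SNP, iv.SNP])
        assert auc == 1.0

    def test_anti_separation(self):
        _, auc = iv.roc_auc([0.9, 0.8, 0.2, 0.1],
                            [iv.SNP, iv.SNP, iv.MUT, iv.MUT])
        assert auc == 0.0

    def test_auc_equals_u_over_n1n2_tie_free(self, rng):
        scores = rng.permutation(np.arange(30, dtype=float))
        labels = [iv.MUT] * 12 + [iv.SNP] * 18
        _, auc = iv.roc_auc(scores, labels)
        mut = scores[:12]
        snp = scores[12:]
        u_greater = sum(1.0 for m in mut for s in snp if m > s)
        assert auc == pytest.approx(u_greater / (12 * 18), abs=1e-12)

    def test_matches_independent_reference(self, rng):
        scores = rng.normal(size=60)
        scores[rng.integers(0, 60, 10)] = 0.5  # inject ties
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        labels = [iv.MUT if v else iv.SNP for v in y]
        _, auc = iv.roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_null_scores_near_half(self):
        gen = np.random.default_rng(12345)
        scores = gen.normal(size=200)
        labels = [iv.MUT if v else iv.SNP for v in gen.integers(0, 2, 200)]
        _, auc = iv.roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.08)

    def test_curve_runs_from_origin_to_corner(self, rng):
        scores = rng.normal(size=25)
        labels = [iv.MUT if v else iv.SNP for v in rng.integers(0, 2, 25)]
        if len(set(labels)) < 2:
            labels[0], labels[1] = iv.MUT, iv.SNP
        points, _ = iv.roc_auc(scores, labels)
        np.testing.assert_allclose(points[0], [0.0, 0.0])
        np.testing.assert_allclose(points[-1], [1.0, 1.0])
        assert np.all(np.diff(points[:, 0]) >= 0)
        assert np.all(np.diff(points[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            iv.roc_auc([0.1, 0.2], [iv.MUT, iv.MUT])


class TestExternalScores:
    @pytest.mark.parametrize("original,expected", [(0.01, 0.99), (0.88, 0.12)])
    def test_sift_reorientation(self, original, expected):
        assert iv.transform_sift_score(original) == pytest.approx(expected)

    def test_sift_score_out_of_range(self):
        with pytest.raises(IngestionError):
            iv.transform_sift_score(1.5)

    @pytest.mark.parametrize(
        "score,tool,expected",
        [(0.01, "sift", iv.MUT), (0.05, "sift", iv.SNP), (0.2, "sift", iv.SNP),
         (0.5, "polyphen2", iv.MUT), (0.49, "polyphen2", iv.SNP),
         (0.9, "PolyPhen-2", iv.MUT)],
    )
    def test_binary_cutoffs(self, score, tool, expected):
        assert iv.binarize_external(score, tool) == expected

    def test_unknown_tool_rejected(self):
        with pytest.raises(IngestionError):
            iv.binarize_external(0.5, "cadd")


class TestEvaluatePredictions:
    def test_full_report(self):
        truths = [iv.MUT] * 5 + [iv.SNP] * 5
        preds = [iv.MUT] * 4 + [iv.SNP] + [iv.SNP] * 4 + [iv.MUT]
        scores = [0.9, 0.8, 0.7, 0.6, 0.2, 0.1, 0.15, 0.12, 0.11, 0.65]
        report = iv.evaluate_predictions(truths, preds, scores)
        assert report.accuracy == pytest.approx(0.8)
        assert report.fisher_p == pytest.approx(
            fisher_enumeration_p([[4, 1], [1, 4]]), rel=1e-8)
        assert 0.0 <= report.auc <= 1.0
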