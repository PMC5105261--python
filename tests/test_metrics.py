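import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from drabal import metrics
from drabal.exceptions import ParameterError


def _report_brute_force(actual, predicted):
    """Independent per-assay confusion enumeration with plain Python loops."""
    M, N = actual.shape
    sens, spec, prec = [], [], []
    for j in range(N):
        tp = fp = tn = fn = 0
        for i in range(M):
            if actual[i, j] == 0:
                continue
            act_pos = actual[i, j] == 1
            pred_pos = predicted[i, j] == 1
            tp += act_pos and pred_pos
            fn += act_pos and not pred_pos
            fp += (not act_pos) and pred_pos
            tn += (not act_pos) and (not pred_pos)
        sens.append(tp / (tp + fn) if tp + fn else 0.0)
        spec.append(tn / (tn + fp) if tn + fp else 0.0)
        prec.append(tp / (tp + fp) if tp + fp else 0.0)
    S = 100 * sum(sens) / N
    P2 = 100 * sum(spec) / N
    P = 100 * sum(prec) / N
    g = math.sqrt(S * P2)
    f1 = 2 * P * S / (P + S) if P + S else 0.0
    f05 = 1.25 * P * S / (0.25 * P + S) if 0.25 * P + S else 0.0
    return S, P2, P, g, f1, f05


class TestOutcomeSets:
    def test_definition(self):
        actual = np.array([[1], [-1], [0]])
        predicted = np.array([[1], [1], [1]])
        s = metrics.outcome_sets(actual, predicted)
        assert s.a_plus[0].tolist() == [0]
        assert s.a_minus[0].tolist() == [1]
        assert s.y_plus[0].tolist() == [0, 1]
        assert s.y_minus[0].tolist() == []

    def test_all_missing_assay(self):
        s = metrics.outcome_sets(np.zeros((3, 1), int), np.ones((3, 1), int))
        assert all(len(x[0]) == 0 for x in (s.a_plus, s.a_minus, s.y_plus, s.y_minus))

    def test_perfect_prediction_sets_coincide(self):
        actual = np.array([[1, -1], [-1, 1], [1, 1]])
        s = metrics.outcome_sets(actual, actual)
        for j in range(2):
            assert s.y_plus[j].tolist() == s.a_plus[j].tolist()
            assert s.y_minus[j].tolist() == s.a_minus[j].tolist()

    def test_shape_mismatch(self):
        with pytest.raises(ParameterError):
            metrics.outcome_sets(np.zeros((2, 2), int), np.zeros((3, 2), int))


class TestEvaluate:
    def test_worked_two_assay_example(self):
        # assay 1: A+={1,2}, A-={3,4}, Y+={1,3}; assay 2: A+={1}, A-={2,3,4}, Y+={1,2}
        actual = np.array([[1, 1], [1, -1], [-1, -1], [-1, -1]])
        predicted = np.array([[1, 1], [-1, 1], [1, -1], [-1, -1]])
        r = metrics.evaluate(actual, predicted)
        assert r.sensitivity == pytest.approx(75.0)
        assert r.specificity == pytest.approx(100 * (0.5 + 2 / 3) / 2)
        assert r.precision == pytest.approx(50.0)
        assert r.gmean == pytest.approx(66.14, abs=0.005)
        assert r.f1 == pytest.approx(60.0)
        assert r.f05 == pytest.approx(53.57, abs=0.005)

    def test_perfect_predictor(self, chain_dataset):
        ds, _ = chain_dataset
        r = metrics.evaluate(ds.labels, ds.labels)
        for v in r.as_dict().values():
            assert v == pytest.approx(100.0)

    def test_sign_flip_zeroes_everything(self):
        actual = np.array([[1, -1], [-1, 1], [1, 1], [-1, -1]])
        r = metrics.evaluate(actual, -actual)
        assert r.sensitivity == 0 and r.specificity == 0 and r.precision == 0
        assert r.f1 == 0 and r.f05 == 0

    def test_gmean_identity(self, chain_dataset):
        ds, _ = chain_dataset
        rng = np.random.default_rng(0)
        predicted = np.where(rng.random(ds.labels.shape) < 0.4, 1, -1)
        r = metrics.evaluate(ds.labels, predicted)
        assert r.gmean**2 == pytest.approx(r.sensitivity * r.specificity, rel=1e-12)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        actual = rng.choice([-1, 0, 1], size=(40, 3))
        predicted = rng.choice([-1, 1], size=(40, 3))
        perm = rng.permutation(40)
        r1 = metrics.evaluate(actual, predicted)
        r2 = metrics.evaluate(actual[perm], predicted[perm])
        assert r1.as_dict(12) == r2.as_dict(12)

    @given(st.integers(0, 10**6), st.integers(1, 4), st.integers(2, 50))
    def test_agrees_with_brute_force(self, seed, N, M):
        rng = np.random.default_rng(seed)
        actual = rng.choice([-1, 0, 1], size=(M, N))
        predicted = rng.choice([-1, 1], size=(M, N))
        r = metrics.evaluate(actual, predicted)
        expected = _report_brute_force(actual, predicted)
        got = (r.sensitivity, r.specificity, r.precision, r.gmean, r.f1, r.f05)
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestRelativeImprovement:
    @pytest.mark.parametrize(
        "a,b,expected", [(51.11, 45.35, 12.70), (61.05, 55.56, 9.88), (42.0, 42.0, 0.0)]
    )
    def test_reported_values(self, a, b, expected):
        assert metrics.relative_improvement(a, b) == expected

    def test_zero_reference(self):
        with pytest.raises(ParameterError):
            metrics.relative_improvement(10.0, 0.0)


class TestPairedTTest:
    def test_identical_lists_not_significant(self):
        r = metrics.paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert not r.significant and r.p_value == 1.0

    def test_constant_differences_degenerate(self):
        r = metrics.paired_ttest([3, 4, 5, 6, 7], [1, 2, 3, 4, 5])
        assert r.p_value == 1.0 and not r.significant

    def test_closed_form_example(self):
        # differences 1..5: t = 3 / (1.5811 / sqrt(5)) ~= 4.2426, p ~= 0.0132
        r = metrics.paired_ttest([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert r.statistic == pytest.approx(4.2426, abs=1e-4)
        assert r.p_value == pytest.approx(0.0132, abs=1e-3)
        assert r.significant


class TestOverlap:
    def test_single_all_positive_method(self):
        actual = np.array([[1, -1], [1, 1], [0, -1]])
        pred = np.ones_like(actual)
        o = metrics.correct_positive_overlap(actual, {"m": pred})
        assert o.total_positives == 3
        assert o.unique["m"] == 3 and o.missed == 0

    def test_identical_methods_share_intersection(self):
        actual = np.array([[1], [1], [-1]])
        pred = np.array([[1], [-1], [1]])
        o = metrics.correct_positive_overlap(actual, {"a": pred, "b": pred})
        assert o.unique == {"a": 0, "b": 0}
        assert o.regions[frozenset(["a", "b"])] == 1
        assert o.missed == 1

    def test_three_method_partition(self):
        # positives at rows 1..4 (assay 0); hits: A={1,2}, B={2,3}, C={2}
        actual = np.array([[1], [1], [1], [1]])

        def hit(rows):
            p = -np.ones((4, 1), int)
            p[list(rows)] = 1
            return p

        o = metrics.correct_positive_overlap(
            actual, {"A": hit([0, 1]), "B": hit([1, 2]), "C": hit([1])}
        )
        assert o.regions[frozenset(["A"])] == 1
        assert o.regions[frozenset(["B"])] == 1
        assert o.regions[frozenset(["A", "B", "C"])] == 1
        assert o.missed == 1
        assert sum(o.regions.values()) + o.missed == o.total_positives

    @given(st.integers(0, 10**6))
    def test_region_counts_partition_universe(self, seed):
        rng = np.random.default_rng(seed)
        actual = rng.choice([-1, 0, 1], size=(20, 2))
        preds = {n: rng.choice([-1, 1], size=(20, 2)) for n in "xyz"}
        o = metrics.correct_positive_overlap(actual, preds)
        assert sum(o.regions.values()) + o.missed == o.total_positives
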