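import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import metaga as m
from metaga.errors import InputError
from metaga.roc import roc_curve_from_scores

from conftest import make_prediction_set
from oracles import auc_pair_count, youden_brute_force


def _random_instance(rng, n_max=50):
    n = int(rng.integers(4, n_max + 1))
    scores = np.round(rng.normal(38, 2, n), 1)  # rounding forces ties
    labels = rng.random(n) < 0.4
    if labels.all() or not labels.any():
        labels[0], labels[-1] = True, False
    return scores, labels


class TestAuc:
    def test_separable_toy(self):
        curve = roc_curve_from_scores(
            np.array([33.0, 34.0, 39.0, 40.0]), np.array([True, True, False, False])
        )
        assert m.auc(curve) == 1.0
        assert m.youden(curve).j == 1.0

    def test_interleaved_toy_pair_count(self):
        scores = np.array([35.0, 38.0, 36.0, 39.0])
        labels = np.array([True, True, False, False])
        assert m.auc_from_scores(scores, labels) == pytest.approx(0.75)
        assert m.auc(roc_curve_from_scores(scores, labels)) == pytest.approx(0.75)

    def test_trapezoid_equals_mann_whitney_and_oracles(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            scores, labels = _random_instance(rng)
            trap = m.auc(roc_curve_from_scores(scores, labels))
            mw = m.auc_from_scores(scores, labels)
            brute = auc_pair_count(scores, labels)
            skl = roc_auc_score(labels, -scores)
            assert trap == pytest.approx(mw, abs=1e-12)
            assert trap == pytest.approx(brute, abs=1e-12)
            assert trap == pytest.approx(skl, abs=1e-12)

    def test_orientation_flip(self):
        rng = np.random.default_rng(1)
        scores, labels = _random_instance(rng, 100)
        a = m.auc_from_scores(scores, labels)
        assert m.auc_from_scores(-scores, labels) == pytest.approx(1 - a)

    def test_null_case_near_half(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(38, 2, 4000)
        labels = rng.random(4000) < 0.3
        assert m.auc_from_scores(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_single_class_errors(self):
        with pytest.raises(InputError):
            roc_curve_from_scores(np.array([1.0, 2.0]), np.array([True, True]))


class TestCurveShape:
    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(3)
        scores, labels = _random_instance(rng, 80)
        curve = roc_curve_from_scores(scores, labels)
        sens = [p.sensitivity for p in curve.points]
        spec = [p.specificity for p in curve.points]
        assert (sens[0], spec[0]) == (0.0, 1.0)
        assert (sens[-1], spec[-1]) == (1.0, 0.0)
        assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(spec, spec[1:]))


class TestYouden:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            scores, labels = _random_instance(rng, 200)
            yj = m.youden(roc_curve_from_scores(scores, labels))
            assert yj.j == pytest.approx(youden_brute_force(scores, labels), abs=1e-12)
            assert yj.j == pytest.approx(yj.sensitivity + yj.specificity - 1.0)

    def test_orientation_leaves_j_unchanged(self):
        rng = np.random.default_rng(8)
        scores, labels = _random_instance(rng, 150)
        j_fwd = m.youden(roc_curve_from_scores(scores, labels)).j
        # reversing orientation and swapping classes yields the same curve
        j_rev = m.youden(roc_curve_from_scores(-scores, ~labels)).j
        assert j_fwd == pytest.approx(j_rev, abs=1e-12)

    def test_null_j_small(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(38, 2, 5000)
        labels = rng.random(5000) < 0.3
        assert m.youden(roc_curve_from_scores(scores, labels)).j < 0.07

    def test_separable_criterion_between_classes(self):
        curve = roc_curve_from_scores(
            np.array([33.0, 34.0, 39.0, 40.0]), np.array([True, True, False, False])
        )
        yj = m.youden(curve)
        assert 34.0 < yj.criterion <= 39.0


class TestBootstrap:
    def test_seed_reproducibility(self, holdout_predictions):
        _, p2 = holdout_predictions
        a = m.bootstrap_ci(p2, "auc", B=200, seed=20)
        b = m.bootstrap_ci(p2, "auc", B=200, seed=20)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        c = m.bootstrap_ci(p2, "auc", B=200, seed=21)
        assert (a.lower, a.upper) != (c.lower, c.upper)

    def test_degenerate_statistic_zero_width(self):
        ps = make_prediction_set(
            [33.0, 33.5, 40.0, 41.0] * 5, [30.0, 30.0, 42.0, 42.0] * 5
        )
        ci = m.bootstrap_ci(ps, "auc", B=100, seed=1)
        assert ci.lower == ci.upper == ci.estimate == 1.0

    def test_interval_contains_estimate(self, holdout_predictions):
        _, p2 = holdout_predictions
        for stat in ("auc", "youden_j"):
            ci = m.bootstrap_ci(p2, stat, B=200, seed=20)
            assert ci.lower <= ci.estimate <= ci.upper

    def test_stratified_flag_keeps_class_sizes(self, holdout_predictions):
        _, p2 = holdout_predictions
        ci = m.bootstrap_ci(p2, "auc", B=100, seed=20, stratified=True)
        assert ci.n_redraws == 0


class TestFixedOperatingPoint:
    def test_fix_sensitivity_on_separable(self):
        curve = roc_curve_from_scores(
            np.array([33.0, 34.0, 39.0, 40.0]), np.array([True, True, False, False])
        )
        op = m.fixed_operating_point(curve, "sensitivity", 0.99)
        assert op.point.specificity == 1.0

    def test_lookup_at_achieved_specificity(self):
        # 1000 positives: 807 at 33, 193 at 41; 1000 negatives: 224 at 33, 776 at 41
        scores = np.concatenate(
            [np.full(807, 33.0), np.full(193, 41.0), np.full(224, 33.0), np.full(776, 41.0)]
        )
        labels = np.concatenate([np.ones(1000, bool), np.zeros(1000, bool)])
        curve = roc_curve_from_scores(scores, labels)
        op = m.fixed_operating_point(curve, "specificity", 0.776)
        assert op.point.sensitivity == pytest.approx(0.807)

    def test_monotone_in_fixed_value(self):
        rng = np.random.default_rng(11)
        scores, labels = _random_instance(rng, 200)
        curve = roc_curve_from_scores(scores, labels)
        prev = 1.1
        for v in (0.2, 0.4, 0.6, 0.8, 0.95):
            spec = m.fixed_operating_point(curve, "sensitivity", v).point.specificity
            assert spec <= prev + 1e-12
            prev = spec

    def test_out_of_range_value(self):
        curve = roc_curve_from_scores(
            np.array([33.0, 40.0]), np.array([True, False])
        )
        with pytest.raises(InputError):
            m.fixed_operating_point(curve, "sensitivity", 1.5)


class TestCompareRoc:
    def _two_groups(self, seed, shift=0.0, n=400):
        rng = np.random.default_rng(seed)
        ga = np.where(rng.random(n) < 0.25, 34.0, 39.5)
        noise = rng.normal(0, 1.5, n)
        pred_a = ga + noise
        pred_b = ga + noise * (1.0 + shift)
        ids_a = [f"a{i}" for i in range(n)]
        ids_b = [f"b{i}" for i in range(n)]
        pa = m.PredictionSet(np.array(ids_a), ga, pred_a, np.full(n, "r1"), np.zeros(n, bool))
        pb = m.PredictionSet(np.array(ids_b), ga, pred_b, np.full(n, "r2"), np.zeros(n, bool))
        return pa, pb

    def test_identical_groups_null(self):
        pa, pb = self._two_groups(5, shift=0.0)
        cmp = m.compare_roc(pa, pb, B=300, seed=20)
        assert cmp.delta_auc == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value > 0.9

    def test_seed_reproducibility(self):
        pa, pb = self._two_groups(6, shift=1.5)
        c1 = m.compare_roc(pa, pb, B=300, seed=20)
        c2 = m.compare_roc(pa, pb, B=300, seed=20)
        assert (c1.delta_auc, c1.ci.lower, c1.ci.upper, c1.p_value) == (
            c2.delta_auc, c2.ci.lower, c2.ci.upper, c2.p_value
        )

    def test_overlapping_ids_rejected(self):
        pa, _ = self._two_groups(7)
        with pytest.raises(InputError, match="independent"):
            m.compare_roc(pa, pa, B=50, seed=20)

    def test_detects_true_difference(self):
        """Two binormal groups with different separation: CI excludes 0."""
        rng = np.random.default_rng(12)
        n = 2000

        def group(prefix, delta):
            labels = rng.random(n) < 0.3
            scores = np.where(labels, 37.0 - delta, 39.3) + rng.normal(0, 1.5, n)
            ga = np.where(labels, 34.0, 39.5)
            ids = np.array([f"{prefix}{i}" for i in range(n)])
            return m.PredictionSet(ids, ga, scores, np.full(n, prefix), np.zeros(n, bool))

        pa, pb = group("a", 2.3), group("b", 0.9)
        cmp = m.compare_roc(pa, pb, B=400, seed=20)
        assert cmp.delta_auc > 0
        assert cmp.ci.lower > 0
        assert cmp.p_value < 0.05
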