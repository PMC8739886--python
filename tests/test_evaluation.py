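"""Parcellation statistics: accuracy, Dice, boundary profiles, homogeneity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parcelgnn.evaluation import (
    accuracy,
    boundary_error_profile,
    bootstrap_se,
    consensus,
    dice,
    functional_homogeneity,
    mean_dice,
    mean_probability_maps,
    scalar_homogeneity,
)
from parcelgnn.features import TimeSeriesMatrix
from parcelgnn.labels import LabelMap
from conftest import path_graph


def _lm(vals, c=None):
    return LabelMap(np.array(vals), num_classes=c or int(max(vals)))


class TestAccuracy:
    def test_identity_and_total_disagreement(self):
        t = _lm([1, 2, 3, 1])
        assert accuracy(t, t)[0] == 100.0
        assert accuracy(_lm([2, 3, 1, 2], c=3), t)[0] == 0.0

    def test_three_of_four_correct(self):
        pred = _lm([1, 2, 3, 3])
        truth = _lm([1, 2, 3, 1])
        pct, correct = accuracy(pred, truth)
        assert pct == 75.0
        assert correct.sum() == 3

    def test_truth_unlabeled_vertices_excluded(self):
        pred = _lm([1, 2, 2], c=2)
        truth = LabelMap(np.array([1, 0, 2]), num_classes=2)
        assert accuracy(pred, truth)[0] == 100.0

    def test_invariant_under_consistent_relabeling(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(1, 5, size=40)
        truth = rng.integers(1, 5, size=40)
        perm = np.array([0, 3, 4, 1, 2])  # relabeling of codes 1..4
        a = accuracy(_lm(pred, c=4), _lm(truth, c=4))[0]
        b = accuracy(_lm(perm[pred], c=4), _lm(perm[truth], c=4))[0]
        assert a == b


class TestDice:
    def test_hand_counted_overlap(self):
        a = _lm([9, 9, 9, 9, 1, 1, 1, 1], c=9)
        b = _lm([1, 1, 9, 9, 9, 9, 1, 1], c=9)
        # area 9: J={0,1,2,3}, K={2,3,4,5} -> 2*2/(4+4)
        assert dice(a, b, 9) == 0.5

    def test_identical_and_disjoint_sets(self):
        a = _lm([1, 1, 2, 2])
        assert dice(a, a, 1) == 1.0
        b = _lm([2, 2, 1, 1])
        assert dice(a, b, 1) == 0.0

    def test_absent_area_reported_missing(self):
        a = _lm([1, 1], c=3)
        assert np.isnan(dice(a, a, 3))

    def test_mean_dice_skips_missing_areas(self):
        a = _lm([1, 1, 2, 2], c=3)
        b = _lm([1, 1, 2, 3], c=3)
        vals = [dice(a, b, k) for k in (1, 2, 3)]
        expected = np.mean([v for v in vals if not np.isnan(v)])
        assert mean_dice(a, b) == pytest.approx(expected)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(1, 3), min_size=4, max_size=12), st.integers(1, 3))
    def test_symmetry(self, labels, area):
        rng = np.random.default_rng(sum(labels))
        other = rng.integers(1, 4, size=len(labels))
        a, b = _lm(labels, c=3), _lm(other, c=3)
        x, y = dice(a, b, area), dice(b, a, area)
        assert (np.isnan(x) and np.isnan(y)) or x == y


class TestBoundaryErrorProfile:
    def test_path_with_boundary_misclassification(self):
        g = path_graph(5)
        truth = _lm([1, 1, 1, 2, 2])
        pred = _lm([1, 1, 2, 2, 2])
        profile = boundary_error_profile(pred, truth, g)
        assert profile == {0: 1.0}  # vertex 2 is itself a boundary vertex

    def test_interior_error_binned_by_hops(self):
        g = path_graph(6)
        truth = _lm([1, 1, 1, 1, 1, 2])
        pred = _lm([2, 1, 1, 1, 1, 2])
        profile = boundary_error_profile(pred, truth, g)
        assert profile == {4: 1.0}

    def test_perfect_prediction_gives_empty_profile(self):
        g = path_graph(4)
        truth = _lm([1, 1, 2, 2])
        assert boundary_error_profile(truth, truth, g) == {}

    def test_fractions_sum_to_one(self):
        g = path_graph(8)
        truth = _lm([1, 1, 1, 1, 2, 2, 2, 2])
        pred = _lm([2, 1, 2, 1, 2, 1, 2, 2])
        profile = boundary_error_profile(pred, truth, g)
        assert sum(profile.values()) == pytest.approx(1.0)

    def test_single_label_truth_rejected(self):
        g = path_graph(3)
        with pytest.raises(ValueError, match="boundar"):
            boundary_error_profile(_lm([1, 1, 1]), _lm([1, 1, 1]), g)


class TestFunctionalHomogeneity:
    def test_identical_series_within_parcel_scores_100(self):
        rng = np.random.default_rng(1)
        shared = rng.normal(size=30)
        other = rng.normal(size=30)
        ts = TimeSeriesMatrix(np.vstack([shared, shared, other, other]))
        mean, per = functional_homogeneity(ts, _lm([1, 1, 2, 2]))
        assert per[1] == pytest.approx(100.0)
        assert per[2] == pytest.approx(100.0)
        assert mean == pytest.approx(100.0)

    def test_orthogonal_equal_norm_rows_score_50(self):
        # two parcel vertices whose cortex-correlation rows are orthogonal
        # with equal norm -> equal singular values -> 50%
        t = 400000  # long series so empirical correlations are near-exact
        rng = np.random.default_rng(2)
        a = rng.standard_normal(t)
        b = rng.standard_normal(t)
        ts = TimeSeriesMatrix(np.vstack([a, b, a, b]))
        _, per = functional_homogeneity(ts, _lm([1, 1, 2, 2]))
        assert per[1] == pytest.approx(50.0, abs=0.5)

    def test_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(6, 40))
        parcels = _lm([1, 1, 1, 2, 2, 2])
        _, per = functional_homogeneity(TimeSeriesMatrix(values), parcels)
        corr = np.corrcoef(values)  # vertex x vertex Pearson
        for area, members in ((1, [0, 1, 2]), (2, [3, 4, 5])):
            s = np.linalg.svd(corr[members], compute_uv=False)
            expected = 100.0 * s[0] ** 2 / (s**2).sum()
            assert per[area] == pytest.approx(expected, abs=1e-8)

    def test_singleton_parcel_flagged_100(self):
        rng = np.random.default_rng(4)
        ts = TimeSeriesMatrix(rng.normal(size=(3, 20)))
        with pytest.warns(UserWarning, match="single vertex"):
            _, per = functional_homogeneity(ts, _lm([1, 2, 2]))
        assert per[1] == 100.0

    def test_range_bounds(self):
        rng = np.random.default_rng(5)
        ts = TimeSeriesMatrix(rng.normal(size=(10, 30)))
        mean, per = functional_homogeneity(ts, _lm([1, 1, 1, 1, 1, 2, 2, 2, 2, 2]))
        assert 0 < mean <= 100
        assert all(0 < v <= 100 for v in per.values())


class TestScalarHomogeneity:
    def test_hand_computed_ratio(self):
        feature = np.array([0.0, 2.0, 10.0, 12.0])
        parcels = _lm([1, 1, 2, 2])
        assert scalar_homogeneity(feature, parcels) == pytest.approx(0.04)

    def test_constant_within_parcels_gives_zero(self):
        feature = np.array([3.0, 3.0, 8.0, 8.0])
        assert scalar_homogeneity(feature, _lm([1, 1, 2, 2])) == 0.0

    def test_scale_and_shift_invariance(self):
        rng = np.random.default_rng(6)
        feature = rng.normal(size=12)
        parcels = _lm(list(np.repeat([1, 2, 3], 4)))
        base = scalar_homogeneity(feature, parcels)
        assert scalar_homogeneity(feature * 7.3, parcels) == pytest.approx(base)
        assert scalar_homogeneity(feature + 100.0, parcels) == pytest.approx(base)

    def test_identical_parcel_means_reported_missing(self):
        feature = np.array([1.0, -1.0, 1.0, -1.0])
        assert np.isnan(scalar_homogeneity(feature, _lm([1, 1, 2, 2])))


class TestConsensus:
    def test_unanimous_predictions(self):
        maps = [_lm([1, 2, 3])] * 3
        assert consensus(maps) == maps[0]

    def test_majority_vote(self):
        maps = [_lm([5, 1], c=9), _lm([5, 1], c=9), _lm([9, 1], c=9)]
        np.testing.assert_array_equal(consensus(maps).labels, [5, 1])

    def test_tie_broken_by_smallest_code(self):
        maps = [_lm([5], c=9), _lm([9], c=9)]
        assert consensus(maps).labels[0] == 5


class TestMeanProbabilityMaps:
    def test_single_subject_identity_threshold_zero(self):
        p = np.array([[0.7, 0.3], [0.2, 0.8]])
        np.testing.assert_array_equal(mean_probability_maps([p], threshold=0.0), p)

    def test_default_threshold_is_uniform_probability(self):
        p = np.array([[0.996, 0.004], [0.6, 0.4]])
        out = mean_probability_maps([p])  # 1/C = 0.5
        assert out[0, 1] == 0.0
        assert out[1, 0] == 0.6 and out[1, 1] == 0.0

    def test_agreeing_one_hot_stacks(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_array_equal(mean_probability_maps([p, p], threshold=0.0), p)

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            mean_probability_maps([np.array([[0.5, 0.2]])])


class TestBootstrapSE:
    def test_constant_accuracies_give_zero(self):
        assert bootstrap_se([80.0, 80.0, 80.0], reps=100, seed=0) == 0.0

    def test_seeded_determinism(self):
        accs = [60.0, 70.0, 80.0]
        assert bootstrap_se(accs, seed=5) == bootstrap_se(accs, seed=5)

    def test_matches_analytic_bootstrap_variance(self):
        accs = [60.0, 70.0, 80.0]
        se = bootstrap_se(accs, sample_size=3, reps=10000, seed=1)
        pop_var = np.var(accs)  # bootstrap resamples the empirical distribution
        expected = np.sqrt(pop_var / 3)
        assert se == pytest.approx(expected, rel=0.02)
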