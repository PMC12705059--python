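import numpy as np
import pytest

from comorbmtl import (RobustnessProfile, classify_markers, cv_subject_errors,
                       display_filter, lambda_max, loco_cv, rank_models,
                       refit_development, robustness_path, selected_features)
from comorbmtl.model_selection import (TAG_DISCRIMINATOR, TAG_MARKER,
                                       TAG_NEVER, TAG_UNSTABLE)
from comorbmtl.mtl_core import TaskCollection, TaskData
from comorbmtl.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="module")
def dev_data():
    cfg = SimConfig(n_subjects=320, n_features=15, n_centers=4,
                    effect_size=0.5, seed=21)
    data, truth = generate_dataset(cfg)
    return data, truth


class TestLocoCv:
    def test_one_fold_per_center_with_exact_partition(self, dev_data):
        data, _ = dev_data
        cv = loco_cv(data, np.array([0.1, 0.3]))
        assert len(cv.fold_centers) == 4
        assert sorted(cv.fold_centers) == sorted(np.unique(data.tasks[0].centers))
        assert cv.fold_errors.shape == (2, 4, 2)

    def test_grid_beyond_lambda_max_has_no_admissible_model(self, dev_data):
        data, _ = dev_data
        # standardized outcomes keep lambda_max near the gradient scale;
        # a grid far above it selects nothing anywhere
        with pytest.raises(ValueError, match="admissible"):
            loco_cv(data, np.array([50.0, 80.0]))

    def test_selection_minimizes_mean_mse_among_admissible(self, dev_data):
        data, _ = dev_data
        cv = loco_cv(data)
        idx = np.flatnonzero(np.isclose(cv.lambda_grid, cv.selected_lambda))[0]
        assert cv.admissible[idx]
        assert cv.mean_mse[idx] == pytest.approx(np.min(cv.mean_mse[cv.admissible]))

    def test_bitwise_reproducible(self, dev_data):
        data, _ = dev_data
        grid = np.array([0.05, 0.2, 0.5])
        a, b = loco_cv(data, grid), loco_cv(data, grid)
        np.testing.assert_array_equal(a.fold_errors, b.fold_errors)
        assert a.selected_lambda == b.selected_lambda

    def test_center_with_one_subject_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        centers = np.array(["a", "a", "b", "b", "c"])
        data = TaskCollection([TaskData(X, rng.standard_normal(5), "t", centers)])
        with pytest.raises(ValueError, match="fewer than 2"):
            loco_cv(data, np.array([0.1]))

    def test_planted_support_contained_in_selection(self, dev_data):
        data, truth = dev_data
        cv = loco_cv(data)
        model = refit_development(data, cv.selected_lambda)
        sel = set(selected_features(model.model).tolist())
        assert set(truth.support.tolist()) <= sel


class TestSubjectErrors:
    def test_every_subject_scored_exactly_once(self, dev_data):
        data, _ = dev_data
        errs = cv_subject_errors(data, 0.2)
        assert errs.shape == (2, data.tasks[0].n)
        assert np.all(np.isfinite(errs)) and np.all(errs >= 0)


class TestRankModels:
    def test_orders_by_selected_mse_and_truncates(self, dev_data):
        data, _ = dev_data
        grid = np.array([0.1, 0.4])
        results = []
        for label in ("c", "a", "b"):
            r = loco_cv(data, grid, label=label)
            results.append(r)
        # fabricate distinct MSEs to check ordering determinism
        results[0].mean_mse = results[0].mean_mse + 0.2
        top = rank_models(results, top_k=2)
        assert len(top) == 2
        assert top[0].selected_mse <= top[1].selected_mse

    def test_single_candidate_and_overlong_topk(self, dev_data):
        data, _ = dev_data
        r = loco_cv(data, np.array([0.1]))
        assert rank_models([r], top_k=1) == [r]
        with pytest.warns(RuntimeWarning):
            out = rank_models([r], top_k=3)
        assert out == [r]


def make_profile(selected, signs, start_weights=None):
    n_lambda, p = selected.shape
    t = signs.shape[2]
    if start_weights is None:
        start_weights = signs[0].astype(float)
    return RobustnessProfile(np.linspace(0.1, 0.1 + 0.01 * (n_lambda - 1), n_lambda),
                             selected, signs, start_weights,
                             [f"f{j}" for j in range(p)],
                             [f"t{i}" for i in range(t)])


class TestClassification:
    def test_sign_patterns_map_to_tags(self):
        selected = np.array([[True, True, True, False],
                             [True, True, True, False]])
        signs = np.zeros((2, 4, 2), dtype=np.int8)
        signs[:, 0] = [1, 1]                     # always same sign
        signs[:, 1] = [1, -1]                    # always opposing
        signs[0, 2] = [1, 1]; signs[1, 2] = [1, -1]  # flips: unstable
        profile = make_profile(selected, signs)
        assert classify_markers(profile) == [TAG_MARKER, TAG_DISCRIMINATOR,
                                             TAG_UNSTABLE, TAG_NEVER]

    def test_exact_zero_weight_while_selected_is_unstable(self):
        selected = np.array([[True]])
        signs = np.array([[[1, 0]]], dtype=np.int8)
        assert classify_markers(make_profile(selected, signs)) == [TAG_UNSTABLE]


class TestRobustnessPath:
    def test_single_point_path_counts_in_01(self, dev_data):
        data, _ = dev_data
        profile = robustness_path(data, 0.3, end_lambda=0.3)
        assert profile.lambda_path.size == 1
        assert set(np.unique(profile.selection_counts)) <= {0, 1}

    def test_path_is_start_step_sequence(self, dev_data):
        data, _ = dev_data
        profile = robustness_path(data, 0.9, step=0.01, end_lambda=0.99)
        np.testing.assert_allclose(profile.lambda_path,
                                   np.round(np.arange(0.9, 1.0, 0.01), 10))

    def test_planted_features_outlast_null_features(self, dev_data):
        data, truth = dev_data
        cv = loco_cv(data)
        profile = robustness_path(data, cv.selected_lambda)
        counts = profile.selection_counts
        planted = truth.support
        null = np.setdiff1d(np.arange(data.p), planted)
        assert counts[planted].min() > counts[null].max()

    def test_support_shrinks_along_the_path(self, dev_data):
        data, _ = dev_data
        cv = loco_cv(data)
        profile = robustness_path(data, cv.selected_lambda)
        sizes = profile.selected.sum(axis=1)
        assert sizes[-1] <= sizes[0]

    def test_invalid_path_bounds_rejected(self, dev_data):
        data, _ = dev_data
        with pytest.raises(ValueError):
            robustness_path(data, 0.5, end_lambda=0.4)
        with pytest.raises(ValueError):
            robustness_path(data, 0.0)


class TestDisplayFilter:
    def test_dual_ten_percent_rule(self):
        selected = np.ones((10, 3), dtype=bool)
        selected[1:, 1] = False   # feature 1: fraction 0.1
        selected[:, 2] = False
        selected[0, 2] = True     # feature 2: fraction 0.1 but tiny weight
        signs = np.ones((10, 3, 2), dtype=np.int8)
        W = np.array([[1.0, 0.5], [0.2, 0.1], [0.05, 0.01]])
        profile = make_profile(selected, signs, start_weights=W)
        kept = display_filter(profile)
        assert 0 in kept            # most robust, biggest weight
        assert 1 in kept            # fraction exactly 0.10, weight 20% of max
        assert 2 not in kept        # weight below 10% of max

    def test_low_fraction_dropped_regardless_of_weight(self):
        selected = np.zeros((20, 2), dtype=bool)
        selected[:, 0] = True
        selected[0, 1] = True       # fraction 0.05
        signs = np.ones((20, 2, 2), dtype=np.int8)
        W = np.array([[1.0, 1.0], [5.0, 5.0]])
        kept = display_filter(make_profile(selected, signs, start_weights=W))
        assert 1 not in kept
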