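"""Isolation forest scoring vs brute-force oracles; LOF/EE comparator contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurotask.detectors import (
    EULER_GAMMA,
    IsolationForestModel,
    IsolationTree,
    anomaly_score,
    average_path_length,
    build_iforest,
    decide,
    ee_scores,
    forest_from_json,
    forest_scores,
    forest_to_json,
    lof_scores,
    path_length,
)


def brute_force_path(point, node, depth=0):
    """Independent recursive traversal oracle."""
    if node.is_external:
        return depth + average_path_length(node.size)
    if point[node.split_attribute] < node.split_value:
        return brute_force_path(point, node.left, depth + 1)
    return brute_force_path(point, node.right, depth + 1)


class TestAveragePathLength:
    def test_boundary_conventions(self):
        assert average_path_length(0) == 0.0
        assert average_path_length(1) == 0.0
        with pytest.raises(ValueError):
            average_path_length(-1)

    def test_small_values(self):
        assert average_path_length(2) == pytest.approx(2 * EULER_GAMMA - 1,
                                                       abs=1e-12)
        assert average_path_length(256) == pytest.approx(10.2448, abs=1e-3)

    @given(st.integers(min_value=101, max_value=10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_close_to_exact_harmonic_form(self, n):
        # the ln + gamma approximation of the harmonic number is only
        # accurate for large arguments (error ~ 1/n); sub-sample sizes in
        # practice are >= 100, where agreement is within 0.01
        exact = 2 * np.sum(1.0 / np.arange(1, n)) - 2 * (n - 1) / n
        assert abs(average_path_length(n) - exact) < 0.01


class TestForestConstruction:
    def test_protocol_configuration(self, rng):
        data = rng.standard_normal((1000, 5))
        forest = build_iforest(data, n_trees=150, psi=256, seed=0)
        assert forest.n_trees == 150
        assert all(sum(t.external_sizes()) == 256 for t in forest.trees)

    def test_psi_two_single_split(self, rng):
        data = rng.standard_normal((50, 2))
        forest = build_iforest(data, n_trees=10, psi=2, seed=1)
        for tree in forest.trees:
            if tree.is_external:
                continue  # duplicate pair
            assert tree.left.is_external and tree.right.is_external

    def test_deterministic_forests(self, rng):
        data = rng.standard_normal((100, 3))
        a = build_iforest(data, 20, 32, seed=7)
        b = build_iforest(data, 20, 32, seed=7)
        pts = rng.standard_normal((10, 3))
        assert np.array_equal(forest_scores(a, pts), forest_scores(b, pts))

    def test_constant_data_collapses_to_roots(self):
        data = np.ones((20, 3))
        forest = build_iforest(data, 5, 16, seed=0)
        assert all(t.is_external for t in forest.trees)


class TestPathLength:
    def test_hand_built_tree(self):
        # 1-D points {0, 1, 10}: split at 5, then 0.5
        tree = IsolationTree(
            split_attribute=0, split_value=5.0,
            left=IsolationTree(split_attribute=0, split_value=0.5,
                               left=IsolationTree(size=1),
                               right=IsolationTree(size=1),
                               size=2),
            right=IsolationTree(size=1),
            size=3, height_limit=8,
        )
        assert path_length(np.array([10.0]), tree) == 1.0
        assert path_length(np.array([0.0]), tree) == 2.0

    def test_truncated_node_adjustment(self):
        tree = IsolationTree(split_attribute=0, split_value=0.0,
                             left=IsolationTree(size=4),
                             right=IsolationTree(size=1),
                             size=5, height_limit=1)
        assert path_length(np.array([-1.0]), tree) == pytest.approx(
            1.0 + average_path_length(4))

    def test_single_external_root(self):
        assert path_length(np.array([1.0]), IsolationTree(size=1)) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        data = rng.standard_normal((64, 2))
        for psi in (2, 4, 8):
            forest = build_iforest(data, n_trees=25, psi=psi, seed=psi)
            for point in rng.standard_normal((20, 2)):
                for tree in forest.trees:
                    assert path_length(point, tree) == brute_force_path(point,
                                                                        tree)


class TestAnomalyScore:
    def test_fixed_points_of_score_formula(self):
        # one tree, all psi points in the root: E[l] = alpha(psi) -> A = 0.5
        forest = IsolationForestModel([IsolationTree(size=16)], psi=16)
        assert anomaly_score(np.zeros(1), forest).score == 0.5
        # isolated immediately: E[l] = 0 -> A = 1
        forest1 = IsolationForestModel([IsolationTree(size=1)], psi=16)
        assert anomaly_score(np.zeros(1), forest1).score == 1.0

    def test_score_decreasing_in_path_length(self):
        trees = [IsolationTree(size=k) for k in (1, 2, 4, 8, 16)]
        scores = [anomaly_score(np.zeros(1),
                                IsolationForestModel([t], psi=16)).score
                  for t in trees]
        assert all(a > b for a, b in zip(scores, scores[1:]))
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_far_point_outscores_center(self):
        for seed in range(20):
            gen = np.random.default_rng(seed)
            data = gen.standard_normal((500, 1))
            forest = build_iforest(data, n_trees=150, psi=256, seed=seed)
            far = anomaly_score(np.array([10.0]), forest).score
            center = anomaly_score(np.array([0.0]), forest).score
            assert far > center

    def test_tiny_psi_normalizer_rejected(self):
        forest = IsolationForestModel([IsolationTree(size=1)], psi=1)
        with pytest.raises(ValueError):
            anomaly_score(np.zeros(1), forest)


class TestDecide:
    @pytest.mark.parametrize("score,expected", [
        (0.9, "anomaly"),
        (0.1, "normal"),
        (0.5, "uncertain"),
    ])
    def test_threshold_rule(self, score, expected):
        assert decide(score, threshold=0.5, uncertain_band=0.05) == expected

    def test_zero_band_is_binary(self):
        assert decide(0.5001) == "anomaly"
        assert decide(0.4999) == "normal"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            decide(1.2)
        with pytest.raises(ValueError):
            decide(0.5, threshold=1.0)


class TestComparators:
    def test_lof_near_one_inside_grid(self):
        xx, yy = np.meshgrid(np.arange(10.0), np.arange(10.0))
        train = np.column_stack([xx.ravel(), yy.ravel()])
        deep = lof_scores(train, np.array([[4.5, 4.5]]), n_neighbors=8)
        assert 0.9 <= deep[0] <= 1.1

    def test_lof_flags_isolated_point(self, rng):
        train = rng.standard_normal((200, 2))
        scores = lof_scores(train, np.array([[8.0, 8.0], [0.0, 0.0]]),
                            n_neighbors=35)
        assert scores[0] > 1.5
        assert scores[0] > scores[1]

    def test_lof_neighbor_count_validated(self, rng):
        with pytest.raises(ValueError):
            lof_scores(rng.standard_normal((10, 2)),
                       np.zeros((1, 2)), n_neighbors=10)

    def test_ee_zero_at_robust_center(self, rng):
        train = rng.standard_normal((300, 3))
        from sklearn.covariance import MinCovDet
        center = MinCovDet(support_fraction=0.9, random_state=0
                           ).fit(train).location_
        assert ee_scores(train, center[None], 0.9)[0] == pytest.approx(0.0,
                                                                       abs=1e-8)

    def test_ee_robust_to_gross_outliers(self):
        hits = 0
        for seed in range(20):
            gen = np.random.default_rng(seed)
            inliers = gen.standard_normal((190, 2))
            gross = gen.standard_normal((10, 2)) + 25.0
            data = np.vstack([inliers, gross])
            from sklearn.covariance import MinCovDet
            robust = MinCovDet(support_fraction=0.9, random_state=seed
                               ).fit(data).location_
            plain = data.mean(axis=0)
            hits += np.linalg.norm(robust) < np.linalg.norm(plain)
        assert hits >= 18  # >= 90% of seeds

    def test_ee_isotropic_matches_distance_order(self, rng):
        train = rng.standard_normal((500, 2))
        test = rng.standard_normal((30, 2)) * 3
        scores = ee_scores(train, test, 0.9)
        dists = np.linalg.norm(test - train.mean(axis=0), axis=1)
        assert abs(np.corrcoef(np.argsort(np.argsort(scores)),
                               np.argsort(np.argsort(dists)))[0, 1]) > 0.95


class TestDetectorsSeparateOutlier:
    def test_all_three_rank_planted_outlier_first(self, rng):
        train = rng.standard_normal((300, 4))
        inliers = rng.standard_normal((20, 4))
        outlier = np.full((1, 4), 12.0)
        test = np.vstack([inliers, outlier])

        forest = build_iforest(train, 100, 128, seed=0)
        for scores in (
            forest_scores(forest, test),
            lof_scores(train, test, 35),
            ee_scores(train, test, 0.9),
        ):
            assert np.argmax(scores) == 20  # AUC = 1 on this fixture


def test_forest_json_round_trip(rng, tmp_path):
    data = rng.standard_normal((60, 3))
    forest = build_iforest(data, 12, 16, seed=5)
    path = str(tmp_path / "forest.json")
    forest_to_json(forest, path)
    back = forest_from_json(path)
    pts = rng.standard_normal((15, 3))
    assert np.array_equal(forest_scores(forest, pts), forest_scores(back, pts))
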