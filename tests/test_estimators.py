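import numpy as np
import pytest

import mesoconn as mc
from mesoconn.estimators import class_leaf_mean, el_predict, nnls_fit, nw_predict

from conftest import make_experiment


def _brute_nw(loc, centroids, Y, sigma):
    w = np.array([np.exp(-0.5 * (np.linalg.norm(c - loc) / sigma) ** 2) for c in centroids])
    return sum(wi * yi for wi, yi in zip(w, Y)) / w.sum()


class TestClassSpace:
    def test_identical_projections_give_zero_distance(self, small_brain):
        _, ont = small_brain
        y = np.arange(1.0, ont.n_targets + 1)
        exps = [make_experiment(ont, f"e{i}", v, (i, 0, 0), y)
                for i, v in enumerate(["a", "a", "b", "b"])]
        space = mc.build_class_space(mc.Dataset(exps, ont))
        assert space.distance("a", "b") == pytest.approx(0.0, abs=1e-12)
        assert space.distance("a", "a") == 0.0

    def test_orthogonal_means_have_unit_cosine_distance(self, small_brain):
        _, ont = small_brain
        ya = np.zeros(ont.n_targets); ya[0] = 1.0
        yb = np.zeros(ont.n_targets); yb[1] = 1.0
        exps = [make_experiment(ont, "a0", "a", (0, 0, 0), ya),
                make_experiment(ont, "b0", "b", (1, 0, 0), yb)]
        space = mc.build_class_space(mc.Dataset(exps, ont))
        assert space.distance("a", "b") == pytest.approx(1.0)

    def test_distances_match_bruteforce_pairwise_formula(self, noisy_dataset):
        space = mc.build_class_space(noisy_dataset)
        d = noisy_dataset
        for v in d.classes:
            for w in d.classes:
                mv = d.Y[d.of_class(v)].mean(axis=0)
                mw = d.Y[d.of_class(w)].mean(axis=0)
                expected = 1.0 - mv @ mw / (np.linalg.norm(mv) * np.linalg.norm(mw))
                assert space.distance(v, w) == pytest.approx(max(expected, 0.0), abs=1e-12)
                assert space.distance(v, w) == space.distance(w, v)


class TestNWPredict:
    def test_single_support_returns_its_projection(self):
        y = np.array([[1.0, 2.0, 3.0]])
        c = np.array([[0.0, 0.0, 0.0]])
        for sigma in (1.0, 100.0, 1e6):
            assert np.allclose(nw_predict(np.array([500.0, 0, 0]), c, y, sigma), y[0])

    def test_equidistant_pair_gives_componentwise_mean(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        C = np.array([[0.0, 0, 0], [200.0, 0, 0]])
        pred = nw_predict(np.array([100.0, 0, 0]), C, Y, 150.0)
        assert np.allclose(pred, [0.5, 0.5])

    def test_matches_bruteforce_weighted_average(self):
        rng = np.random.default_rng(21)
        C = rng.uniform(0, 1000, size=(10, 3))
        Y = rng.random((10, 6))
        loc = rng.uniform(0, 1000, size=3)
        assert np.allclose(nw_predict(loc, C, Y, 250.0), _brute_nw(loc, C, Y, 250.0), atol=1e-12)

    def test_empty_support_is_missing_not_exception(self):
        assert nw_predict(np.zeros(3), np.empty((0, 3)), np.empty((0, 4)), 100.0) is None

    def test_prediction_within_support_bounds(self):
        rng = np.random.default_rng(22)
        C, Y = rng.uniform(0, 500, (8, 3)), rng.random((8, 5))
        pred = nw_predict(rng.uniform(0, 500, 3), C, Y, 80.0)
        assert np.all(pred >= Y.min(axis=0) - 1e-12)
        assert np.all(pred <= Y.max(axis=0) + 1e-12)

    def test_huge_bandwidth_limit_is_unweighted_mean(self):
        rng = np.random.default_rng(23)
        C, Y = rng.uniform(0, 500, (8, 3)), rng.random((8, 5))
        pred = nw_predict(rng.uniform(0, 500, 3), C, Y, 1e12)
        assert np.allclose(pred, Y.mean(axis=0), atol=1e-9)

    def test_tiny_bandwidth_localizes_to_nearest_centroid(self):
        rng = np.random.default_rng(24)
        C, Y = rng.uniform(0, 500, (8, 3)), rng.random((8, 5))
        pred = nw_predict(C[3], C, Y, 1e-6)
        assert np.allclose(pred, Y[3], atol=1e-9)


class TestCreNW:
    def _dataset(self, ont):
        rng = np.random.default_rng(31)
        exps = []
        for i in range(8):
            v = "a" if i % 2 == 0 else "b"
            exps.append(make_experiment(ont, f"e{i}", v, (i % 3, i % 3, i % 3),
                                        rng.random(ont.n_targets)))
        return mc.Dataset(exps, ont)

    def test_single_class_experiment_returned_exactly(self, small_brain):
        _, ont = small_brain
        y = np.arange(1.0, ont.n_targets + 1)
        exps = [make_experiment(ont, "e0", "a", (0, 0, 0), y),
                make_experiment(ont, "e1", "b", (1, 1, 1), 2 * y)]
        d = mc.Dataset(exps, ont)
        pred = mc.cre_nw_predict(np.array([250.0, 250.0, 250.0]), "a", d, 100.0)
        assert np.allclose(pred, y)

    def test_class_absent_from_leaf_is_missing(self, small_brain):
        _, ont = small_brain
        d = self._dataset(ont)
        assert mc.cre_nw_predict(np.array([150.0, 150.0, 150.0]), "zz", d, 100.0) is None

    def test_equals_nw_on_manually_filtered_support(self, small_brain):
        _, ont = small_brain
        d = self._dataset(ont)
        loc = np.array([140.0, 160.0, 130.0])
        leaf = ont.leaf_at(loc)
        mask = d.in_leaf(leaf) & d.of_class("a")
        expected = _brute_nw(loc, d.centroids[mask], d.Y[mask], 120.0)
        assert np.allclose(mc.cre_nw_predict(loc, "a", d, 120.0), expected, atol=1e-12)


class TestEL:
    def _dataset(self, ont):
        rng = np.random.default_rng(41)
        exps = []
        for i in range(6):  # all in the first leaf block (voxels 0..2)
            v = ["a", "a", "b", "b", "c", "c"][i]
            exps.append(make_experiment(ont, f"e{i}", v,
                                        (rng.integers(0, 3), rng.integers(0, 3), rng.integers(0, 3)),
                                        rng.random(ont.n_targets)))
        return mc.Dataset(exps, ont)

    def test_alpha_one_is_class_leaf_mean(self, small_brain):
        _, ont = small_brain
        d = self._dataset(ont)
        space = mc.build_class_space(d)
        loc = np.array([150.0, 150.0, 150.0])
        leaf = ont.leaf_at(loc)
        pred = el_predict(loc, "a", d, space, 100.0, 1.0, alpha=1.0)
        assert np.allclose(pred, class_leaf_mean(d, space, "a", leaf), atol=1e-12)

    def test_alpha_zero_large_class_bandwidth_equals_class_agnostic_nw(self, small_brain):
        _, ont = small_brain
        d = self._dataset(ont)
        space = mc.build_class_space(d)
        loc = np.array([150.0, 150.0, 150.0])
        leaf = ont.leaf_at(loc)
        mask = d.in_leaf(leaf)
        expected = _brute_nw(loc, d.centroids[mask], d.Y[mask], 200.0)
        pred = el_predict(loc, "a", d, space, 200.0, 1e12, alpha=0.0)
        assert np.allclose(pred, expected, atol=1e-9)

    def test_half_blend_equals_hand_composed_average(self, small_brain):
        _, ont = small_brain
        d = self._dataset(ont)
        space = mc.build_class_space(d)
        loc = np.array([120.0, 180.0, 140.0])
        leaf = ont.leaf_at(loc)
        mask = d.in_leaf(leaf)
        # oracle: both terms composed by hand
        m = d.Y[mask & d.of_class("a")].mean(axis=0)
        dx = np.linalg.norm(d.centroids[mask] - loc, axis=1)
        dc = np.array([space.distance("a", w) for w in d.cell_class[mask]])
        w = np.exp(-0.5 * ((dx / 150.0) ** 2 + (dc / 0.5) ** 2))
        g = (w[:, None] * d.Y[mask]).sum(axis=0) / w.sum()
        expected = 0.5 * m + 0.5 * g
        pred = el_predict(loc, "a", d, space, 150.0, 0.5, alpha=0.5)
        assert np.allclose(pred, expected, atol=1e-12)

    def test_small_class_bandwidth_concentrates_on_same_class(self, small_brain):
        _, ont = small_brain
        d = self._dataset(ont)
        space = mc.build_class_space(d)
        loc = np.array([150.0, 150.0, 150.0])
        pred = el_predict(loc, "a", d, space, 200.0, 1e-9, alpha=0.0)
        expected = mc.cre_nw_predict(loc, "a", d, 200.0)
        assert np.allclose(pred, expected, atol=1e-9)

    def test_empty_leaf_is_missing(self, small_brain):
        _, ont = small_brain
        d = self._dataset(ont)
        space = mc.build_class_space(d)
        # last leaf block has no experiments
        loc = np.array([1050.0, 150.0, 150.0])
        assert el_predict(loc, "a", d, space, 100.0, 1.0, alpha=0.3) is None

    def test_prediction_within_componentwise_hull(self, small_brain):
        _, ont = small_brain
        d = self._dataset(ont)
        space = mc.build_class_space(d)
        loc = np.array([150.0, 150.0, 150.0])
        leaf = ont.leaf_at(loc)
        mask = d.in_leaf(leaf)
        pred = el_predict(loc, "a", d, space, 100.0, 0.7, alpha=0.4)
        pool = np.vstack([d.Y[mask], class_leaf_mean(d, space, "a", leaf)])
        assert np.all(pred >= pool.min(axis=0) - 1e-12)
        assert np.all(pred <= pool.max(axis=0) + 1e-12)
        assert np.all(pred >= 0)


class TestNNLS:
    def test_identity_design_recovers_targets(self):
        X = np.eye(3)
        Y = np.array([[1.0, 2.0], [0.5, 0.0], [3.0, 1.0]])
        assert np.allclose(nnls_fit(X, Y), Y)

    def test_noiseless_recovery_of_planted_weights(self):
        rng = np.random.default_rng(51)
        X = rng.random((20, 4))
        W_true = rng.random((4, 5))
        assert np.allclose(nnls_fit(X, X @ W_true), W_true, atol=1e-8)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            nnls_fit(np.eye(2), np.array([[1.0, -0.1], [0.0, 1.0]]))

    def test_dead_source_column_yields_zero_row(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0]])
        Y = np.array([[1.0], [2.0]])
        W = nnls_fit(X, Y)
        assert np.allclose(W[1], 0.0)


def test_model_serialization_roundtrip():
    model = mc.EstimatorModel(kind="el",
                              sigma_x={100: 300.0, None: 200.0},
                              sigma_c={100: 1.0, None: 1.0},
                              alpha={(100, "wt"): 0.5, None: 0.5})
    again = mc.EstimatorModel.from_json(model.to_json())
    assert again.kind == "el"
    assert again.sigma_x == model.sigma_x
    assert again.alpha == model.alpha
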