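"""Connectome CNN: layer arithmetic, training protocol, saliency and
occlusion."""

import numpy as np
import pytest

import metanet as mn
from metanet.classifier import (
    CNNConfig,
    ConnectomeCNN,
    _softmax,
    chance_level,
    consensus_mask,
    e2e_layer,
    e2n_layer,
    evaluate,
    guided_backprop_saliency,
    n2g_layer,
    occlude_and_evaluate,
    per_class_occlusion,
)
from metanet.cohort import synthetic_matrix_classes

REDUCED = dict(e2e_maps=8, e2n_maps=16, n2g_maps=32, fc_sizes=(32, 16))


class TestLayerPrimitives:
    def test_e2e_one_hot_row_filter_copies_column(self, rng):
        X = rng.normal(size=(2, 6, 6, 1))
        r = np.zeros((6, 1, 1))
        r[0, 0, 0] = 1.0
        s = np.zeros((6, 1, 1))
        Y = e2e_layer(X, r, s, np.zeros(1))
        for j in range(6):
            assert np.allclose(Y[:, :, j, 0], X[:, :, 0, 0])

    def test_e2e_hand_computed_two_by_two(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])[None, :, :, None]
        r = np.ones((2, 1, 1))
        s = np.ones((2, 1, 1))
        Y = e2e_layer(X, r, s, np.zeros(1))[0, :, :, 0]
        # Y(i,j) = row_i sum + col_j sum
        rows = np.array([3.0, 7.0])
        cols = np.array([4.0, 6.0])
        assert np.allclose(Y, rows[:, None] + cols[None, :])
        assert Y[0, 0] == 7.0

    def test_e2e_linearity(self, rng):
        X = rng.normal(size=(3, 5, 5, 2))
        Z = rng.normal(size=(3, 5, 5, 2))
        r = rng.normal(size=(5, 2, 4))
        s = rng.normal(size=(5, 2, 4))
        b = np.zeros(4)
        lhs = e2e_layer(2.0 * X + 3.0 * Z, r, s, b)
        rhs = 2.0 * e2e_layer(X, r, s, b) + 3.0 * e2e_layer(Z, r, s, b)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_e2n_ones_weights_give_row_sums(self, rng):
        X = rng.normal(size=(2, 6, 6, 1))
        n = e2n_layer(X, np.ones((6, 1, 1)), np.zeros(1))
        assert np.allclose(n[:, :, 0], X[:, :, :, 0].sum(axis=2), atol=1e-12)

    def test_e2n_zero_weights_give_bias(self, rng):
        X = rng.normal(size=(2, 6, 6, 3))
        bias = np.array([1.5, -2.0])
        n = e2n_layer(X, np.zeros((6, 3, 2)), bias)
        assert np.allclose(n, np.broadcast_to(bias, (2, 6, 2)))

    def test_e2n_matches_einsum_oracle(self, rng):
        X = rng.normal(size=(4, 5, 5, 3))
        w = rng.normal(size=(5, 3, 2))
        expected = np.einsum("bikc,kco->bio", X, w)
        assert np.allclose(e2n_layer(X, w, np.zeros(2)), expected, atol=1e-10)

    def test_n2g_reductions(self, rng):
        n = rng.normal(size=(3, 6, 2))
        ones = np.ones((6, 2, 1))
        assert np.allclose(n2g_layer(n, ones, np.zeros(1))[:, 0],
                           n.sum(axis=(1, 2)), atol=1e-12)
        bias = np.array([0.7])
        assert np.allclose(n2g_layer(n, np.zeros((6, 2, 1)), bias), 0.7)
        v = rng.normal(size=(6, 2, 4))
        assert np.allclose(n2g_layer(n, v, np.zeros(4)),
                           np.einsum("bic,ico->bo", n, v), atol=1e-10)

    def test_shape_validation(self, rng):
        with pytest.raises(ValueError):
            e2e_layer(rng.normal(size=(1, 4, 5, 1)), np.ones((4, 1, 1)),
                      np.ones((4, 1, 1)), np.zeros(1))
        with pytest.raises(ValueError):
            e2n_layer(rng.normal(size=(1, 4, 4, 2)), np.ones((4, 1, 1)), np.zeros(1))


@pytest.fixture(scope="module")
def separable_run():
    """Shared training run on well-separated dense classes."""
    X, y = synthetic_matrix_classes(50, separation=5.0, noise_sd=0.02, seed=1)
    cfg = CNNConfig(seed=0, **REDUCED)
    return X, y, mn.train_classifier(X, y, cfg)


@pytest.fixture(scope="module")
def sparse_run():
    """Training run where each class differs only on a few connections
    (the regime where saliency-guided occlusion is meaningful)."""
    X, y = synthetic_matrix_classes(50, separation=8.0, noise_sd=0.02,
                                    sparse_edges=10, seed=1)
    cfg = CNNConfig(seed=0, **REDUCED)
    return X, y, mn.train_classifier(X, y, cfg)


class TestTraining:
    def test_separable_classes_classified_accurately(self, separable_run):
        _, _, res = separable_run
        assert res.mean_accuracy >= 0.90
        assert res.confusion.shape == (8, 8)
        assert np.allclose(res.confusion.sum(axis=1), 1.0)

    def test_shuffled_labels_fall_to_chance(self):
        X, y = synthetic_matrix_classes(25, separation=5.0, noise_sd=0.02, seed=1)
        rng = np.random.default_rng(0)
        res = mn.train_classifier(X, rng.permutation(y),
                                  CNNConfig(seed=0, max_epochs=60, **REDUCED))
        assert abs(res.mean_accuracy - 0.125) <= 0.05

    def test_kfold_test_folds_disjoint_and_cover(self, separable_run):
        X, _, res = separable_run
        all_idx = np.concatenate(res.test_indices)
        assert len(all_idx) == len(X)
        assert len(np.unique(all_idx)) == len(X)

    def test_single_class_protocol_bypass(self):
        X, y = synthetic_matrix_classes(10, n_classes=2, seed=0)
        keep = y == 0
        cfg = CNNConfig(n_classes=2, max_epochs=30, seed=0, **REDUCED)
        model = ConnectomeCNN(cfg)
        model.classes_ = np.array([0, 1])
        model.fit(X[keep], y[keep], rng=np.random.default_rng(0))
        acc, confusion = evaluate(model, X[keep], y[keep])
        assert acc == 1.0
        assert confusion[0, 0] == 1.0  # all mass in the trained class row

    def test_missing_class_in_fold_raises(self):
        X, y = synthetic_matrix_classes(2, n_classes=8, seed=0)
        with pytest.raises(ValueError, match="per fold"):
            mn.train_classifier(X, y, CNNConfig(folds=5, seed=0))

    def test_softmax_rows_sum_to_one(self, separable_run, rng):
        X, _, res = separable_run
        proba = res.models[0].predict_proba(X[:16])
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(proba >= 0)

    def test_evaluation_deterministic(self, separable_run):
        X, y, res = separable_run
        m = res.models[0]
        a = m.predict_proba(X[:20])
        b = m.predict_proba(X[:20])
        assert np.array_equal(a, b)  # dropout disabled at eval


class TestSaliency:
    def test_positive_linear_model_matches_analytic_gradient(self, rng):
        """With all-positive weights and inputs every unit stays in the
        linear region and no gradient is clipped, so guided saliency
        equals the gradient of the composed linear map (checked by
        finite differences)."""
        cfg = CNNConfig(d=5, n_classes=3, e2e_maps=2, e2n_maps=2,
                        n2g_maps=3, fc_sizes=(3, 3), seed=0)
        model = ConnectomeCNN(cfg)
        for k in model.params:
            model.params[k] = np.abs(model.params[k]) + 0.01
        model.trained = True
        x = np.abs(rng.normal(size=(5, 5)))
        x = (x + x.T) / 2 + 0.1
        sal = guided_backprop_saliency(model, x)
        logits = model.predict_proba(x[None])  # winning class via argmax
        win = int(np.argmax(model._forward(model._prepare(x))[0]))
        eps = 1e-6
        num = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                xp, xm = x.copy(), x.copy()
                xp[i, j] += eps
                xm[i, j] -= eps
                lp = model._forward(model._prepare(xp))[0][0, win]
                lm = model._forward(model._prepare(xm))[0][0, win]
                num[i, j] = (lp - lm) / (2 * eps)
        assert np.allclose(sal, num, atol=1e-4)

    def test_zero_weights_give_zero_saliency(self):
        cfg = CNNConfig(d=4, n_classes=2, e2e_maps=1, e2n_maps=1,
                        n2g_maps=1, fc_sizes=(2, 2), seed=0)
        model = ConnectomeCNN(cfg)
        for k in model.params:
            model.params[k][:] = 0.0
        model.trained = True
        sal = guided_backprop_saliency(model, np.ones((4, 4)))
        assert np.all(sal == 0)

    def test_saliency_shape_matches_input(self, sparse_run):
        X, _, res = sparse_run
        sal = guided_backprop_saliency(res.models[0], X[0])
        assert sal.shape == X[0].shape

    def test_untrained_model_warns(self):
        model = ConnectomeCNN(CNNConfig(d=4, n_classes=2, e2e_maps=1,
                                        e2n_maps=1, n2g_maps=1, fc_sizes=(2, 2)))
        with pytest.warns(UserWarning, match="untrained"):
            guided_backprop_saliency(model, np.zeros((4, 4)))


class TestConsensusMask:
    def test_identical_maps_reproduce_top_fraction(self, rng):
        s = rng.normal(size=(14, 14))
        mask = consensus_mask([s] * 5, top_frac=0.10, consensus=0.90)
        k = int(round(0.10 * 196))
        assert mask.sum() == k
        thresh = np.sort(s.ravel())[::-1][k - 1]
        assert np.all(s[mask] >= thresh)

    def test_full_consensus_with_disagreement_is_empty(self, rng):
        a = rng.normal(size=(14, 14))
        b = rng.normal(size=(14, 14))
        mask = consensus_mask([a, b], top_frac=0.10, consensus=1.0)
        assert not mask.any()

    def test_split_cohort_cannot_reach_high_consensus(self):
        """Two disjoint half-cohort patterns max out at 50% consensus,
        below a 90% requirement."""
        a = np.zeros((14, 14))
        b = np.zeros((14, 14))
        a[:2, :] = 1.0
        b[7:9, :] = 1.0
        mask = consensus_mask([a] * 5 + [b] * 5, top_frac=0.10, consensus=0.90)
        assert not mask.any()


class TestOcclusion:
    def test_empty_mask_changes_nothing(self, sparse_run):
        X, y, res = sparse_run
        m = res.models[0]
        test = res.test_indices[0]
        base, _ = evaluate(m, X[test], y[test])
        occ, _ = occlude_and_evaluate(m, X[test], y[test],
                                      np.zeros((14, 14), dtype=bool))
        assert occ == base

    def test_full_mask_collapses_accuracy(self, sparse_run):
        X, y, res = sparse_run
        m = res.models[0]
        test = res.test_indices[0]
        occ, _ = occlude_and_evaluate(m, X[test], y[test],
                                      np.ones((14, 14), dtype=bool))
        assert occ <= 0.2  # constant input cannot beat chance by much

    def test_consensus_occlusion_strictly_reduces_accuracy(self, sparse_run):
        X, y, res = sparse_run
        m = res.models[0]
        test = res.test_indices[0]
        base, _ = evaluate(m, X[test], y[test])
        Xocc, masks = per_class_occlusion(m, X[test], y[test])
        occ, _ = evaluate(m, Xocc, y[test])
        assert any(mask.any() for mask in masks.values())
        assert occ < base


class TestChanceLevel:
    def test_uniform_random_classifier_near_one_eighth(self):
        acc = chance_level(n_draws=100_000, n_classes=8, seed=0)
        assert acc == pytest.approx(0.125, abs=0.01)
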