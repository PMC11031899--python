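"""Embedding network correctness and the common fit/predict contract."""

import numpy as np
import pytest

from taxbenefit import features as ft
from taxbenefit import models as md
from .conftest import make_patient, tiny_embed_params


class TestEmbedAggregate:
    def test_empty_set_is_zero_vector(self):
        E = np.arange(12.0).reshape(4, 3)
        assert np.array_equal(md.embed_aggregate([], E), np.zeros(3))

    def test_single_index_returns_row(self):
        E = np.arange(12.0).reshape(4, 3)
        assert np.array_equal(md.embed_aggregate([2], E, "mean"), E[2])
        assert np.array_equal(md.embed_aggregate([2], E, "sum"), E[2])

    def test_mean_of_two_rows(self):
        E = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.allclose(md.embed_aggregate({0, 1}, E, "mean"), [0.5, 0.5])
        assert np.allclose(md.embed_aggregate({0, 1}, E, "sum"), [1.0, 1.0])

    def test_duplicates_and_order_ignored(self):
        E = np.random.default_rng(0).normal(size=(5, 3))
        a = md.embed_aggregate([3, 1, 1, 3], E)
        b = md.embed_aggregate([1, 3], E)
        assert np.array_equal(a, b)

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            md.embed_aggregate([5], np.zeros((4, 2)))


class TestForward:
    def test_zero_parameters_give_half(self):
        params = md.EmbedNetParams(
            np.zeros((4, 3)), np.zeros((9, 2)), np.zeros(2), np.zeros(2), 0.0
        )
        assert md.forward_embednet(np.zeros(6), {0, 1}, params) == pytest.approx(0.5)

    def test_output_bias_monotone(self):
        params = tiny_embed_params()
        probs = []
        for b2 in (-5.0, 0.0, 5.0, 50.0):
            params.b2 = b2
            probs.append(md.forward_embednet(np.ones(6), {0}, params))
        assert probs == sorted(probs)
        assert probs[-1] > 0.999

    def test_variant_order_invariance(self):
        params = tiny_embed_params()
        a = md.forward_embednet(np.ones(6), [0, 2, 3], params)
        b = md.forward_embednet(np.ones(6), [3, 0, 2, 2], params)
        assert a == b

    def test_shape_mismatch_error(self):
        params = tiny_embed_params(k=6)
        with pytest.raises(ValueError):
            md.forward_embednet(np.zeros(4), {0}, params)


class TestGradients:
    @pytest.mark.parametrize("aggregation", ["sum", "mean"])
    def test_analytic_matches_central_differences(self, aggregation):
        rng = np.random.default_rng(0)
        V, k, n = 6, 3, 5
        spec = md.ModelSpec(kind="ann_with_ge", embedding_dim=4, hidden_units=5)
        params = md._init_params(V, k, spec, rng)
        X = rng.integers(0, 2, size=(n, k)).astype(float)
        sets = [frozenset({0, 1}), frozenset({2}), frozenset(),
                frozenset({3, 4, 5}), frozenset({1, 4})]
        y = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        _, grads = md.embednet_loss_and_grads(params, X, sets, y, aggregation)
        eps = 1e-6

        def loss():
            return md.embednet_loss_and_grads(params, X, sets, y, aggregation)[0]

        worst = 0.0
        for name in ("E", "W1", "b1", "w2"):
            arr, g = getattr(params, name), getattr(grads, name)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = arr[ix]
                arr[ix] = orig + eps
                lp = loss()
                arr[ix] = orig - eps
                lm = loss()
                arr[ix] = orig
                num = (lp - lm) / (2 * eps)
                worst = max(worst, abs(num - g[ix]) / max(abs(num), abs(g[ix]), 1e-8))
        orig = params.b2
        params.b2 = orig + eps
        lp = loss()
        params.b2 = orig - eps
        lm = loss()
        params.b2 = orig
        num = (lp - lm) / (2 * eps)
        worst = max(worst, abs(num - grads.b2) / max(abs(num), abs(grads.b2), 1e-8))
        assert worst < 1e-4


class TestTrainEmbednet:
    def test_separable_toy_set_fits_perfectly(self, separable_toy_features):
        fs = separable_toy_features
        spec = md.ModelSpec(
            kind="ann_with_ge", seed=0, early_stopping=False,
            batch_size=None, max_epochs=800, learning_rate=0.05,
        )
        model = md.fit_classifier(spec, fs, [0, 1, 2, 3])
        proba = md.predict_proba(model, fs, [0, 1, 2, 3])
        assert np.array_equal((proba >= 0.5).astype(int), [1, 1, 0, 0])

    def test_single_class_rejected(self, separable_toy_features):
        spec = md.ModelSpec(kind="ann_with_ge", seed=0)
        with pytest.raises(ValueError):
            md.fit_classifier(spec, separable_toy_features, [0, 1])

    def test_unseen_embedding_rows_untouched(self, small_features):
        fs = small_features
        labeled = [i for i, l in enumerate(fs.labels) if l != ft.EXCLUDED]
        # restrict training to patients avoiding one chosen variant
        target = 0
        train = [i for i in labeled if target not in fs.variant_sets[i]][:60]
        spec = md.ModelSpec(kind="ann_with_ge", seed=1, max_epochs=30)
        model = md.fit_classifier(spec, fs, train)
        rng = np.random.default_rng(spec.seed)
        init = md._init_params(len(fs.vocabulary), 6, spec, rng)
        assert np.array_equal(model.embed_params.E[target], init.E[target])
        # and at least one trained row moved
        seen = set().union(*(fs.variant_sets[i] for i in train))
        moved = [v for v in seen if not np.array_equal(model.embed_params.E[v], init.E[v])]
        assert moved

    def test_more_epochs_never_worse_full_batch(self, separable_toy_features):
        fs = separable_toy_features
        losses = {}
        for epochs in (50, 100):
            spec = md.ModelSpec(
                kind="ann_with_ge", seed=0, early_stopping=False,
                batch_size=None, max_epochs=epochs, learning_rate=0.05,
            )
            params = md.train_embednet(
                fs.clinical_matrix, fs.variant_sets,
                fs.binary_labels(range(4)), len(fs.vocabulary), spec,
            )
            losses[epochs], _ = md.embednet_loss_and_grads(
                params, fs.clinical_matrix, fs.variant_sets,
                fs.binary_labels(range(4)), spec.aggregation,
            )
        assert losses[100] <= losses[50] + 1e-12


class TestFitPredictContract:
    @pytest.mark.parametrize("kind", md.MODEL_KINDS)
    def test_all_kinds_smoke_and_determinism(self, kind, small_features):
        fs = small_features
        labeled = [i for i, l in enumerate(fs.labels) if l != ft.EXCLUDED]
        spec = md.ModelSpec(kind=kind, seed=3, n_trees=50, max_epochs=30)
        m1 = md.fit_classifier(spec, fs, labeled)
        m2 = md.fit_classifier(spec, fs, labeled)
        p1 = md.predict_proba(m1, fs, labeled)
        p2 = md.predict_proba(m2, fs, labeled)
        assert np.array_equal(p1, p2)
        assert np.all((p1 >= 0) & (p1 <= 1))

    def test_lr_separable_accuracy(self, separable_toy_features):
        fs = separable_toy_features
        model = md.fit_classifier(
            md.ModelSpec(kind="logistic_regression", seed=0), fs, [0, 1, 2, 3]
        )
        proba = md.predict_proba(model, fs, [0, 1, 2, 3])
        assert np.array_equal((proba >= 0.5).astype(int), [1, 1, 0, 0])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            md.ModelSpec(kind="gradient_boosting")

    def test_prediction_permutation_equivariance(self, small_features):
        fs = small_features
        labeled = [i for i, l in enumerate(fs.labels) if l != ft.EXCLUDED]
        spec = md.ModelSpec(kind="ann_with_ge", seed=3, max_epochs=20)
        model = md.fit_classifier(spec, fs, labeled)
        idx = labeled[:10]
        p = md.predict_proba(model, fs, idx)
        perm = idx[::-1]
        # pointwise map: same probabilities up to BLAS summation-order jitter
        assert np.allclose(md.predict_proba(model, fs, perm), p[::-1],
                           rtol=0, atol=1e-12)

    def test_vocabulary_mismatch_rejected(self, small_features, separable_toy_features):
        spec = md.ModelSpec(kind="logistic_regression", seed=0)
        model = md.fit_classifier(spec, separable_toy_features, [0, 1, 2, 3])
        with pytest.raises(ValueError):
            md.predict_proba(model, small_features, [0])


class TestSerialization:
    @pytest.mark.parametrize("kind", ["ann_with_ge", "logistic_regression"])
    def test_bundle_roundtrip(self, kind, small_features, tmp_path):
        fs = small_features
        labeled = [i for i, l in enumerate(fs.labels) if l != ft.EXCLUDED]
        spec = md.ModelSpec(kind=kind, seed=5, max_epochs=20)
        model = md.fit_classifier(spec, fs, labeled)
        md.save_model(model, tmp_path / "bundle")
        reloaded = md.load_model(tmp_path / "bundle")
        assert np.array_equal(
            md.predict_proba(model, fs, labeled),
            md.predict_proba(reloaded, fs, labeled),
        )
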