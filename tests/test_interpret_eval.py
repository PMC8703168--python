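import numpy as np
import pytest

from libspec import interpret_eval, nn
from libspec.interpret_eval import (
    accuracy,
    confusion,
    origin_average_saliency,
    round_percent,
    saliency_map,
    tsne_layer_view,
)
from libspec.models import TrainResult, build_cnn2d, train_staged, TrainSchedule


class TestAccuracy:
    def test_identical_and_discordant(self):
        assert accuracy([1, 2, 3], [1, 2, 3]) == 100.0
        assert accuracy([1, 2, 3], [2, 3, 1]) == 0.0

    def test_survey_prediction_set_rounding(self):
        """354 of 384 correct reports as 92.19% under half-up rounding."""
        y_true = np.ones(384, dtype=int)
        y_pred = np.ones(384, dtype=int)
        y_pred[:30] = 2
        assert round_percent(accuracy(y_true, y_pred)) == 92.19

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy([], [])


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array([1, 2, 3, 3, 2, 1])
        cm = confusion(y, y, 3)
        assert np.all(cm.counts == np.diag([2, 2, 2]))

    def test_single_spectrum_entry(self):
        cm = confusion([3], [5], 12)
        assert cm.counts[2, 4] == 1
        assert cm.total == 1

    def test_matches_independent_tally_on_random_labels(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(1, 13, 500)
        y_pred = rng.integers(1, 13, 500)
        cm = confusion(y_true, y_pred, 12)
        brute = np.zeros((12, 12), dtype=int)
        for t, p in zip(y_true, y_pred):
            brute[t - 1, p - 1] += 1
        np.testing.assert_array_equal(cm.counts, brute)
        assert cm.total == 500
        assert cm.accuracy() == pytest.approx(100.0 * np.trace(brute) / 500)

    def test_label_outside_range_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 13], [1, 1], 12)


def linear_network(w, n_classes, dtype=np.float64):
    """One dense layer on the flattened input with fixed weights."""
    rng = np.random.default_rng(0)
    net = nn.Network(
        [("flatten", nn.Flatten()), ("logits", nn.Dense(w.shape[0], n_classes, rng, dtype))],
        n_classes,
        dtype,
    )
    dense = dict(net.layers)["logits"]
    dense.w.value[...] = 0
    dense.w.value[:, 0] = w
    dense.b.value[...] = 0
    return net


class TestSaliency:
    def test_input_ignoring_score_gives_zero_weights(self):
        net = linear_network(np.zeros(12), 2)
        sal = saliency_map(net, np.ones((3, 4)), target_class_index=0)
        assert sal.shape == (3, 4)
        assert np.all(sal == 0)

    def test_linear_score_weights_are_absolute_coefficients(self):
        w = np.array([1.0, -2.0, 0.5, 0.0, 3.0, -1.5])
        net = linear_network(w, 2)
        sal = saliency_map(net, np.arange(6.0).reshape(2, 3), 0)
        np.testing.assert_allclose(sal, np.abs(w).reshape(2, 3))

    def test_gradient_matches_finite_differences(self):
        """Input gradient of a small trained-shape 2-D network agrees with
        central differences to 1e-4 relative error (float64)."""
        spec = build_cnn2d((8, 8), n_classes=3)
        net = spec.build(seed=1, dtype=np.float64)
        rng = np.random.default_rng(2)
        x = rng.random((8, 8))
        # stabilize batch-norm running statistics at this input's scale
        net.forward(x[None, None, ...], train=True)
        grad = net.input_gradient(x[None, None, ...], 1)[0, 0]
        eps = 1e-6
        fd = np.zeros_like(x)
        for i in range(8):
            for j in range(8):
                for sign in (1, -1):
                    xp = x.copy()
                    xp[i, j] += sign * eps
                    fd[i, j] += sign * net.forward(xp[None, None, ...])[0, 1]
        fd /= 2 * eps
        np.testing.assert_allclose(grad, fd, rtol=1e-4, atol=1e-10)

    def test_origin_average_of_identical_maps_is_the_map(self):
        w = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        net = linear_network(w, 3)
        result = TrainResult(model_ref=net, classes_=np.array([1, 2, 3]))
        stack = np.ones((4, 2, 3))
        origins = np.array([1, 1, 2, 2])
        wavelengths = np.linspace(229, 878, 6)
        res = origin_average_saliency(result, stack, origins, 1, wavelengths)
        np.testing.assert_allclose(res.weights, w.reshape(2, 3))
        # ranking is consistent: weight 6 sits at variable 5 -> last wavelength
        assert res.ranked_wavelengths[0] == (pytest.approx(wavelengths[5]), 6.0)
        single = origin_average_saliency(result, stack[:1], origins[:1], 1, wavelengths)
        np.testing.assert_allclose(single.weights, res.weights)

    def test_absent_origin_rejected(self):
        net = linear_network(np.ones(6), 3)
        result = TrainResult(model_ref=net, classes_=np.array([1, 2, 3]))
        with pytest.raises(ValueError):
            origin_average_saliency(result, np.ones((1, 2, 3)), np.array([1]), 2,
                                    np.linspace(229, 878, 6))


class TestTSNE:
    @pytest.fixture(scope="class")
    def trained(self):
        """Short 2-D CNN fit on two far-separated synthetic classes."""
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.05, (60, 8, 16)) + 0
        b = rng.normal(0, 0.05, (60, 8, 16)) + 3.0
        x = np.concatenate([a, b])
        y = np.array([1] * 60 + [2] * 60)
        spec = build_cnn2d((8, 16), n_classes=2)
        schedule = TrainSchedule(stages=((0.05, 1.0),), max_iterations_per_stage=15, seed=0)
        result = train_staged(spec, (x, y), (x[::6], y[::6]), schedule)
        return result, x, y

    def test_deterministic_and_separates_far_classes(self, trained):
        result, x, y = trained
        emb1 = tsne_layer_view(result, x, "dense2", perplexity=20, seed=4)
        emb2 = tsne_layer_view(result, x, "dense2", perplexity=20, seed=4)
        np.testing.assert_array_equal(emb1, emb2)
        from sklearn.metrics import silhouette_score
        assert silhouette_score(emb1, y) > 0.5

    def test_deeper_layer_clusters_at_least_as_well(self, trained):
        """Features late in the network separate the classes no worse than
        the first convolution block's features."""
        result, x, y = trained
        from sklearn.metrics import silhouette_score
        shallow = silhouette_score(
            tsne_layer_view(result, x, "conv_block1", perplexity=20, seed=4), y
        )
        deep = silhouette_score(
            tsne_layer_view(result, x, "dense2", perplexity=20, seed=4), y
        )
        assert deep >= shallow

    def test_unknown_layer_rejected(self, trained):
        result, x, _ = trained
        with pytest.raises(KeyError):
            tsne_layer_view(result, x, "no_such_layer")
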