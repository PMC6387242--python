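"""CNN feature extractor: conv oracle, pooling, gradients, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mivae import (
    CnnConfig,
    activation,
    cnn_forward,
    conv_forward,
    extract_features,
    init_cnn,
    max_pool,
    train_cnn,
)
from mivae.cnn import _forward_full, _loss_and_grads, cnn_predict, unflatten_features
from mivae.representation import ImageSet
from mivae._nn import softmax_xent

from conftest import fast_cnn_config


def make_imageset(images, labels):
    return ImageSet(
        images=np.asarray(images, dtype=np.float32),
        labels=np.asarray(labels, dtype=np.int64),
        channel_order=("C3", "Cz", "C4"),
        band_layout={},
    )


class TestInit:
    @pytest.mark.parametrize("nh", [93, 155])
    def test_kernel_shapes(self, nh):
        m = init_cnn(CnnConfig(), (nh, 32))
        assert m.kernels.shape == (30, nh, 3)
        assert m.head.n_in == 30 * 3  # 30 conv outputs pooled by 10 -> 3 each

    def test_seeded_init_reproducible(self):
        a = init_cnn(CnnConfig(seed=5), (93, 32))
        b = init_cnn(CnnConfig(seed=5), (93, 32))
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.head.W, b.head.W)


class TestConvForward:
    def test_feature_map_shape_and_total(self):
        m = init_cnn(CnnConfig(), (93, 32))
        img = np.random.default_rng(0).standard_normal((93, 32))
        fm = conv_forward(m, img)
        assert fm.shape == (30, 30)  # NF x (Nt - width + 1); 900 values total
        assert fm.size == 900

    def test_matches_brute_force_double_sum(self):
        """Vectorized conv equals the direct sum_m sum_n K*I definition."""
        rng = np.random.default_rng(4)
        cfg = CnnConfig(
            n_filters=5, kernel_width=2, activation="identity", dtype="float64",
            init_scale=0.5, seed=2,
        )
        m = init_cnn(cfg, (5, 6))
        for _ in range(3):
            img = rng.standard_normal((5, 6))
            out = conv_forward(m, img)
            K = m.kernels
            brute = np.zeros((5, 5))
            for k in range(5):
                for j in range(5):
                    acc = m.b[k]
                    for mm in range(5):
                        for nn in range(2):
                            acc += K[k, mm, nn] * img[mm, j + nn]
                    brute[k, j] = acc
            np.testing.assert_allclose(out, brute, atol=1e-12)

    def test_toy_row_image(self):
        """1x3 'image' [1,2,3] with kernel [1,1,1] sums to [6]."""
        cfg = CnnConfig(n_filters=1, kernel_width=3, activation="identity",
                        dtype="float64")
        m = init_cnn(cfg, (1, 3))
        m.W[:] = 1.0
        m.b[:] = 0.0
        np.testing.assert_allclose(conv_forward(m, np.array([[1.0, 2.0, 3.0]])), [[6.0]])

    def test_zero_kernel_softplus_gives_ln2(self):
        m = init_cnn(CnnConfig(dtype="float64"), (93, 32))
        m.W[:] = 0.0
        m.b[:] = 0.0
        fm = conv_forward(m, np.random.default_rng(0).standard_normal((93, 32)))
        np.testing.assert_allclose(fm, np.log(2.0))

    def test_shape_mismatch_rejected(self):
        m = init_cnn(CnnConfig(), (93, 32))
        with pytest.raises(ValueError, match="does not match model input"):
            conv_forward(m, np.zeros((155, 32)))


class TestActivation:
    def test_values_and_limits(self):
        assert activation(0.0) == pytest.approx(np.log(2.0))
        assert activation(1.0) == pytest.approx(1.3133, abs=1e-4)
        assert activation(-40.0) == pytest.approx(0.0, abs=1e-12)
        assert activation(40.0) == pytest.approx(40.0, rel=1e-6)
        assert activation(-1.0, kind="relu") == 0.0
        assert activation(2.5, kind="relu") == 2.5


class TestMaxPool:
    def test_factor_ten_on_thirty(self):
        fm = np.arange(30.0).reshape(1, 1, 30)
        assert max_pool(fm, 10).shape == (1, 1, 3)

    def test_factor_one_identity(self):
        fm = np.random.default_rng(0).standard_normal((2, 3, 7))
        np.testing.assert_array_equal(max_pool(fm, 1), fm)

    def test_zero_padded_window(self):
        np.testing.assert_array_equal(max_pool(np.array([1.0, 5.0, 2.0]), 2), [5.0, 2.0])

    @given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=30),
           st.integers(1, 40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_pool_outputs_are_input_values(self, vals, factor):
        """Each pooled value is one of the inputs (zero pad never wins
        against positive activations), and pooling by >= length collapses
        to the global max."""
        arr = np.array(vals)
        pooled = max_pool(arr, factor)
        assert set(np.atleast_1d(pooled)) <= set(arr)
        if factor >= len(vals):
            assert pooled[0] == arr.max()


class TestHeadAndTraining:
    def test_probabilities_normalized(self, tiny_images):
        m = init_cnn(CnnConfig(), tiny_images.images.shape[1:])
        probs = cnn_forward(m, tiny_images)
        assert probs.shape == (len(tiny_images), 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-5)

    def test_zero_head_gives_even_odds(self, tiny_images):
        m = init_cnn(CnnConfig(), tiny_images.images.shape[1:])
        m.head.W[:] = 0.0
        m.head.b[:] = 0.0
        probs = cnn_forward(m, tiny_images)
        np.testing.assert_allclose(probs, 0.5, atol=1e-7)

    def test_zero_learning_rate_freezes_weights(self, tiny_images):
        cfg = fast_cnn_config(learning_rate=0.0, epochs=3)
        m = init_cnn(cfg, tiny_images.images.shape[1:])
        w0 = m.W.copy()
        train_cnn(m, tiny_images)
        np.testing.assert_array_equal(m.W, w0)

    def test_full_batch_equals_single_batch(self, tiny_images):
        """batch_size >= n is one full-batch step per epoch regardless of
        how much larger it is."""
        n = len(tiny_images)
        runs = []
        for bs in (n, 5 * n):
            m = init_cnn(fast_cnn_config(batch_size=bs, epochs=3), tiny_images.images.shape[1:])
            train_cnn(m, tiny_images)
            runs.append(m.W.copy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_loss_decreases_and_separable_accuracy(self, small_images):
        m = init_cnn(fast_cnn_config(epochs=20), small_images.images.shape[1:])
        arr = small_images.images
        normed = ImageSet(
            (arr - arr.mean()) / arr.std(), small_images.labels,
            small_images.channel_order, small_images.band_layout,
        )
        _, hist = train_cnn(m, normed)
        assert hist.loss[-1] <= hist.loss[0]
        assert hist.accuracy[-1] > 0.9
        assert cnn_predict(m, normed).shape == (len(normed),)

    def test_single_class_rejected(self, tiny_images):
        only_left = ImageSet(
            tiny_images.images[tiny_images.labels == 0],
            tiny_images.labels[tiny_images.labels == 0],
            tiny_images.channel_order, tiny_images.band_layout,
        )
        m = init_cnn(fast_cnn_config(), tiny_images.images.shape[1:])
        with pytest.raises(ValueError, match="both classes"):
            train_cnn(m, only_left)

    def test_gradients_match_finite_differences(self):
        """Analytic CNN gradients vs central differences, rel err < 1e-4."""
        cfg = CnnConfig(n_filters=4, kernel_width=2, pool_factor=3,
                        dtype="float64", seed=1, init_scale=0.3)
        m = init_cnn(cfg, (5, 7))
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((6, 5, 7))
        y = np.array([0, 1, 0, 1, 1, 0])
        _, _, grads = _loss_and_grads(m, arr, y)

        def loss():
            *_, logits = _forward_full(m, arr)
            return softmax_xent(logits, y)[0]

        for name, p in (("W", m.W), ("b", m.b), ("head.W", m.head.W), ("head.b", m.head.b)):
            num = np.zeros_like(p)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = p[i]
                p[i] = old + 1e-6
                lp = loss()
                p[i] = old - 1e-6
                lm = loss()
                p[i] = old
                num[i] = (lp - lm) / 2e-6
            rel = np.abs(num - grads[name]).max() / (np.abs(num).max() + 1e-12)
            assert rel < 1e-4, name


class TestFeatures:
    def test_default_feature_length_900(self, tiny_images):
        m = init_cnn(CnnConfig(), tiny_images.images.shape[1:])
        feats = extract_features(m, tiny_images)
        assert feats.shape == (len(tiny_images), 900)

    def test_single_image(self, tiny_images):
        m = init_cnn(CnnConfig(), tiny_images.images.shape[1:])
        feats = extract_features(m, tiny_images.images[0])
        assert feats.shape == (1, 900)

    def test_flatten_round_trip(self, tiny_images):
        m = init_cnn(CnnConfig(), tiny_images.images.shape[1:])
        fm = conv_forward(m, tiny_images)
        feats = extract_features(m, tiny_images)
        np.testing.assert_array_equal(unflatten_features(feats, 30), fm)
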