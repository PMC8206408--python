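import numpy as np
import pytest

from lgnenc import cnn
from lgnenc import preprocess as pp
from lgnenc import simulate as sim
from lgnenc import stimulus as st


def conv1d_same_oracle(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Brute-force sliding dot product with 'same' zero padding.

    x: (T, C), W: (F, K, C), b: (F,). Independent of the layer implementation.
    """
    T, C = x.shape
    F, K, _ = W.shape
    pad_l = (K - 1) // 2
    out = np.zeros((T, F))
    for t in range(T):
        for f in range(F):
            acc = 0.0
            for k in range(K):
                src = t + k - pad_l
                if 0 <= src < T:
                    for c in range(C):
                        acc += x[src, c] * W[f, k, c]
            out[t, f] = acc + b[f]
    return out


class TestPrelu:
    def test_positive_identity(self):
        assert cnn.prelu(2.0, 0.7) == 2.0

    def test_negative_slope(self):
        assert cnn.prelu(-2.0, 0.1) == pytest.approx(-0.2)

    def test_zero_alpha_is_relu(self):
        x = np.array([-3.0, -1.0, 0.0, 2.0])
        assert np.array_equal(cnn.prelu(x, 0.0), np.maximum(x, 0.0))


class TestConfig:
    def test_L_values(self):
        assert cnn.EncoderConfig(n_pixels=32, n_neurons=4, w_ms=50).L == 10
        assert cnn.EncoderConfig(n_pixels=32, n_neurons=4, w_ms=10).L == 50

    def test_window_is_500ms(self):
        for w in (10, 50):
            cfg = cnn.EncoderConfig(n_pixels=32, n_neurons=4, w_ms=w)
            assert cfg.L * cfg.w_ms == 500

    def test_default_blocks(self):
        assert cnn.EncoderConfig(n_pixels=8, n_neurons=2, w_ms=50).conv_blocks == 1
        assert cnn.EncoderConfig(n_pixels=8, n_neurons=2, w_ms=10).conv_blocks == 3

    @pytest.mark.parametrize("bad", [{"filter_len": 2}, {"filter_len": 9}, {"variant": "X"}, {"w_ms": 37}])
    def test_invalid_config(self, bad):
        with pytest.raises(ValueError):
            cnn.EncoderConfig(n_pixels=8, n_neurons=2, **bad)


class TestBuildModel:
    def test_layer_count_w50(self):
        model = cnn.build_model(cnn.EncoderConfig(n_pixels=32, n_neurons=12, w_ms=50))
        assert model.n_layers == 9

    def test_layer_count_w10(self):
        model = cnn.build_model(cnn.EncoderConfig(n_pixels=32, n_neurons=12, w_ms=10))
        assert model.n_layers == 17

    def test_pooled_visual_shape_w50(self):
        model = cnn.build_model(cnn.EncoderConfig(n_pixels=32, n_neurons=12, w_ms=50))
        assert model.pooled_shape("visual") == (5, 32)

    def test_pooled_chain_w10(self):
        model = cnn.build_model(cnn.EncoderConfig(n_pixels=32, n_neurons=12, w_ms=10))
        # visual 50 -> 25 -> 12 -> 6; history 49 -> 24 -> 12 -> 6
        assert model.pooled_shape("visual") == (6, 32)
        assert model.pooled_shape("history") == (6, 12)

    def test_history_pool_w50(self):
        model = cnn.build_model(cnn.EncoderConfig(n_pixels=32, n_neurons=12, w_ms=50))
        assert model.pooled_shape("history") == (4, 12)

    def test_variant_branches(self):
        v = cnn.build_model(cnn.EncoderConfig(n_pixels=8, n_neurons=3, variant="V"))
        fh = cnn.build_model(cnn.EncoderConfig(n_pixels=8, n_neurons=3, variant="FH"))
        assert not v.history_layers and v.visual_layers
        assert not fh.visual_layers and fh.history_layers
        assert "concat" not in v.layer_names

    def test_too_many_blocks_error(self):
        cfg = cnn.EncoderConfig(n_pixels=4, n_neurons=2, w_ms=50, conv_blocks=5)
        with pytest.raises(ValueError, match="pooled length"):
            cnn.build_model(cfg)

    def test_zero_biases_init(self):
        model = cnn.build_model(cnn.EncoderConfig(n_pixels=8, n_neurons=3))
        for layer in model.all_layers():
            if hasattr(layer, "b"):
                assert np.all(layer.b == 0)


class TestConvOracle:
    @pytest.mark.parametrize("K", range(3, 9))
    def test_matches_brute_force(self, K, rng):
        layer = cnn.Conv1D(n_channels=3, n_filters=4, filter_len=K, rng=rng)
        x = rng.normal(size=(2, 5, 3))
        out = layer.forward(x)
        for b in range(2):
            expected = conv1d_same_oracle(x[b], layer.W, layer.b)
            assert np.abs(out[b] - expected).max() < 1e-6

    def test_gradients_match_finite_differences(self, rng):
        cfg = cnn.EncoderConfig(n_pixels=3, n_neurons=2, filter_len=3, seed=5)
        model = cnn.build_model(cfg)
        xv = rng.normal(size=(4, 10, 3))
        xh = rng.normal(size=(4, 9, 2))
        y = rng.normal(size=(4, 2))

        def loss():
            return float(np.sqrt(np.mean((model.forward(xv, xh) - y) ** 2)))

        err = model.forward(xv, xh) - y
        rmse = np.sqrt(np.mean(err**2))
        model.backward(err / (err.size * rmse))
        eps = 1e-6
        for p, g in zip(model.parameters(), model.gradients()):
            flat = p.reshape(-1)
            gflat = g.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 3)):
                old = flat[idx]
                flat[idx] = old + eps
                l1 = loss()
                flat[idx] = old - eps
                l2 = loss()
                flat[idx] = old
                num = (l1 - l2) / (2 * eps)
                assert abs(num - gflat[idx]) < 1e-5 * max(1.0, abs(num))


class TestAssemble:
    def _rates(self, n_bins, N, seed=0):
        rng = np.random.default_rng(seed)
        return pp.RateMatrix(rates=rng.uniform(0, 40, (n_bins, N)), w_ms=50)

    def test_boundary_single_sample(self):
        cfg = cnn.EncoderConfig(n_pixels=4, n_neurons=2)
        stim_bins = np.zeros((10, 4))
        batch = cnn.assemble_samples(stim_bins, self._rates(10, 2), cfg)
        assert len(batch) == 1

    def test_shapes(self):
        cfg = cnn.EncoderConfig(n_pixels=32, n_neurons=12)
        batch = cnn.assemble_samples(np.zeros((40, 32)), self._rates(40, 12), cfg)
        assert batch.visual.shape[1:] == (10, 32)
        assert batch.history.shape[1:] == (9, 12)
        assert batch.target.shape[1:] == (12,)

    def test_sample_count(self):
        cfg = cnn.EncoderConfig(n_pixels=4, n_neurons=2)
        n_bins = 37
        batch = cnn.assemble_samples(np.zeros((n_bins, 4)), self._rates(n_bins, 2), cfg)
        assert len(batch) == n_bins - cfg.L + 1

    def test_window_alignment(self):
        cfg = cnn.EncoderConfig(n_pixels=1, n_neurons=1)
        stim_bins = np.arange(20, dtype=float).reshape(-1, 1)
        rates = pp.RateMatrix(rates=100 + np.arange(20, dtype=float).reshape(-1, 1), w_ms=50)
        batch = cnn.assemble_samples(stim_bins, rates, cfg)
        k = batch.bin_index[3]
        assert np.array_equal(batch.visual[3, :, 0], np.arange(k - 9, k + 1))
        assert np.array_equal(batch.history[3, :, 0], 100 + np.arange(k - 9, k))
        assert batch.target[3, 0] == 100 + k

    def test_too_short_error(self):
        cfg = cnn.EncoderConfig(n_pixels=4, n_neurons=2)
        with pytest.raises(ValueError, match="fewer"):
            cnn.assemble_samples(np.zeros((5, 4)), self._rates(5, 2), cfg)


class TestTraining:
    def _toy_batch(self, rng, n=50, P=12, N=8):
        cfg = cnn.EncoderConfig(n_pixels=P, n_neurons=N, epochs=500, batch_size=16, seed=2)
        visual = rng.normal(size=(n, cfg.L, P))
        history = rng.normal(size=(n, cfg.L - 1, N))
        target = rng.uniform(0, 10, size=(n, N))
        return cfg, cnn.SampleBatch(visual, history, target, np.arange(n))

    def test_memorization(self, rng):
        cfg, batch = self._toy_batch(rng)
        model = cnn.build_model(cfg)
        cnn.train(model, batch)
        pred = cnn.predict(model, batch)
        rmse = np.sqrt(np.mean((pred - batch.target) ** 2))
        assert rmse < 0.05 * batch.target.std()

    def test_zero_target_loss_decreases(self, rng):
        cfg, batch = self._toy_batch(rng)
        batch.target[...] = 0.0
        model = cnn.build_model(cfg)
        losses = cnn.train(model, batch, epochs=50)
        assert losses[-1] < 0.05 * losses[0]

    def test_seed_reproducibility(self, rng):
        cfg, batch = self._toy_batch(rng)
        l1 = cnn.train(cnn.build_model(cfg), batch, epochs=5)
        l2 = cnn.train(cnn.build_model(cfg), batch, epochs=5)
        assert l1 == l2

    def test_predict_finite_on_zeros(self):
        cfg = cnn.EncoderConfig(n_pixels=4, n_neurons=3)
        model = cnn.build_model(cfg)
        batch = cnn.SampleBatch(
            np.zeros((2, cfg.L, 4)), np.zeros((2, cfg.L - 1, 3)), np.zeros((2, 3)), np.arange(2)
        )
        assert np.all(np.isfinite(cnn.predict(model, batch)))

    def test_clamp_flag(self, rng):
        cfg = cnn.EncoderConfig(n_pixels=4, n_neurons=3)
        model = cnn.build_model(cfg)
        batch = cnn.SampleBatch(
            rng.normal(size=(8, cfg.L, 4)), rng.normal(size=(8, cfg.L - 1, 3)),
            np.zeros((8, 3)), np.arange(8),
        )
        assert np.all(cnn.predict(model, batch, clamp_negative=True) >= 0)


def test_noiseless_mapping_learnable(small_checkerboard, small_population):
    """Deterministic intensity -> rate mapping is learned to corr > 0.8."""
    lam = sim.compute_intensity(small_checkerboard, small_population)
    N = len(small_population)
    rates = pp.RateMatrix(rates=lam.reshape(-1, 50, N).mean(axis=1), w_ms=50)
    cfg = cnn.EncoderConfig(n_pixels=8, n_neurons=N, variant="V", epochs=200, seed=0)
    model = cnn.build_model(cfg)
    batch = cnn.assemble_samples(small_checkerboard, rates, cfg)
    split = int(0.8 * len(batch))
    cnn.train(model, batch.subset(np.arange(split)))
    pred = cnn.predict(model, batch.subset(np.arange(split, len(batch))))
    actual = batch.target[split:]
    cors = [np.corrcoef(actual[:, i], pred[:, i])[0, 1] for i in range(N)]
    assert min(cors) > 0.8
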