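import numpy as np
import pytest
from scipy import stats

from lgnenc import cnn
from lgnenc import evaluate as ev
from lgnenc import preprocess as pp
from lgnenc import simulate as sim
from lgnenc import stimulus as st


def _markers(n_patterns, trials):
    """Trial blocks cycling through patterns (one pass per trial index)."""
    out = []
    idx = 0
    for t in range(trials):
        for p in range(n_patterns):
            out.append((idx, p, idx * 500))
            idx += 1
    return out


class TestSplitFolds:
    def test_per_pixel_trials_20_per_fold(self):
        markers = _markers(1, 100)
        folds = ev.split_folds(markers, scheme="per_pixel_trials", k=5, seed=0)
        sizes = [len(f) for f in folds]
        assert sizes == [20] * 5
        covered = sorted(t for f in folds for t in f)
        assert covered == list(range(100))

    def test_per_pattern_32_into_5(self):
        markers = _markers(32, 3)
        folds = ev.split_folds(markers, scheme="per_pattern", k=5, seed=0)
        pattern_sets = []
        by_trial = {m[0]: m[1] for m in markers}
        for f in folds:
            pattern_sets.append({by_trial[t] for t in f})
        sizes = sorted(len(s) for s in pattern_sets)
        assert sizes == [6, 6, 6, 7, 7]
        assert set().union(*pattern_sets) == set(range(32))
        for i in range(5):
            for j in range(i + 1, 5):
                assert not pattern_sets[i] & pattern_sets[j]

    def test_disjoint_cover_property(self):
        markers = _markers(8, 10)
        for scheme in ev.SCHEMES:
            folds = ev.split_folds(markers, scheme=scheme, k=4, seed=3)
            covered = sorted(t for f in folds for t in f)
            assert covered == [m[0] for m in markers]

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            ev.split_folds(_markers(4, 10), k=1)

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            ev.split_folds(_markers(4, 3), scheme="per_pixel_trials", k=5)


class TestPredictionCorrelation:
    def _slices(self, n_trials, bins_per_trial):
        return [np.arange(i * bins_per_trial, (i + 1) * bins_per_trial) for i in range(n_trials)]

    def test_identity(self, rng):
        actual = rng.uniform(0, 10, (50, 3))
        corr, skipped = ev.prediction_correlation(actual, actual, self._slices(5, 10))
        assert np.allclose(corr, 1.0)
        assert skipped == 0

    def test_anticorrelated(self, rng):
        actual = rng.uniform(0, 10, (50, 2))
        pred = -actual + 7.0
        corr, _ = ev.prediction_correlation(actual, pred, self._slices(5, 10))
        assert np.allclose(corr, -1.0)

    def test_formula_oracle(self):
        a = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        b = np.array([2.0, 2.5, 1.0, 6.0, 3.0])
        # textbook covariance / (sd * sd), computed by hand here
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov / (a.std() * b.std())
        corr, _ = ev.prediction_correlation(a[:, None], b[:, None], [np.arange(5)])
        assert abs(corr[0] - expected) < 1e-12

    def test_zero_variance_trial_skipped(self, rng):
        actual = rng.uniform(0, 10, (20, 1))
        pred = actual.copy()
        actual[:10] = 5.0  # flat actual in first trial
        corr, skipped = ev.prediction_correlation(actual, pred, self._slices(2, 10))
        assert skipped == 1
        assert np.isfinite(corr[0])


class TestCorrelationMatrix:
    def test_identity_diagonal(self, rng):
        actual = rng.uniform(0, 10, (100, 4))
        mat = ev.correlation_matrix(actual, actual)
        assert np.allclose(np.diag(mat), 1.0)

    def test_permutation_equivariance(self, rng):
        actual = rng.uniform(0, 10, (100, 4))
        pred = rng.uniform(0, 10, (100, 4))
        perm = [2, 0, 3, 1]
        base = ev.correlation_matrix(actual, pred)
        permuted = ev.correlation_matrix(actual, pred[:, perm])
        assert np.allclose(permuted, base[:, perm])


class TestPeakRate:
    def test_identity_r2(self, rng):
        actual = rng.uniform(0, 30, (40, 3))
        markers = _markers(2, 2)
        _, r2 = ev.peak_rate_analysis(actual, actual, markers, w_ms=50)
        assert r2 == pytest.approx(1.0)

    def test_scaled_r2(self, rng):
        actual = rng.uniform(0, 30, (40, 3))
        _, r2 = ev.peak_rate_analysis(actual, 2.0 * actual, _markers(2, 2), w_ms=50)
        assert r2 == pytest.approx(1.0)

    def test_r2_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.3, 3.7])
        slope, intercept = np.polyfit(x, y, 1)
        ss_res = np.sum((y - (slope * x + intercept)) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        expected = 1 - ss_res / ss_tot
        assert abs(ev._r_squared(x, y) - expected) < 1e-12


class TestTrialVariability:
    def test_identical_trials_zero_sd(self):
        actual = np.tile(np.arange(10.0)[:, None], (3, 2))
        slices = [np.arange(i * 10, (i + 1) * 10) for i in range(3)]
        sd = ev.trial_variability(actual, actual, slices)
        assert np.allclose(sd, 0.0)

    def test_identity_line(self, rng):
        actual = rng.uniform(0, 10, (30, 2))
        slices = [np.arange(i * 10, (i + 1) * 10) for i in range(3)]
        sd = ev.trial_variability(actual, actual, slices)
        assert np.allclose(sd[:, 0], sd[:, 1])

    def test_three_trial_oracle(self):
        actual = np.zeros((15, 1))
        actual[:5, 0] = 2.0  # trial means: 2, 4, 9
        actual[5:10, 0] = 4.0
        actual[10:, 0] = 9.0
        slices = [np.arange(0, 5), np.arange(5, 10), np.arange(10, 15)]
        sd = ev.trial_variability(actual, actual, slices)
        expected = np.std([2.0, 4.0, 9.0])
        assert abs(sd[0, 0] - expected) < 1e-12


class TestFitBeta:
    def test_recover_known_parameters(self, rng):
        samples = stats.beta.rvs(7.45, 2.48, size=10_000, random_state=rng)
        a, b, ll = ev.fit_beta(samples)
        assert a == pytest.approx(7.45, rel=0.1)
        assert b == pytest.approx(2.48, rel=0.1)

    def test_uniform_is_beta_1_1(self, rng):
        samples = rng.uniform(0, 1, 10_000)
        a, b, _ = ev.fit_beta(samples)
        assert a == pytest.approx(1.0, rel=0.1)
        assert b == pytest.approx(1.0, rel=0.1)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ev.fit_beta(np.full(100, 0.5))


@pytest.fixture(scope="module")
def cv_report(small_checkerboard, small_recording):
    spikes, rates = small_recording
    cfg = cnn.EncoderConfig(n_pixels=8, n_neurons=5, epochs=40, seed=0)
    return ev.cross_validate(
        small_checkerboard, rates, cfg, scheme="per_pixel_trials", k=4, seed=0
    )


class TestCrossValidate:
    def test_folds_partition(self, cv_report, small_checkerboard):
        covered = sorted(t for f in cv_report.fold_assignments for t in f)
        assert covered == [m[0] for m in small_checkerboard.markers]

    def test_correlations_in_range(self, cv_report):
        corr = cv_report.per_neuron_corr
        assert np.all(corr[~np.isnan(corr)] >= -1.0)
        assert np.all(corr[~np.isnan(corr)] <= 1.0)

    def test_stimulus_locked_population_predictable(self, cv_report):
        # per-trial metric is noisy at 10 bins/trial; the concatenated-bin
        # diagonal gives the stabler readout
        assert np.nanmean(cv_report.per_neuron_corr) > 0.05
        assert np.mean(np.diag(cv_report.corr_matrix)) > 0.1

    def test_corr_matrix_shape(self, cv_report):
        assert cv_report.corr_matrix.shape == (5, 5)

    def test_report_serializable(self, cv_report):
        import json

        text = json.dumps(cv_report.to_dict())
        assert "per_neuron_corr" in text


def test_snr_performance_relationship():
    """Per-neuron prediction quality ranks with stimulus locking."""
    stim = st.make_checkerboard(n_patterns=16, pixels_per_pattern=4, trials=20, seed=5)
    rng = np.random.default_rng(6)
    snrs = np.linspace(0.05, 1.0, 12)
    specs = [
        sim.NeuronSpec(
            rf_center=(int(rng.integers(4)), int(rng.integers(8))),
            polarity="ON" if i % 3 else "OFF",
            kernel="transient" if i % 2 else "sustained",
            snr=float(snrs[i]),
            baseline=4,
        )
        for i in range(12)
    ]
    spikes = sim.simulate_population(stim, specs, seed=7)
    rates = pp.bin_rates(spikes, 50)
    cfg = cnn.EncoderConfig(n_pixels=32, n_neurons=12, epochs=30, seed=0)
    model = cnn.build_model(cfg)
    batch = cnn.assemble_samples(stim, rates, cfg)
    split = int(0.8 * len(batch))
    cnn.train(model, batch.subset(np.arange(split)))
    pred = cnn.predict(model, batch.subset(np.arange(split, len(batch))))
    actual = batch.target[split:]
    cors = [np.corrcoef(actual[:, i], pred[:, i])[0, 1] for i in range(12)]
    assert stats.spearmanr(snrs, cors).statistic > 0.6


class TestGeneralization:
    def test_checkerboard_to_shapes(self):
        """A model trained on the full checkerboard set transfers to projected
        shapes with positive but lower correlation."""
        grid = (4, 8)
        train_stim = st.make_checkerboard(n_patterns=16, pixels_per_pattern=4, trials=12, seed=2)
        shapes = st.make_shapes(canvas=(90, 160), n_patterns=10, trials=10, seed=3)
        shape_stim = st.project_to_grid(shapes, grid=grid)
        specs = [
            sim.NeuronSpec(rf_center=(i % 4, (2 * i) % 8), snr=0.9,
                           kernel="transient" if i % 2 else "sustained",
                           polarity="ON" if i % 3 else "OFF", baseline=4)
            for i in range(6)
        ]
        train_spikes = sim.simulate_population(train_stim, specs, seed=4)
        shape_spikes = sim.simulate_population(shape_stim, specs, seed=5)
        train_rates = pp.bin_rates(train_spikes, 50)
        shape_rates = pp.bin_rates(shape_spikes, 50)
        cfg = cnn.EncoderConfig(n_pixels=32, n_neurons=6, epochs=30, seed=0)
        model = cnn.build_model(cfg)
        cnn.train(model, cnn.assemble_samples(train_stim, train_rates, cfg))

        report = ev.generalization_eval(model, shape_stim, shape_rates)
        assert report.meta["trained_on_test_data"] is False
        gen_corr = np.nanmean(report.per_neuron_corr)
        assert gen_corr > 0.0

        # in-distribution performance on held-out checkerboard bins is higher
        batch = cnn.assemble_samples(train_stim, train_rates, cfg)
        pred = cnn.predict(model, batch)
        in_dist = np.nanmean(
            [np.corrcoef(batch.target[:, i], pred[:, i])[0, 1] for i in range(6)]
        )
        assert in_dist > gen_corr

    def test_matching_distribution_matches_in_distribution_levels(self):
        """Testing on the very patterns trained on gives similar correlations."""
        stim = st.make_checkerboard(grid=(2, 4), n_patterns=8, pixels_per_pattern=2,
                                    trials=10, seed=0)
        specs = [sim.NeuronSpec(rf_center=(i % 2, i % 4), snr=1.0, baseline=4) for i in range(4)]
        spikes = sim.simulate_population(stim, specs, seed=1)
        rates = pp.bin_rates(spikes, 50)
        cfg = cnn.EncoderConfig(n_pixels=8, n_neurons=4, epochs=25, seed=0)
        model = cnn.build_model(cfg)
        cnn.train(model, cnn.assemble_samples(stim, rates, cfg))
        report = ev.generalization_eval(model, stim, rates)
        assert np.nanmean(report.per_neuron_corr) > 0.05
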