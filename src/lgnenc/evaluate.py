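"""Cross-validated assessment of encoder models.

Two split schemes over the trial-block structure of a recording:

* ``per_pixel_trials`` -- within every pattern's trials, k disjoint
  near-equal test blocks (for the single-pixel protocol, 100 trials per
  pixel -> 20-trial test blocks at k = 5);
* ``per_pattern`` -- patterns partitioned into k near-equal groups; all
  trials of the held-out patterns form the test set.

The headline metric is the Pearson correlation between actual and predicted
firing rates computed per neuron per test trial and averaged over trials and
folds.  Additional analyses: the N x N correlation matrix over concatenated
test bins, predicted-vs-actual peak firing rate following pattern onsets,
trial-to-trial variability (SD across trials), a maximum-likelihood Beta fit
of correlation histograms, and a train-on-checkerboard / test-on-shapes
generalization protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from lgnenc import cnn
from lgnenc.preprocess import RateMatrix
from lgnenc.stimulus import StimulusSequence

__all__ = [
    "EvalReport",
    "split_folds",
    "trial_bins",
    "prediction_correlation",
    "correlation_matrix",
    "peak_rate_analysis",
    "trial_variability",
    "fit_beta",
    "cross_validate",
    "generalization_eval",
]

SCHEMES = ("per_pixel_trials", "per_pattern")


@dataclass
class EvalReport:
    """Cross-validation results for one model on one recording."""

    per_neuron_corr: np.ndarray  # (N,) mean over test trials and folds
    corr_matrix: np.ndarray  # (N, N) over concatenated test bins
    peak_rate_pairs: np.ndarray  # (n_pairs, 2) actual vs predicted
    peak_rate_r2: float
    trial_sd_pairs: np.ndarray  # (N, 2) actual vs predicted SD
    beta_fit: tuple[float, float] | None
    fold_assignments: list[list[int]]
    n_skipped_trials: int = 0
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_neuron_corr": self.per_neuron_corr.tolist(),
            "corr_matrix": self.corr_matrix.tolist(),
            "peak_rate_pairs": self.peak_rate_pairs.tolist(),
            "peak_rate_r2": self.peak_rate_r2,
            "trial_sd_pairs": self.trial_sd_pairs.tolist(),
            "beta_fit": list(self.beta_fit) if self.beta_fit else None,
            "fold_assignments": self.fold_assignments,
            "n_skipped_trials": self.n_skipped_trials,
            "meta": self.meta,
        }


def split_folds(
    markers: list[tuple[int, int, int]],
    scheme: str = "per_pixel_trials",
    k: int = 5,
    seed: int | None = 0,
) -> list[list[int]]:
    """Assign trial blocks to k cross-validation test sets.

    Returns a list of k disjoint trial-index lists that together cover all
    trials.  ``per_pixel_trials`` partitions each pattern's own trials into k
    near-equal blocks; ``per_pattern`` holds out whole patterns (near-equal
    pattern groups, seed-controlled, since k rarely divides the pattern
    count evenly).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    rng = np.random.default_rng(seed)
    by_pattern: dict[int, list[int]] = {}
    for trial_idx, pattern_id, _ in markers:
        by_pattern.setdefault(pattern_id, []).append(trial_idx)
    folds: list[list[int]] = [[] for _ in range(k)]
    if scheme == "per_pixel_trials":
        for pid, trials in by_pattern.items():
            if len(trials) < k:
                raise ValueError(
                    f"pattern {pid} has {len(trials)} trials, fewer than k={k}"
                )
            order = rng.permutation(len(trials))
            for f, chunk in enumerate(np.array_split(order, k)):
                folds[f].extend(trials[i] for i in chunk)
    else:
        pids = sorted(by_pattern)
        if len(pids) < k:
            raise ValueError(f"{len(pids)} patterns, fewer than k={k}")
        order = rng.permutation(len(pids))
        for f, chunk in enumerate(np.array_split(order, k)):
            for i in chunk:
                folds[f].extend(by_pattern[pids[i]])
    return [sorted(f) for f in folds]


def trial_bins(
    markers: list[tuple[int, int, int]], w_ms: int, trial_len_ms: int, n_bins: int
) -> dict[int, np.ndarray]:
    """Bin indices covered by each trial block (trials extending past the
    binned recording are truncated)."""
    out = {}
    for trial_idx, _, onset in markers:
        b0 = onset // w_ms
        b1 = min((onset + trial_len_ms) // w_ms, n_bins)
        out[trial_idx] = np.arange(b0, b1)
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else np.nan


def prediction_correlation(
    actual: np.ndarray,
    predicted: np.ndarray,
    trial_slices: list[np.ndarray],
) -> tuple[np.ndarray, int]:
    """Per-neuron correlation averaged over test trials.

    ``actual`` and ``predicted`` are (n_bins, N) with NaN rows where no
    prediction exists; ``trial_slices`` lists the bin indices of each test
    trial.  Trials where either series has zero variance (e.g. no spikes)
    are skipped and counted, not imputed.  Returns
    ``(mean corr per neuron, number of skipped neuron-trials)``.
    """
    N = actual.shape[1]
    sums = np.zeros(N)
    counts = np.zeros(N, dtype=int)
    skipped = 0
    for bins in trial_slices:
        valid = bins[bins < len(predicted)]
        valid = valid[~np.isnan(predicted[valid]).any(axis=1)]
        if len(valid) < 2:
            skipped += N
            continue
        for n in range(N):
            r = _pearson(actual[valid, n], predicted[valid, n])
            if np.isnan(r):
                skipped += 1
            else:
                sums[n] += r
                counts[n] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return mean, skipped


def correlation_matrix(actual: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Entry (i, j) = corr(actual neuron i, predicted neuron j) over all bins."""
    mask = ~np.isnan(predicted).any(axis=1) & ~np.isnan(actual).any(axis=1)
    a, p = actual[mask], predicted[mask]
    N = a.shape[1]
    out = np.empty((N, N))
    for i in range(N):
        for j in range(N):
            out[i, j] = _pearson(a[:, i], p[:, j])
    return out


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


def peak_rate_analysis(
    actual: np.ndarray,
    predicted: np.ndarray,
    markers: list[tuple[int, int, int]],
    w_ms: int,
    on_ms: int = 200,
    trial_len_ms: int = 500,
) -> tuple[np.ndarray, float]:
    """Peak firing rate following pattern onset, actual vs predicted.

    For every (neuron, pattern) pair the peak is the maximum of the
    trial-averaged rate within the ON window after onset.  Returns the pairs
    and the least-squares r^2 of predicted against actual.
    """
    n_bins = len(actual)
    on_bins = max(1, on_ms // w_ms)
    by_pattern: dict[int, list[int]] = {}
    for _, pid, onset in markers:
        by_pattern.setdefault(pid, []).append(onset)
    pairs = []
    for pid, onsets in by_pattern.items():
        acc_a, acc_p, n_tr = 0.0, 0.0, 0
        stack_a, stack_p = [], []
        for onset in onsets:
            b0 = onset // w_ms
            if b0 + on_bins > n_bins:
                continue
            seg_a = actual[b0 : b0 + on_bins]
            seg_p = predicted[b0 : b0 + on_bins]
            if np.isnan(seg_p).any():
                continue
            stack_a.append(seg_a)
            stack_p.append(seg_p)
        if not stack_a:
            continue
        mean_a = np.mean(stack_a, axis=0)  # (on_bins, N)
        mean_p = np.mean(stack_p, axis=0)
        for n in range(actual.shape[1]):
            pairs.append((mean_a[:, n].max(), mean_p[:, n].max()))
    pairs_arr = np.array(pairs)
    if len(pairs_arr) < 2 or np.std(pairs_arr[:, 0]) == 0:
        return pairs_arr, np.nan
    return pairs_arr, _r_squared(pairs_arr[:, 0], pairs_arr[:, 1])


def trial_variability(
    actual: np.ndarray,
    predicted: np.ndarray,
    trial_slices: list[np.ndarray],
    mode: str = "trial_mean",
) -> np.ndarray:
    """Trial-to-trial variability: per-neuron SD across trials.

    ``trial_mean`` (default) takes the SD across trials of each trial's mean
    rate; ``binwise`` averages the per-bin SD across trials (trials must
    share a common length for the latter).  Returns (N, 2): actual and
    predicted SD per neuron.
    """
    if mode not in ("trial_mean", "binwise"):
        raise ValueError("mode must be 'trial_mean' or 'binwise'")
    valid_slices = []
    for bins in trial_slices:
        bins = bins[bins < len(predicted)]
        if len(bins) and not np.isnan(predicted[bins]).any():
            valid_slices.append(bins)
    if len(valid_slices) < 2:
        raise ValueError("need at least two complete trials")
    if mode == "trial_mean":
        a = np.stack([actual[b].mean(axis=0) for b in valid_slices])
        p = np.stack([predicted[b].mean(axis=0) for b in valid_slices])
        return np.stack([a.std(axis=0), p.std(axis=0)], axis=1)
    n = min(len(b) for b in valid_slices)
    a = np.stack([actual[b[:n]] for b in valid_slices])  # (trials, n, N)
    p = np.stack([predicted[b[:n]] for b in valid_slices])
    return np.stack([a.std(axis=0).mean(axis=0), p.std(axis=0).mean(axis=0)], axis=1)


def fit_beta(correlations: np.ndarray, eps: float = 1e-4) -> tuple[float, float, float]:
    """Maximum-likelihood Beta fit of a correlation histogram.

    Values are shrunk into the open interval (eps, 1 - eps); returns
    ``(alpha, beta, loglik)``.  Degenerate (constant) input is rejected.
    """
    x = np.clip(np.asarray(correlations, dtype=float), eps, 1.0 - eps)
    if len(x) < 2 or np.std(x) == 0:
        raise ValueError("degenerate correlation sample; Beta fit undefined")
    a, b, _, _ = stats.beta.fit(x, floc=0.0, fscale=1.0)
    ll = float(np.sum(stats.beta.logpdf(x, a, b)))
    return float(a), float(b), ll


# ---------------------------------------------------------------------------
# cross-validation drivers


def _masked_predictions(
    model: cnn.EncoderModel,
    samples: cnn.SampleBatch,
    test_idx: np.ndarray,
    n_bins: int,
    n_neurons: int,
) -> np.ndarray:
    """Predict the test samples and scatter them onto the full bin grid."""
    pred_full = np.full((n_bins, n_neurons), np.nan)
    if len(test_idx):
        pred = cnn.predict(model, samples.subset(test_idx))
        pred_full[samples.bin_index[test_idx]] = pred
    return pred_full


def cross_validate(
    stimulus: StimulusSequence,
    rates: RateMatrix,
    cfg: cnn.EncoderConfig,
    scheme: str = "per_pattern",
    k: int = 5,
    seed: int | None = 0,
    epochs: int | None = None,
) -> EvalReport:
    """K-fold cross-validation of the convolutional encoder.

    Samples are assigned to folds by the trial block containing their target
    bin.  Each fold trains a fresh model on the training trials and predicts
    the held-out trials; metrics aggregate over all folds.
    """
    samples = cnn.assemble_samples(stimulus, rates, cfg)
    folds = split_folds(stimulus.markers, scheme=scheme, k=k, seed=seed)
    tb = trial_bins(stimulus.markers, rates.w_ms, stimulus.trial_len_ms, rates.n_bins)
    bin_to_trial = np.full(rates.n_bins, -1, dtype=int)
    for t_idx, bins in tb.items():
        bin_to_trial[bins] = t_idx
    sample_trial = bin_to_trial[samples.bin_index]

    actual = rates.rates
    predicted = np.full_like(actual, np.nan, dtype=float)
    for f, test_trials in enumerate(folds):
        test_set = set(test_trials)
        is_test = np.isin(sample_trial, list(test_set))
        train_idx = np.flatnonzero(~is_test & (sample_trial >= 0))
        test_idx = np.flatnonzero(is_test)
        fold_cfg = cnn.EncoderConfig(**{**cfg.__dict__, "seed": cfg.seed + f})
        model = cnn.build_model(fold_cfg)
        cnn.train(model, samples.subset(train_idx), epochs=epochs)
        pred_fold = _masked_predictions(model, samples, test_idx, rates.n_bins, rates.n_neurons)
        fill = ~np.isnan(pred_fold).any(axis=1)
        predicted[fill] = pred_fold[fill]

    slices = [tb[t] for f in folds for t in f]
    per_neuron, skipped = prediction_correlation(actual, predicted, slices)
    corr_mat = correlation_matrix(actual, predicted)
    pairs, r2 = peak_rate_analysis(
        actual, predicted, stimulus.markers, rates.w_ms, stimulus.on_ms, stimulus.trial_len_ms
    )
    sd_pairs = trial_variability(actual, predicted, slices)
    beta = None
    try:
        beta_a, beta_b, _ = fit_beta(np.clip(per_neuron[~np.isnan(per_neuron)], 0, 1))
        beta = (beta_a, beta_b)
    except (ValueError, RuntimeError):
        warnings.warn("Beta fit of per-neuron correlations failed", stacklevel=2)
    return EvalReport(
        per_neuron_corr=per_neuron,
        corr_matrix=corr_mat,
        peak_rate_pairs=pairs,
        peak_rate_r2=r2,
        trial_sd_pairs=sd_pairs,
        beta_fit=beta,
        fold_assignments=folds,
        n_skipped_trials=skipped,
        meta={"scheme": scheme, "k": k, "seed": seed, "variant": cfg.variant, "w_ms": cfg.w_ms},
    )


def generalization_eval(
    model: cnn.EncoderModel,
    shapes_stimulus: StimulusSequence,
    shapes_rates: RateMatrix,
) -> EvalReport:
    """Evaluate a model trained elsewhere (e.g. on the full checkerboard set)
    on a shapes recording, with no retraining.

    The report's ``meta['trained_on_test_data']`` audit field records that
    the model saw none of these trials during training.
    """
    samples = cnn.assemble_samples(shapes_stimulus, shapes_rates, model.cfg)
    pred_full = _masked_predictions(
        model, samples, np.arange(len(samples)), shapes_rates.n_bins, shapes_rates.n_neurons
    )
    tb = trial_bins(
        shapes_stimulus.markers,
        shapes_rates.w_ms,
        shapes_stimulus.trial_len_ms,
        shapes_rates.n_bins,
    )
    slices = list(tb.values())
    actual = shapes_rates.rates
    per_neuron, skipped = prediction_correlation(actual, pred_full, slices)
    pairs, r2 = peak_rate_analysis(
        actual,
        pred_full,
        shapes_stimulus.markers,
        shapes_rates.w_ms,
        shapes_stimulus.on_ms,
        shapes_stimulus.trial_len_ms,
    )
    return EvalReport(
        per_neuron_corr=per_neuron,
        corr_matrix=correlation_matrix(actual, pred_full),
        peak_rate_pairs=pairs,
        peak_rate_r2=r2,
        trial_sd_pairs=trial_variability(actual, pred_full, slices),
        beta_fit=None,
        fold_assignments=[sorted(tb)],
        n_skipped_trials=skipped,
        meta={"protocol": "generalization", "trained_on_test_data": False},
    )
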