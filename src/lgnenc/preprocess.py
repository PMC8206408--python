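"""Spike-train preprocessing: detection, alignment, sorting, binning, PSTH.

Raw traces are thresholded at ``k`` times a robust estimate of the noise
standard deviation (median(|x|)/0.6745, insensitive to embedded spikes),
waveform snippets are cut 0.75 ms pre / 2 ms post threshold crossing,
aligned at their trough, reduced to their first two principal components and
clustered with K-means into single units.  Spike trains are then binned into
firing rates (spike count per bin divided by the bin width in seconds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from lgnenc.simulate import SpikeData

__all__ = [
    "RateMatrix",
    "WaveformSet",
    "robust_noise_sd",
    "detect_spikes",
    "align_troughs",
    "sort_units",
    "bin_rates",
    "psth",
]


@dataclass
class RateMatrix:
    """Binned firing rates in spikes/s, shape (n_bins, N).

    Bin k (1-based) covers the half-open interval ((k-1)*w, k*w] ms; a
    trailing partial bin shorter than w is dropped.
    """

    rates: np.ndarray
    w_ms: int
    t0: int = 0

    @property
    def n_bins(self) -> int:
        return int(self.rates.shape[0])

    @property
    def n_neurons(self) -> int:
        return int(self.rates.shape[1])

    def counts(self) -> np.ndarray:
        """Spike counts per bin (inverse of the rate conversion)."""
        return np.rint(self.rates * (self.w_ms / 1000.0)).astype(int)


@dataclass
class WaveformSet:
    """Aligned spike waveform snippets from one channel."""

    snippets: np.ndarray  # (n_spikes, n_samples)
    spike_times: np.ndarray  # sample indices of the threshold crossing/trough
    fs: float
    channel_id: int = 0
    threshold: float = 0.0
    pre_samples: int = 0

    @property
    def n_spikes(self) -> int:
        return int(self.snippets.shape[0])


def robust_noise_sd(trace: np.ndarray) -> float:
    """Median-based noise SD estimate, median(|x|)/0.6745."""
    return float(np.median(np.abs(trace)) / 0.6745)


def detect_spikes(
    trace: np.ndarray,
    fs: float = 25_000.0,
    k: float = 3.0,
    pre_ms: float = 0.75,
    post_ms: float = 2.0,
) -> WaveformSet:
    """Detect negative threshold crossings and cut waveform snippets.

    The threshold is ``k`` times the robust noise SD; detections are the
    trough of each sub-threshold excursion, with excursions closer than the
    snippet window merged to the larger (deeper) one.  At 25 kHz the default
    window is 19 pre-samples (0.75 ms, rounded up from 18.75) and 50
    post-samples (2 ms).
    """
    trace = np.asarray(trace, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    sd = robust_noise_sd(trace)
    if sd == 0.0:
        raise ValueError("flat trace: noise SD is zero, cannot set threshold")
    thr = k * sd
    pre = int(np.ceil(pre_ms * fs / 1000.0))
    post = int(round(post_ms * fs / 1000.0))
    if len(trace) <= pre + post:
        raise ValueError("trace shorter than one snippet window")

    below = trace < -thr
    # excursion starts/ends
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        ends = np.r_[ends, len(trace)]
    troughs = np.array(
        [s + int(np.argmin(trace[s:e])) for s, e in zip(starts, ends)], dtype=int
    )
    # merge detections within the refractory window, keeping the deeper one
    merged: list[int] = []
    refractory = pre + post
    for t in troughs:
        if merged and t - merged[-1] < refractory:
            if trace[t] < trace[merged[-1]]:
                merged[-1] = t
        else:
            merged.append(t)
    times = np.array([t for t in merged if pre <= t <= len(trace) - post], dtype=int)
    snippets = np.stack([trace[t - pre : t + post] for t in times]) if len(times) else np.empty((0, pre + post))
    return WaveformSet(
        snippets=snippets, spike_times=times, fs=fs, threshold=thr, pre_samples=pre
    )


def align_troughs(ws: WaveformSet) -> WaveformSet:
    """Shift snippets so every trough sits at the same sample index.

    The common index is the median trough position; vacated samples are
    edge-padded and spike times are shifted by the same amount.
    """
    if ws.n_spikes == 0:
        return ws
    mins = ws.snippets.argmin(axis=1)
    target = int(np.median(mins))
    aligned = np.empty_like(ws.snippets)
    new_times = ws.spike_times.copy()
    for i, (snip, m) in enumerate(zip(ws.snippets, mins)):
        shift = int(m) - target
        if shift > 0:
            aligned[i, :-shift] = snip[shift:]
            aligned[i, -shift:] = snip[-1]
        elif shift < 0:
            aligned[i, -shift:] = snip[:shift]
            aligned[i, : -shift] = snip[0]
        else:
            aligned[i] = snip
        new_times[i] = ws.spike_times[i] + shift
    return WaveformSet(
        snippets=aligned,
        spike_times=new_times,
        fs=ws.fs,
        channel_id=ws.channel_id,
        threshold=ws.threshold,
        pre_samples=ws.pre_samples,
    )


def sort_units(
    ws: WaveformSet, n_units: int, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster waveforms into single units.

    PCA on the aligned snippets, first two scores as features, K-means with
    ``n_units`` clusters (k-means++ init, fixed seed). Returns
    ``(labels, scores)`` where scores are the two PC projections.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if n_units > ws.n_spikes:
        raise ValueError(f"n_units={n_units} exceeds number of spikes ({ws.n_spikes})")
    scores = PCA(n_components=2, random_state=seed).fit_transform(ws.snippets)
    km = KMeans(n_clusters=n_units, n_init=10, random_state=seed)
    labels = km.fit_predict(scores)
    return labels, scores


def bin_rates(spikes: SpikeData, w_ms: int) -> RateMatrix:
    """Bin spike trains into firing rates (spikes/s)."""
    if w_ms <= 0:
        raise ValueError("w_ms must be positive")
    T, N = spikes.trains.shape
    n_bins = T // w_ms
    counts = spikes.trains[: n_bins * w_ms].reshape(n_bins, w_ms, N).sum(axis=1)
    return RateMatrix(rates=counts / (w_ms / 1000.0), w_ms=w_ms)


def psth(
    spikes: SpikeData,
    markers: list[tuple[int, int, int]] | None = None,
    bin_ms: int = 10,
    window_ms: int | None = None,
) -> tuple[np.ndarray, np.ndarray, list[list[np.ndarray]]]:
    """Post-stimulus time histogram and raster aligned to trial onsets.

    Returns ``(hist, edges, raster)``: ``hist`` is the mean spike count per
    trial per bin, shape (n_bins, N); ``edges`` the bin edges in ms relative
    to onset; ``raster[n][trial]`` the spike times of neuron ``n`` in that
    trial, relative to its onset.
    """
    markers = markers if markers is not None else spikes.markers
    if not markers:
        raise ValueError("no trial markers")
    if window_ms is None:
        onsets = [m[2] for m in markers]
        window_ms = min(b - a for a, b in zip(onsets, onsets[1:])) if len(onsets) > 1 else (
            spikes.duration_ms - onsets[0]
        )
    n_bins = window_ms // bin_ms
    edges = np.arange(n_bins + 1) * bin_ms
    T, N = spikes.trains.shape
    counts = np.zeros((n_bins, N))
    raster: list[list[np.ndarray]] = [[] for _ in range(N)]
    n_trials = 0
    for _, _, onset in markers:
        if onset + n_bins * bin_ms > T:
            continue
        seg = spikes.trains[onset : onset + n_bins * bin_ms]
        counts += seg.reshape(n_bins, bin_ms, N).sum(axis=1)
        n_trials += 1
        for n in range(N):
            raster[n].append(np.flatnonzero(seg[:, n]))
    if n_trials == 0:
        raise ValueError("no complete trials within the recording")
    return counts / n_trials, edges, raster
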