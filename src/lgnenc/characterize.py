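"""Neuron characterization: responsiveness, temporal class, receptive fields.

* Responsiveness index ``R = 10*log10(max(PSD(f), PSD(2f), PSD(3f)))`` of a
  neuron's binned firing rate, with ``f`` the periodic stimulation frequency
  (2 Hz for the default 200/300 ms cycle).  The PSD is a periodogram of the
  mean-subtracted rate with a rectangular window, harmonics looked up at the
  nearest frequency bin.
* Transient-sustained ratio ``tsr = Spk_t / Spk_s``: mean spikes per trial
  inside the 100 ms windows after stimulus onset and offset over the mean
  spikes per trial of the whole cycle; neurons with tsr > 0.5 are classified
  transient, otherwise sustained.
* Spike-triggered average (STA): mean stimulus in the window preceding each
  spike; its time integral per pixel, min-max normalized, is the receptive
  field matrix.  A neuron whose best pixel's STA is high at short pre-spike
  lags is ON, low is OFF.
* Adjusted correlation ``(corr + (1 - R_norm)) / 2`` discounts prediction
  correlations by population-normalized responsiveness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from lgnenc.simulate import SpikeData
from lgnenc.stimulus import StimulusSequence

__all__ = [
    "NeuronProfile",
    "responsiveness_index",
    "normalize_responsiveness",
    "transient_sustained_ratio",
    "sta_receptive_field",
    "classify_on_off",
    "adjusted_correlation",
    "profile_population",
]

FLOOR_DB = -100.0


@dataclass
class NeuronProfile:
    """Summary of one neuron's response properties."""

    neuron_id: int
    r_db: float
    r_norm: float | None
    tsr: float
    temporal_class: str
    rf: np.ndarray
    spatial_class: str


def responsiveness_index(
    rate: np.ndarray,
    w_ms: int,
    f_hz: float = 2.0,
    floor_db: float = FLOOR_DB,
) -> float:
    """Responsiveness index in dB from the rate periodogram.

    ``rate`` is one neuron's binned firing-rate series on a ``w_ms`` grid.
    Power is read at the nearest periodogram bins to f, 2f and 3f; zero power
    at all three harmonics returns ``floor_db`` with a warning.
    """
    rate = np.asarray(rate, dtype=float)
    fs = 1000.0 / w_ms
    if 3 * f_hz > fs / 2:
        raise ValueError(
            f"third harmonic {3 * f_hz} Hz above Nyquist {fs / 2} Hz of the rate sampling"
        )
    if len(rate) < 3 * fs / f_hz:
        raise ValueError("rate series shorter than three stimulus periods")
    freqs, psd = periodogram(rate - rate.mean(), fs=fs, window="boxcar", detrend=False)
    power = max(
        float(psd[np.argmin(np.abs(freqs - h * f_hz))]) for h in (1, 2, 3)
    )
    if power <= 0.0:
        warnings.warn("no power at stimulus harmonics; returning floor", stacklevel=2)
        return floor_db
    return float(10.0 * np.log10(power))


def harmonic_power(rate: np.ndarray, w_ms: int, f_hz: float = 2.0) -> float:
    """Linear-scale harmonic maximum used inside :func:`responsiveness_index`."""
    r = responsiveness_index(rate, w_ms, f_hz)
    return float(10 ** (r / 10.0))


def normalize_responsiveness(r_db: np.ndarray) -> np.ndarray:
    """Min-max normalize responsiveness indices over a population to [0, 1].

    Implemented as (R - min) / (max - min); the degenerate all-equal case
    returns zeros with a warning.
    """
    r = np.asarray(r_db, dtype=float)
    lo, hi = r.min(), r.max()
    if hi == lo:
        warnings.warn("all responsiveness values equal; returning zeros", stacklevel=2)
        return np.zeros_like(r)
    return (r - lo) / (hi - lo)


def transient_sustained_ratio(
    spikes: SpikeData,
    neuron: int,
    markers: list[tuple[int, int, int]] | None = None,
    on_ms: int = 200,
    trial_len_ms: int = 500,
    window_ms: int = 100,
) -> tuple[float, str]:
    """Transient-sustained ratio and temporal class of one neuron.

    ``Spk_t`` counts spikes inside [onset, onset+window) and
    [offset, offset+window) where offset = onset + on_ms; ``Spk_s`` counts
    spikes over the whole trial; both are averaged across trials.
    """
    markers = markers if markers is not None else spikes.markers
    if not markers:
        raise ValueError("no trial markers")
    train = spikes.trains[:, neuron]
    T = len(train)
    spk_t = spk_s = 0
    n_trials = 0
    for _, _, onset in markers:
        if onset + trial_len_ms > T:
            continue
        n_trials += 1
        spk_s += int(train[onset : onset + trial_len_ms].sum())
        spk_t += int(train[onset : onset + window_ms].sum())
        spk_t += int(train[onset + on_ms : onset + on_ms + window_ms].sum())
    if n_trials == 0:
        raise ValueError("no complete trials within the recording")
    if spk_s == 0:
        raise ValueError("neuron fired no spikes; tsr undefined")
    tsr = (spk_t / n_trials) / (spk_s / n_trials)
    return tsr, ("transient" if tsr > 0.5 else "sustained")


def sta_receptive_field(
    spikes: SpikeData,
    stimulus: StimulusSequence,
    neuron: int,
    lag_ms: int = 500,
    min_spikes: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike-triggered average and receptive field of one neuron.

    Returns ``(rf, sta)``: ``sta[tau-1, p]`` is the mean intensity of pixel
    ``p`` at ``tau`` ms before a spike (tau = 1..lag_ms, spikes earlier than
    ``lag_ms`` excluded), and ``rf`` is the per-pixel time integral of the
    STA reshaped to the grid and min-max normalized.
    """
    frames = stimulus.frames.astype(float)
    T, P = frames.shape
    times = spikes.spike_times(neuron)
    times = times[times >= lag_ms]
    if len(times) == 0:
        raise ValueError("no spikes at or beyond lag_ms; STA undefined")
    if len(times) < min_spikes:
        warnings.warn(
            f"only {len(times)} spikes available for the STA (< {min_spikes}); "
            "estimate will be noisy",
            stacklevel=2,
        )
    # sta rows ordered tau = 1 (just before the spike) .. lag_ms
    sta = np.zeros((lag_ms, P))
    for chunk in np.array_split(times, max(1, len(times) // 512)):
        # windows: for spike t, stimulus at t - tau
        idx = chunk[:, None] - np.arange(1, lag_ms + 1)[None, :]
        sta += frames[idx].sum(axis=0)
    sta /= len(times)
    integral = sta.sum(axis=0)
    lo, hi = integral.min(), integral.max()
    if hi == lo:
        warnings.warn("flat STA integral; receptive field undefined", stacklevel=2)
        rf = np.zeros(P)
    else:
        rf = (integral - lo) / (hi - lo)
    return rf.reshape(stimulus.grid_shape), sta


def classify_on_off(sta: np.ndarray, on_ms: int = 200, recent_ms: int = 30) -> str:
    """ON/OFF classification from the STA of the best-responding pixel.

    The best pixel is the one with the largest time-integrated STA; if its
    average at short pre-spike lags exceeds its full-window mean the neuron
    is ON (the stimulus tends to be on just before its spikes), otherwise
    OFF.  The short-lag window defaults to 30 ms -- well below the ON
    duration, because transient neurons spike early in the ON period and
    longer windows dilute the onset signature.
    """
    best = int(np.argmax(sta.sum(axis=0)))
    trace = sta[:, best]
    recent = trace[: min(recent_ms, on_ms)].mean()
    return "ON" if recent > trace.mean() else "OFF"


def adjusted_correlation(corr: float | np.ndarray, r_norm: float | np.ndarray) -> np.ndarray:
    """Responsiveness-adjusted correlation, (corr + (1 - R_norm)) / 2.

    Maps [0,1] x [0,1] into [0,1]; negative correlations are clipped to 0
    with a warning (the measure assumes correlations in [0, 1]).
    """
    corr = np.asarray(corr, dtype=float)
    r_norm = np.asarray(r_norm, dtype=float)
    if np.any(r_norm < 0) or np.any(r_norm > 1):
        raise ValueError("r_norm must lie in [0, 1]")
    if np.any(corr > 1):
        raise ValueError("corr must not exceed 1")
    if np.any(corr < 0):
        warnings.warn("negative correlations clipped to 0", stacklevel=2)
        corr = np.clip(corr, 0.0, 1.0)
    return (corr + (1.0 - r_norm)) / 2.0


def profile_population(
    spikes: SpikeData,
    stimulus: StimulusSequence,
    w_ms: int = 50,
    lag_ms: int = 500,
) -> list[NeuronProfile]:
    """Characterize every neuron of a recording against its stimulus."""
    from lgnenc.preprocess import bin_rates

    rates = bin_rates(spikes, w_ms).rates
    f_hz = stimulus.frequency_hz
    r_db = np.array(
        [responsiveness_index(rates[:, i], w_ms, f_hz) for i in range(spikes.n_neurons)]
    )
    r_norm = normalize_responsiveness(r_db) if spikes.n_neurons > 1 else np.full(1, np.nan)
    profiles = []
    for i in range(spikes.n_neurons):
        tsr, t_class = transient_sustained_ratio(
            spikes, i, on_ms=stimulus.on_ms, trial_len_ms=stimulus.trial_len_ms
        )
        rf, sta = sta_receptive_field(spikes, stimulus, i, lag_ms=lag_ms)
        profiles.append(
            NeuronProfile(
                neuron_id=spikes.neuron_ids[i],
                r_db=float(r_db[i]),
                r_norm=float(r_norm[i]),
                tsr=tsr,
                temporal_class=t_class,
                rf=rf,
                spatial_class=classify_on_off(sta, on_ms=stimulus.on_ms),
            )
        )
    return profiles
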