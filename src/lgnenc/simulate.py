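"""Synthetic LGN population: a linear-nonlinear-Poisson (LNP) simulator.

Each neuron has a Gaussian spatial receptive field on the stimulation grid,
an ON or OFF polarity, a transient (exponentially decaying) or sustained
(boxcar) temporal kernel, and a stimulus-locking factor ``snr`` that scales
the stimulus-driven intensity relative to the baseline.  Spiking is drawn
per millisecond as Bernoulli(lambda * 1 ms), the standard discrete-time
approximation of an inhomogeneous Poisson process.

Onset drive is the rectified positive temporal derivative of the
RF-weighted stimulus and offset drive the rectified negative derivative;
OFF-polarity neurons swap the two.  Optional pairwise coupling adds a
weighted, exponentially filtered copy of other neurons' recent spiking to
the intensity, which makes population firing history informative for the
encoder models.

:func:`simulate_raw_trace` additionally embeds per-neuron biphasic spike
templates in Gaussian noise at 25 kHz, providing ground-truth input for the
spike detection/sorting stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from lgnenc.stimulus import StimulusSequence

__all__ = [
    "NeuronSpec",
    "SpikeData",
    "default_population",
    "compute_intensity",
    "simulate_population",
    "simulate_raw_trace",
    "spike_template",
]

TRANSIENT_TAU_MS = 50.0
TRANSIENT_LEN_MS = 300
SUSTAINED_LEN_MS = 200
COUPLING_TAU_MS = 30.0


@dataclass
class NeuronSpec:
    """Ground-truth parameters of one synthetic neuron."""

    rf_center: tuple[int, int]
    rf_sigma: float = 0.8
    polarity: str = "ON"  # "ON" | "OFF"
    kernel: str = "transient"  # "transient" | "sustained"
    onset_gain: float = 100.0  # spikes/s
    offset_gain: float = 50.0  # spikes/s
    baseline: float = 2.0  # spikes/s
    snr: float = 1.0  # stimulus-locking factor in [0, 1]
    coupling: dict[int, float] | None = None  # neuron index -> weight

    def __post_init__(self) -> None:
        if self.polarity not in ("ON", "OFF"):
            raise ValueError(f"polarity must be ON or OFF, got {self.polarity!r}")
        if self.kernel not in ("transient", "sustained"):
            raise ValueError(f"kernel must be transient or sustained, got {self.kernel!r}")
        if self.onset_gain < 0 or self.offset_gain < 0 or self.baseline < 0:
            raise ValueError("gains and baseline must be non-negative")
        if not 0.0 <= self.snr <= 1.0:
            raise ValueError(f"snr must be in [0, 1], got {self.snr}")


@dataclass
class SpikeData:
    """Per-neuron binary spike trains at 1 ms resolution.

    ``trains`` is (T, N) with entries in {0, 1}; the time axis matches the
    driving stimulus and ``markers`` are shared with it.
    """

    trains: np.ndarray
    neuron_ids: list[int] = field(default_factory=list)
    markers: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.neuron_ids:
            self.neuron_ids = list(range(self.trains.shape[1]))

    @property
    def n_neurons(self) -> int:
        return int(self.trains.shape[1])

    @property
    def duration_ms(self) -> int:
        return int(self.trains.shape[0])

    def spike_times(self, neuron: int) -> np.ndarray:
        return np.flatnonzero(self.trains[:, neuron])


def default_population(
    n: int = 12,
    grid: tuple[int, int] = (4, 8),
    seed: int | None = 0,
    frac_transient: float = 0.6,
    frac_on: float = 0.6,
    snr_range: tuple[float, float] = (0.2, 1.0),
    coupled: bool = False,
) -> list[NeuronSpec]:
    """Default population preset: mixed transient/sustained and ON/OFF
    classes with stimulus locking drawn uniformly from ``snr_range``."""
    rng = np.random.default_rng(seed)
    rows, cols = grid
    specs = []
    n_transient = int(round(frac_transient * n))
    n_on = int(round(frac_on * n))
    for i in range(n):
        coupling = None
        if coupled and n > 1:
            partners = rng.choice([j for j in range(n) if j != i], size=min(3, n - 1), replace=False)
            coupling = {int(j): float(rng.uniform(0.05, 0.15)) for j in partners}
        specs.append(
            NeuronSpec(
                rf_center=(int(rng.integers(rows)), int(rng.integers(cols))),
                rf_sigma=float(rng.uniform(0.6, 1.2)),
                polarity="ON" if i < n_on else "OFF",
                kernel="transient" if i < n_transient else "sustained",
                onset_gain=float(rng.uniform(80, 150)),
                offset_gain=float(rng.uniform(30, 80)),
                baseline=float(rng.uniform(2, 8)),
                snr=float(rng.uniform(*snr_range)),
                coupling=coupling,
            )
        )
    return specs


def _rf_weights(spec: NeuronSpec, grid: tuple[int, int]) -> np.ndarray:
    rows, cols = grid
    r0, c0 = spec.rf_center
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError(f"rf_center {spec.rf_center} outside grid {grid}")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    w = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * spec.rf_sigma**2))
    return (w / w.sum()).ravel()


def _temporal_kernel(kind: str) -> np.ndarray:
    if kind == "transient":
        t = np.arange(TRANSIENT_LEN_MS)
        return np.exp(-t / TRANSIENT_TAU_MS)
    return np.ones(SUSTAINED_LEN_MS)


def compute_intensity(
    stimulus: StimulusSequence, specs: list[NeuronSpec]
) -> np.ndarray:
    """Stimulus-driven intensity lambda(t) in spikes/s, shape (T, N).

    Excludes coupling terms (those depend on realized spikes)."""
    if not specs:
        raise ValueError("specs must be non-empty")
    frames = stimulus.frames.astype(float)
    T = frames.shape[0]
    lam = np.zeros((T, len(specs)))
    for i, spec in enumerate(specs):
        w = _rf_weights(spec, stimulus.grid_shape)
        drive = frames @ w
        d = np.diff(drive, prepend=drive[:1])
        u_on = np.clip(d, 0.0, None)
        u_off = np.clip(-d, 0.0, None)
        if spec.polarity == "OFF":
            u_on, u_off = u_off, u_on
        k = _temporal_kernel(spec.kernel)
        driven = spec.onset_gain * np.convolve(u_on, k)[:T]
        driven += spec.offset_gain * np.convolve(u_off, k)[:T]
        lam[:, i] = spec.baseline + spec.snr * driven
    return lam


def _bernoulli_clip(p: np.ndarray) -> np.ndarray:
    if np.any(p > 1.0):
        warnings.warn("lambda * dt exceeded 1; clipping spike probability", stacklevel=3)
    return np.clip(p, 0.0, 1.0)


def simulate_population(
    stimulus: StimulusSequence,
    specs: list[NeuronSpec],
    seed: int | None = 0,
) -> SpikeData:
    """Draw spike trains from the LNP population model.

    Without coupling all neurons are conditionally independent given the
    stimulus and the draw is fully vectorized; with coupling the simulation
    steps through time, feeding each neuron an exponentially filtered
    (tau = 30 ms) spikes/s estimate of its partners' recent firing.
    """
    lam = compute_intensity(stimulus, specs)
    T, N = lam.shape
    rng = np.random.default_rng(seed)
    coupled = any(s.coupling for s in specs)
    if not coupled:
        p = _bernoulli_clip(lam / 1000.0)
        trains = (rng.random((T, N)) < p).astype(np.uint8)
    else:
        C = np.zeros((N, N))
        for i, s in enumerate(specs):
            for j, wgt in (s.coupling or {}).items():
                C[i, j] = wgt
        decay = np.exp(-1.0 / COUPLING_TAU_MS)
        gain = 1000.0 / COUPLING_TAU_MS  # converts filtered spikes to spikes/s
        trains = np.zeros((T, N), dtype=np.uint8)
        y = np.zeros(N)
        u = rng.random((T, N))
        clipped = False
        for t in range(T):
            p = (lam[t] + C @ y) / 1000.0
            clipped |= bool(np.any(p > 1.0))
            spikes = u[t] < np.clip(p, 0.0, 1.0)
            trains[t] = spikes
            y = y * decay + spikes * gain
        if clipped:
            warnings.warn("lambda * dt exceeded 1; clipping spike probability", stacklevel=2)
    return SpikeData(trains=trains, markers=list(stimulus.markers))


def spike_template(
    n_samples: int = 48, fs: float = 25_000.0, width_factor: float = 1.0, rebound: float = 0.35
) -> np.ndarray:
    """Biphasic, trough-dominant extracellular spike template, trough-normalized
    to -1.  ``width_factor`` and ``rebound`` differentiate units."""
    t = np.arange(n_samples) / fs * 1000.0  # ms
    trough = -np.exp(-((t - 0.4 * width_factor) ** 2) / (2 * (0.1 * width_factor) ** 2))
    hump = rebound * np.exp(-((t - 0.9 * width_factor) ** 2) / (2 * (0.25 * width_factor) ** 2))
    tpl = trough + hump
    return tpl / np.abs(tpl.min())


def simulate_raw_trace(
    spikes: SpikeData,
    template_amplitude: float | list[float] = 50.0,
    noise_sd: float = 5.0,
    fs: float = 25_000.0,
    seed: int | None = 0,
    templates: np.ndarray | None = None,
) -> np.ndarray:
    """Render spike trains as a single-channel extracellular trace.

    Gaussian noise of SD ``noise_sd`` plus, at every spike time, that
    neuron's biphasic template scaled by its amplitude.  Neurons sharing the
    channel get distinct template shapes (varying width/rebound).
    """
    rng = np.random.default_rng(seed)
    T_ms, N = spikes.trains.shape
    n_samp = int(round(T_ms * fs / 1000.0))
    trace = rng.normal(0.0, noise_sd, n_samp)
    amps = np.broadcast_to(np.atleast_1d(template_amplitude), (N,)).astype(float)
    if templates is None:
        templates = np.stack(
            [spike_template(fs=fs, width_factor=1.0 + 0.6 * i, rebound=0.3 + 0.2 * i) for i in range(N)]
        )
    for i in range(N):
        tpl = amps[i] * templates[i]
        for t_ms in spikes.spike_times(i):
            s0 = int(round(t_ms * fs / 1000.0))
            s1 = min(s0 + len(tpl), n_samp)
            trace[s0:s1] += tpl[: s1 - s0]
    return trace
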