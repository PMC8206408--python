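"""Dual-branch temporal-convolution firing-rate encoder.

The model predicts the firing rate of all ``N`` neurons at time bin ``k``
from two inputs: the visual stimulus matrix (pixel intensities over bins
``k - L + 1 .. k``, shape L x P) and the firing-history matrix (rates of all
neurons over bins ``k - L + 1 .. k - 1``, shape (L-1) x N).  Each branch is
one or more blocks of [length-preserving 1D temporal convolution -> PReLU ->
max pooling (size 2, stride 2)] followed by flattening; the branch feature
vectors are concatenated and passed through a 2-layer fully connected head
whose hidden and output layers each hold N PReLU units.  The number of
convolutional filters equals the channel count of the branch input (P for
visual, N for history) and each filter spans the full channel depth.

Variants: ``V-FH`` (both branches), ``V`` (visual only), ``FH`` (history
only).  One conv+pool block per branch at w = 50 ms; three cascaded blocks
at w = 10 ms.

Under the documented layer-counting convention -- conv, pool and flatten
per branch, plus the concatenation and the two fully connected layers
(activations are not counted) -- the dual-branch model has 9 layers at
w = 50 ms and 17 at w = 10 ms.

Training is plain numpy backpropagation: RMSE loss minimized by Adam
(lr 0.001, beta1 0.9, beta2 0.999), Xavier-uniform weight initialization
with zero biases, PReLU slopes shared per layer and initialized at 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from lgnenc.preprocess import RateMatrix
from lgnenc.stimulus import StimulusSequence, bin_stimulus

__all__ = [
    "EncoderConfig",
    "SampleBatch",
    "EncoderModel",
    "prelu",
    "build_model",
    "assemble_samples",
    "train",
    "predict",
]

VARIANTS = ("V-FH", "V", "FH")


def prelu(x: np.ndarray, alpha: float) -> np.ndarray:
    """Parametric ReLU: x for x > 0, alpha * x otherwise."""
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, alpha * x)


@dataclass
class EncoderConfig:
    """Hyperparameters of the encoder; ``L = 500 // w_ms`` time bins."""

    n_pixels: int
    n_neurons: int
    variant: str = "V-FH"
    w_ms: int = 50
    filter_len: int = 5
    conv_blocks: int | None = None  # defaults to 1 (w=50) or 3 (w=10)
    pool_size: int = 2
    pool_stride: int = 2
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 200
    batch_size: int = 64
    seed: int = 0
    clamp_negative: bool = False  # clamp predictions at zero

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if 500 % self.w_ms != 0:
            raise ValueError(f"w_ms must divide the 500 ms input window, got {self.w_ms}")
        if not 3 <= self.filter_len <= 8:
            raise ValueError(f"filter_len must lie in [3, 8], got {self.filter_len}")
        if self.conv_blocks is None:
            self.conv_blocks = 1 if self.w_ms >= 50 else 3
        if self.n_pixels < 1 or self.n_neurons < 1:
            raise ValueError("n_pixels and n_neurons must be positive")

    @property
    def L(self) -> int:
        return 500 // self.w_ms


@dataclass
class SampleBatch:
    """Training samples: one row per target time bin."""

    visual: np.ndarray  # (B, L, P)
    history: np.ndarray  # (B, L-1, N)
    target: np.ndarray  # (B, N)
    bin_index: np.ndarray  # (B,) target bin of each sample

    def __len__(self) -> int:
        return len(self.target)

    def subset(self, idx: np.ndarray) -> "SampleBatch":
        return SampleBatch(
            self.visual[idx], self.history[idx], self.target[idx], self.bin_index[idx]
        )


# ---------------------------------------------------------------------------
# layers


class _Layer:
    counted = True  # participates in the layer-count convention

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1D(_Layer):
    """Length-preserving temporal convolution over (B, T, C) inputs.

    ``n_filters`` output channels; each filter spans the full channel depth
    and ``filter_len`` time steps (asymmetric zero padding (K-1)//2 left,
    K//2 right keeps the output length equal to T).
    """

    name = "conv"

    def __init__(self, n_channels: int, n_filters: int, filter_len: int, rng: np.random.Generator):
        fan_in = filter_len * n_channels
        fan_out = filter_len * n_filters
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, (n_filters, filter_len, n_channels))
        self.b = np.zeros(n_filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.K = filter_len

    def forward(self, x: np.ndarray) -> np.ndarray:
        K = self.K
        pad_l, pad_r = (K - 1) // 2, K // 2
        xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
        self._win = sliding_window_view(xp, K, axis=1)  # (B, T, C, K)
        return np.einsum("btck,fkc->btf", self._win, self.W) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, T, _ = dy.shape
        K = self.K
        pad_l = (K - 1) // 2
        self.db[...] = dy.sum(axis=(0, 1))
        self.dW[...] = np.einsum("btck,btf->fkc", self._win, dy)
        C = self.W.shape[2]
        dxp = np.zeros((B, T + K - 1, C))
        for k in range(K):
            dxp[:, k : k + T, :] += np.einsum("btf,fc->btc", dy, self.W[:, k, :])
        return dxp[:, pad_l : pad_l + T, :]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class PReLULayer(_Layer):
    """Shared-slope PReLU; the slope is a single trainable scalar per layer."""

    name = "prelu"
    counted = False

    def __init__(self, alpha: float = 0.25):
        self.alpha = np.array([alpha])
        self.dalpha = np.zeros(1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.where(x > 0, x, self.alpha[0] * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        neg = x <= 0
        self.dalpha[0] = float((dy * x * neg).sum())
        return dy * np.where(neg, self.alpha[0], 1.0)

    def params(self):
        return [self.alpha]

    def grads(self):
        return [self.dalpha]


class MaxPool1D(_Layer):
    """Temporal max pooling, size 2 / stride 2; odd lengths floor-divide."""

    name = "pool"

    def __init__(self, size: int = 2, stride: int = 2):
        if size != stride:
            raise ValueError("only non-overlapping pooling (size == stride) is supported")
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        n_out = T // self.size
        if n_out == 0:
            raise ValueError("pooled length would reach 0; too many conv+pool blocks")
        self._shape = x.shape
        xt = x[:, : n_out * self.size].reshape(B, n_out, self.size, C)
        self._idx = xt.argmax(axis=2)
        return np.take_along_axis(xt, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, T, C = self._shape
        n_out = T // self.size
        dxt = np.zeros((B, n_out, self.size, C))
        np.put_along_axis(dxt, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, T, C))
        dx[:, : n_out * self.size] = dxt.reshape(B, n_out * self.size, C)
        return dx


class Flatten(_Layer):
    name = "flatten"

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(_Layer):
    name = "dense"

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


# ---------------------------------------------------------------------------
# model


class EncoderModel:
    """The assembled encoder; see the module docstring for the topology."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.visual_layers: list[_Layer] = []
        self.history_layers: list[_Layer] = []
        feat = 0
        if cfg.variant in ("V-FH", "V"):
            self.visual_layers, n = self._build_branch(cfg.L, cfg.n_pixels, cfg, rng)
            feat += n
        if cfg.variant in ("V-FH", "FH"):
            self.history_layers, n = self._build_branch(cfg.L - 1, cfg.n_neurons, cfg, rng)
            feat += n
        self.head: list[_Layer] = [
            Dense(feat, cfg.n_neurons, rng),
            PReLULayer(),
            Dense(cfg.n_neurons, cfg.n_neurons, rng),
            PReLULayer(),
        ]

    @staticmethod
    def _build_branch(
        length: int, channels: int, cfg: EncoderConfig, rng: np.random.Generator
    ) -> tuple[list[_Layer], int]:
        layers: list[_Layer] = []
        t = length
        for _ in range(cfg.conv_blocks):
            layers += [
                Conv1D(channels, channels, cfg.filter_len, rng),
                PReLULayer(),
                MaxPool1D(cfg.pool_size, cfg.pool_stride),
            ]
            t //= cfg.pool_size
            if t == 0:
                raise ValueError(
                    f"pooled length reached 0 after {cfg.conv_blocks} blocks on a "
                    f"{length}-bin input; reduce conv_blocks"
                )
        layers.append(Flatten())
        return layers, t * channels

    # -- topology introspection ---------------------------------------------

    @property
    def layer_names(self) -> list[str]:
        """Counted layers under the documented convention: conv/pool/flatten
        per branch, a concatenation when both branches are present, and the
        two fully connected layers.  Activations are not counted."""
        names = [l.name for l in self.visual_layers if l.counted]
        names += [l.name for l in self.history_layers if l.counted]
        if self.visual_layers and self.history_layers:
            names.append("concat")
        names += [l.name for l in self.head if l.counted]
        return names

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    def pooled_shape(self, branch: str = "visual") -> tuple[int, int]:
        """(temporal length, channels) of a branch's final pooled feature map."""
        cfg = self.cfg
        if branch == "visual":
            if not self.visual_layers:
                raise ValueError("model has no visual branch")
            t, c = cfg.L, cfg.n_pixels
        elif branch == "history":
            if not self.history_layers:
                raise ValueError("model has no history branch")
            t, c = cfg.L - 1, cfg.n_neurons
        else:
            raise ValueError("branch must be 'visual' or 'history'")
        for _ in range(cfg.conv_blocks):
            t //= cfg.pool_size
        return t, c

    # -- forward / backward --------------------------------------------------

    def forward(self, visual: np.ndarray | None, history: np.ndarray | None) -> np.ndarray:
        feats = []
        if self.visual_layers:
            v = visual
            for layer in self.visual_layers:
                v = layer.forward(v)
            feats.append(v)
        if self.history_layers:
            h = history
            for layer in self.history_layers:
                h = layer.forward(h)
            feats.append(h)
        self._splits = [f.shape[1] for f in feats]
        z = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
        for layer in self.head:
            z = layer.forward(z)
        return z

    def backward(self, dpred: np.ndarray) -> None:
        d = dpred
        for layer in reversed(self.head):
            d = layer.backward(d)
        pieces = np.split(d, np.cumsum(self._splits)[:-1], axis=1)
        i = 0
        if self.visual_layers:
            dv = pieces[i]
            i += 1
            for layer in reversed(self.visual_layers):
                dv = layer.backward(dv)
        if self.history_layers:
            dh = pieces[i]
            for layer in reversed(self.history_layers):
                dh = layer.backward(dh)

    def all_layers(self) -> list[_Layer]:
        return self.visual_layers + self.history_layers + self.head

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.all_layers() for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.all_layers() for g in layer.grads()]


def build_model(cfg: EncoderConfig) -> EncoderModel:
    """Build an encoder with Xavier-uniform weights and zero biases."""
    rng = np.random.default_rng(cfg.seed)
    return EncoderModel(cfg, rng)


# ---------------------------------------------------------------------------
# sample assembly


def assemble_samples(
    stimulus: StimulusSequence | np.ndarray,
    rates: RateMatrix,
    cfg: EncoderConfig,
) -> SampleBatch:
    """Slide the L-bin input window over a continuous recording.

    ``stimulus`` may be a :class:`StimulusSequence` (down-sampled here to the
    rate time base, pixel intensity = mean of its 1 ms values per bin) or an
    already-binned (n_bins, P) intensity matrix.  One sample is produced per
    target bin k >= L; for a recording of ``n_bins`` bins that is
    ``n_bins - L + 1`` samples.
    """
    L = cfg.L
    stim_bins = (
        bin_stimulus(stimulus.frames, cfg.w_ms)
        if isinstance(stimulus, StimulusSequence)
        else np.asarray(stimulus, dtype=float)
    )
    R = rates.rates
    n_bins = min(len(stim_bins), len(R))
    if n_bins < L:
        raise ValueError(f"recording has {n_bins} bins, fewer than the window L={L}")
    sv = sliding_window_view(stim_bins[:n_bins], L, axis=0)  # (n-L+1, P, L)
    visual = np.ascontiguousarray(sv.transpose(0, 2, 1))
    sh = sliding_window_view(R[: n_bins - 1], L - 1, axis=0)  # (n-L+1, N, L-1)
    history = np.ascontiguousarray(sh.transpose(0, 2, 1))
    target = R[L - 1 : n_bins]
    bin_index = np.arange(L - 1, n_bins)
    return SampleBatch(visual=visual, history=history, target=target, bin_index=bin_index)


# ---------------------------------------------------------------------------
# training


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1: float, beta2: float, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _rmse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - target) ** 2)))


def train(
    model: EncoderModel,
    samples: SampleBatch,
    epochs: int | None = None,
    verbose: bool = False,
) -> list[float]:
    """Fit the model by minimizing RMSE with Adam; returns per-epoch loss.

    Deterministic for a fixed config seed (the shuffling RNG is derived from
    it) and single-threaded execution.
    """
    cfg = model.cfg
    epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.parameters(), cfg.lr, cfg.beta1, cfg.beta2)
    n = len(samples)
    losses: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xv, xh, y = samples.visual[idx], samples.history[idx], samples.target[idx]
            pred = model.forward(xv, xh)
            err = pred - y
            rmse = np.sqrt(np.mean(err**2))
            if not np.isfinite(rmse):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch starting {start}; "
                    f"|pred| max {np.abs(pred).max():.3g}"
                )
            epoch_losses.append(float(rmse))
            if rmse > 1e-12:
                model.backward(err / (err.size * rmse))
                opt.step(model.gradients())
        losses.append(float(np.mean(epoch_losses)))
        if verbose and (epoch % 10 == 0 or epoch == epochs - 1):
            print(f"epoch {epoch:4d}  rmse {losses[-1]:.4f}")
    return losses


def predict(model: EncoderModel, samples: SampleBatch, clamp_negative: bool | None = None) -> np.ndarray:
    """Forward pass on assembled samples; returns (B, N) predicted rates.

    The output PReLU admits negative rates; set ``clamp_negative`` (or the
    config flag) to clip them at zero.
    """
    pred = model.forward(samples.visual, samples.history)
    if not np.all(np.isfinite(pred)):
        raise RuntimeError("non-finite predictions")
    clamp = model.cfg.clamp_negative if clamp_negative is None else clamp_negative
    return np.clip(pred, 0.0, None) if clamp else pred
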