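"""Poisson GLM encoder baseline.

Each neuron's spike count per w-ms bin is modeled with a log-linear
conditional intensity

    lambda_i(t) = exp(beta_i + V_i(t) + H_i(t))

where ``V_i`` sums lagged pixel intensities (lags m = 0..L bins) weighted by
``beta_v`` and ``H_i`` sums the lagged spike counts of all neurons
(lags m = 1..L) weighted by ``beta_h``.  Note the asymmetric lag ranges: the
visual part includes the current bin (m = 0), the history part does not.

Fitting maximizes the per-neuron Poisson log-likelihood (a concave problem)
with L-BFGS on the analytic gradient, optionally with a small L2 ridge on
the slope coefficients for collinear stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import minimize

from lgnenc.preprocess import RateMatrix
from lgnenc.stimulus import StimulusSequence, bin_stimulus

__all__ = ["GlmParams", "build_design", "fit", "predict_rate", "fit_glm", "simulate_counts"]

ETA_CLIP = 30.0  # overflow guard on the log-intensity


@dataclass
class GlmParams:
    """Fitted coefficients for a population of N neurons.

    ``beta0``: (N,) intercepts; ``beta_v``: (N, P, L+1) visual weights
    indexed [neuron, pixel, lag m=0..L]; ``beta_h``: (N, N, L) history
    weights indexed [neuron, source neuron, lag m=1..L].
    """

    beta0: np.ndarray
    beta_v: np.ndarray
    beta_h: np.ndarray
    w_ms: int
    converged: np.ndarray | None = None
    loglik: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return len(self.beta0)

    def coef_vector(self, i: int) -> np.ndarray:
        """Slope coefficients of neuron i in design-column order."""
        return np.concatenate([self.beta_v[i].T.ravel(), self.beta_h[i].T.ravel()])


def _design_columns(P: int, N: int, L: int) -> int:
    return P * (L + 1) + N * L


def build_design(
    stim_bins: np.ndarray, counts: np.ndarray, L: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lagged design matrix and spike-count targets on the bin grid.

    ``stim_bins`` is (n_bins, P) pixel intensity per bin, ``counts`` is
    (n_bins, N) spike counts.  For each usable bin t (t >= L; earlier rows
    lack full lag coverage and are dropped) the covariate row is

        [I_p(t - m) for m = 0..L, each m listing all P pixels] ++
        [S_n(t - m) for m = 1..L, each m listing all N neurons]

    Returns ``(X, y, row_bins)`` with X of shape
    (n_bins - L, P*(L+1) + N*L).
    """
    stim_bins = np.asarray(stim_bins, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(stim_bins) != len(counts):
        raise ValueError(
            f"mismatched time bases: stimulus has {len(stim_bins)} bins, counts {len(counts)}"
        )
    n_bins, P = stim_bins.shape
    N = counts.shape[1]
    if n_bins <= L:
        raise ValueError(f"need more than L={L} bins, got {n_bins}")
    rows = n_bins - L
    # visual block: lag m=0..L -> columns [m][p]
    vis = np.empty((rows, (L + 1), P))
    hist = np.empty((rows, L, N))
    t = np.arange(L, n_bins)
    for m in range(L + 1):
        vis[:, m, :] = stim_bins[t - m]
    for m in range(1, L + 1):
        hist[:, m - 1, :] = counts[t - m]
    X = np.concatenate([vis.reshape(rows, -1), hist.reshape(rows, -1)], axis=1)
    return X, counts[t], t


def _nll_grad(
    beta: np.ndarray, X: np.ndarray, y: np.ndarray, ridge: float
) -> tuple[float, np.ndarray]:
    """Poisson negative log-likelihood (up to the log y! constant) and gradient.

    ``beta[0]`` is the intercept (not penalized)."""
    eta = np.clip(beta[0] + X @ beta[1:], -ETA_CLIP, ETA_CLIP)
    mu = np.exp(eta)
    nll = float(np.sum(mu - y * eta)) + 0.5 * ridge * float(beta[1:] @ beta[1:])
    resid = mu - y
    grad = np.empty_like(beta)
    grad[0] = resid.sum()
    grad[1:] = X.T @ resid + ridge * beta[1:]
    return nll, grad


def fit(
    X: np.ndarray,
    counts: np.ndarray,
    P: int,
    L: int,
    w_ms: int = 50,
    ridge: float = 1e-4,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> GlmParams:
    """Per-neuron Poisson maximum-likelihood fit.

    ``counts`` are non-negative integer spike counts per bin, one column per
    neuron; non-convergence is flagged in ``GlmParams.converged`` rather than
    raised.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0) or not np.allclose(counts, np.rint(counts)):
        raise ValueError("counts must be non-negative integers")
    counts = counts.astype(float)
    N = counts.shape[1]
    D = X.shape[1]
    if D != _design_columns(P, N, L):
        raise ValueError(
            f"design has {D} columns, expected P*(L+1)+N*L = {_design_columns(P, N, L)}"
        )
    beta0 = np.empty(N)
    beta_v = np.empty((N, P, L + 1))
    beta_h = np.empty((N, N, L))
    converged = np.zeros(N, dtype=bool)
    loglik = np.empty(N)
    for i in range(N):
        y = counts[:, i]
        x0 = np.zeros(D + 1)
        x0[0] = np.log(max(y.mean(), 1e-8))
        res = minimize(
            _nll_grad,
            x0,
            args=(X, y, ridge),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
        )
        beta = res.x
        beta0[i] = beta[0]
        vis = beta[1 : 1 + P * (L + 1)].reshape(L + 1, P)
        hist = beta[1 + P * (L + 1) :].reshape(L, N)
        beta_v[i] = vis.T
        beta_h[i] = hist.T
        converged[i] = bool(res.success)
        loglik[i] = -float(res.fun)
    return GlmParams(
        beta0=beta0, beta_v=beta_v, beta_h=beta_h, w_ms=w_ms, converged=converged, loglik=loglik
    )


def predict_rate(params: GlmParams, X: np.ndarray) -> np.ndarray:
    """Predicted firing rates in spikes/s, shape (rows, N).

    The exponential link gives expected counts per bin; dividing by the bin
    width converts to the RateMatrix scale.  The log-intensity is clipped at
    +/- ETA_CLIP to guard against overflow.
    """
    etas = np.stack(
        [
            np.clip(params.beta0[i] + X @ params.coef_vector(i), -ETA_CLIP, ETA_CLIP)
            for i in range(params.n_neurons)
        ],
        axis=1,
    )
    return np.exp(etas) / (params.w_ms / 1000.0)


def fit_glm(
    stimulus: StimulusSequence | np.ndarray,
    rates: RateMatrix,
    L: int,
    ridge: float = 1e-4,
) -> tuple[GlmParams, np.ndarray, np.ndarray]:
    """Convenience wrapper: build the design from a stimulus and binned rates,
    fit, and return ``(params, X, row_bins)``."""
    stim_bins = (
        bin_stimulus(stimulus.frames, rates.w_ms)
        if isinstance(stimulus, StimulusSequence)
        else np.asarray(stimulus, dtype=float)
    )
    n_bins = min(len(stim_bins), rates.n_bins)
    counts = rates.counts()[:n_bins]
    X, y, row_bins = build_design(stim_bins[:n_bins], counts, L)
    params = fit(X, y, P=stim_bins.shape[1], L=L, w_ms=rates.w_ms, ridge=ridge)
    return params, X, row_bins


def simulate_counts(
    params: GlmParams,
    stim_bins: np.ndarray,
    n_bins: int,
    seed: int | None = 0,
) -> np.ndarray:
    """Generate spike counts from known GLM parameters (for recovery tests).

    Steps through time so that history covariates use the realized counts of
    previous bins.  ``stim_bins`` must have at least ``n_bins`` rows.
    """
    rng = np.random.default_rng(seed)
    N = params.n_neurons
    P = params.beta_v.shape[1]
    L = params.beta_h.shape[2]
    counts = np.zeros((n_bins, N))
    for t in range(L, n_bins):
        vis_lags = stim_bins[t - np.arange(L + 1)]  # (L+1, P)
        hist_lags = counts[t - np.arange(1, L + 1)]  # (L, N)
        for i in range(N):
            eta = params.beta0[i]
            eta += float(np.sum(params.beta_v[i] * vis_lags.T))
            eta += float(np.sum(params.beta_h[i] * hist_lags.T))
            counts[t, i] = rng.poisson(np.exp(np.clip(eta, -ETA_CLIP, ETA_CLIP)))
    return counts
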