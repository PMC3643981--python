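"""Noise-covariance estimation and two-stage separable whitening.

The background noise is modelled as zero-mean Gaussian with separable
space-time covariance.  The full spatiotemporal covariance is far too
large to estimate directly, so whitening proceeds in two stages: (1)
estimate a banded (Toeplitz) temporal covariance per electrode over a
short window (default 16 bins, 0.8 ms at 20 kHz) and filter each
electrode with the central column of its inverse matrix square root;
(2) estimate the instantaneous cross-electrode covariance of the
temporally whitened residuals and multiply each time bin by its inverse
square root.  After both stages the residual noise is approximately unit
variance and uncorrelated in time and space, so the likelihood becomes an
unweighted sum of squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .events import SpikeEventSet
from .waveforms import WaveformSet, estimate_waveforms, predict, prune_waveforms

log = logging.getLogger(__name__)


@dataclass
class NoiseModel:
    """Separable noise description plus its whitening transforms.

    ``temporal_cov``: (E, W, W) per-electrode Toeplitz covariance.
    ``temporal_filter``: (E, W) central column of each inverse square root.
    ``spatial_cov`` / ``spatial_whitener``: (E, E) instantaneous
    cross-electrode covariance and its inverse square root.
    """

    temporal_cov: np.ndarray
    temporal_filter: np.ndarray
    spatial_cov: np.ndarray
    spatial_whitener: np.ndarray

    def save(self, path) -> None:
        np.savez(path, temporal_cov=self.temporal_cov,
                 temporal_filter=self.temporal_filter,
                 spatial_cov=self.spatial_cov,
                 spatial_whitener=self.spatial_whitener)

    @classmethod
    def load(cls, path) -> "NoiseModel":
        z = np.load(path)
        return cls(z["temporal_cov"], z["temporal_filter"],
                   z["spatial_cov"], z["spatial_whitener"])


def inv_sqrt_psd(M: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition.

    Eigenvalues are floored at ``floor`` times the largest to survive
    near-singular estimates.
    """
    evals, evecs = scipy.linalg.eigh((M + M.T) / 2)
    evals = np.maximum(evals, floor * evals.max())
    return (evecs / np.sqrt(evals)) @ evecs.T


def compute_residual(data: np.ndarray, ws: WaveformSet,
                     events: SpikeEventSet) -> np.ndarray:
    """Recording minus the model prediction, V - (W * X)."""
    data = np.atleast_2d(np.asarray(data, float))
    return data - predict(ws, events, data.shape[1])


def _autocov(x: np.ndarray, lags: int) -> np.ndarray:
    """Biased autocovariance of one trace at lags 0..lags-1."""
    x = x - x.mean()
    n = x.size
    return np.array([x[: n - k] @ x[k:] / n for k in range(lags)])


def estimate_temporal_cov(residual: np.ndarray, window_bins: int = 16):
    """Per-electrode Toeplitz temporal covariance and whitening filter.

    The banded autocovariance over ``window_bins`` lags is symmetrized
    into a Toeplitz matrix; the whitening filter is the central column of
    its inverse matrix square root.  Non-positive-definite estimates are
    shrunk toward their diagonal until positive definite (logged).
    Returns ``(temporal_cov (E,W,W), temporal_filter (E,W))``.
    """
    residual = np.atleast_2d(np.asarray(residual, float))
    n_e = residual.shape[0]
    if residual.shape[1] < 4 * window_bins:
        raise ValueError("residual too short for the covariance window")
    covs = np.empty((n_e, window_bins, window_bins))
    filters = np.empty((n_e, window_bins))
    for e in range(n_e):
        ac = _autocov(residual[e], window_bins)
        if ac[0] <= 0:
            # constant (e.g. all-zero) residual: fall back to unit covariance
            log.warning("electrode %d: degenerate residual; identity covariance", e)
            covs[e] = np.eye(window_bins)
            filters[e] = np.eye(window_bins)[:, window_bins // 2]
            continue
        C = scipy.linalg.toeplitz(ac)
        lam = 0.0
        while scipy.linalg.eigvalsh(C).min() <= 0 and lam < 1.0:
            lam = min(max(2 * lam, 1e-4), 1.0)
            C = (1 - lam) * scipy.linalg.toeplitz(ac) + lam * ac[0] * np.eye(window_bins)
            log.warning("electrode %d: temporal covariance shrunk (lambda=%g)", e, lam)
        covs[e] = C
        filters[e] = inv_sqrt_psd(C)[:, window_bins // 2]
    return covs, filters


def temporal_whiten(data: np.ndarray, temporal_filter: np.ndarray) -> np.ndarray:
    """FIR-filter each electrode with its whitening filter (zero-phase
    'same' convolution; edge samples see a truncated filter)."""
    data = np.atleast_2d(np.asarray(data, float))
    out = np.empty_like(data)
    for e in range(data.shape[0]):
        out[e] = np.convolve(data[e], temporal_filter[e][::-1], mode="same")
    return out


def estimate_spatial_cov(data: np.ndarray, subsample: int = 16) -> np.ndarray:
    """Instantaneous electrodes x electrodes covariance.

    Time bins are subsampled every ``subsample`` samples to reduce serial
    dependence left over from temporal whitening.
    """
    data = np.atleast_2d(np.asarray(data, float))
    sub = data[:, ::max(1, subsample)]
    sub = sub - sub.mean(axis=1, keepdims=True)
    return sub @ sub.T / sub.shape[1]


def spatial_whiten(data: np.ndarray, spatial_cov: np.ndarray) -> np.ndarray:
    """Multiply the electrode vector in every time bin by the inverse
    square root of the spatial covariance."""
    data = np.atleast_2d(np.asarray(data, float))
    spatial_cov = np.asarray(spatial_cov, float)
    if spatial_cov.shape != (data.shape[0], data.shape[0]):
        raise ValueError("spatial covariance dimension mismatch")
    return inv_sqrt_psd(spatial_cov) @ data


def whiten_pipeline(data: np.ndarray, events: SpikeEventSet, taps: int,
                    window_bins: int = 16, prune_a: float = 1.0,
                    ws: WaveformSet | None = None):
    """Full two-stage whitening: estimate, whiten, and re-fit waveforms.

    Steps: fit waveforms (if not given) -> residual -> temporal covariance
    and filtering -> spatial covariance and whitening -> re-estimate and
    prune waveforms in the whitened space (where the per-electrode noise
    scale is 1).

    Returns ``(whitened_data, whitened_waveforms, noise_model)``.
    """
    data = np.atleast_2d(np.asarray(data, float))
    if ws is None:
        ws = estimate_waveforms(data, events, taps)
    residual = compute_residual(data, ws, events)
    t_cov, t_filt = estimate_temporal_cov(residual, window_bins)
    data_t = temporal_whiten(data, t_filt)
    resid_t = temporal_whiten(residual, t_filt)
    s_cov = estimate_spatial_cov(resid_t, subsample=window_bins)
    whitener = inv_sqrt_psd(s_cov)
    data_w = whitener @ data_t
    ws_w = estimate_waveforms(data_w, events, taps)
    ws_w = prune_waveforms(ws_w, np.ones(data.shape[0]), a=prune_a)
    model = NoiseModel(t_cov, t_filt, s_cov, whitener)
    return data_w, ws_w, model
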