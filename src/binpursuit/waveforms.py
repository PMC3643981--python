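"""Spatiotemporal waveform (template) estimation and manipulation.

Each neuron has a characteristic electrodes x taps voltage signature.
Given spike trains, the full set of templates is recovered jointly by
linear least squares against the recording -- the design matrix is the
bank of shifted spike indicator trains, so temporally overlapping spikes
of different neurons are resolved by the regression rather than averaged
into each other.  Templates can then be pruned to their spatial support
(subset selection on the per-electrode norm against the noise scale) and
differentiated numerically with respect to spike time, amplitude and
width for the sub-bin variability correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.interpolate import CubicSpline

from .events import SpikeEventSet


class RankDeficiencyError(np.linalg.LinAlgError):
    """Raised when the template regression is singular (e.g. two neurons
    with identical spike trains)."""


@dataclass
class WaveformSet:
    """Per-neuron spatiotemporal templates and optional derivative tensors.

    ``templates`` has shape (n_neurons, n_electrodes, n_taps).
    ``alignment_tap`` holds, per neuron, the tap index of the negative
    extremum on the largest-norm electrode (the canonical peak).
    ``d_time`` is the derivative of the template under a forward time
    shift w(t + tau); ``d_amp`` equals the template; ``d_width`` is the
    derivative under time dilation about the alignment peak.
    """

    templates: np.ndarray
    alignment_tap: np.ndarray = None
    support_mask: np.ndarray = None
    d_time: np.ndarray = None
    d_amp: np.ndarray = None
    d_width: np.ndarray = None

    def __post_init__(self):
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.ndim != 3:
            raise ValueError("templates must be (neurons, electrodes, taps)")
        J = self.templates.shape[0]
        if self.alignment_tap is None:
            self.alignment_tap = self._find_alignment()
        self.alignment_tap = np.broadcast_to(
            np.asarray(self.alignment_tap, dtype=int), (J,)
        ).copy()
        if self.support_mask is None:
            self.support_mask = np.any(self.templates != 0, axis=2)
        self.support_mask = np.asarray(self.support_mask, dtype=bool)
        if np.any((self.alignment_tap < 0) | (self.alignment_tap >= self.n_taps)):
            raise ValueError("alignment_tap outside [0, n_taps)")

    def _find_alignment(self) -> np.ndarray:
        norms = np.linalg.norm(self.templates, axis=2)  # (J, E)
        taps = []
        for j in range(self.templates.shape[0]):
            e = int(np.argmax(norms[j]))
            taps.append(int(np.argmin(self.templates[j, e])))
        return np.asarray(taps)

    @property
    def n_neurons(self) -> int:
        return self.templates.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.templates.shape[1]

    @property
    def n_taps(self) -> int:
        return self.templates.shape[2]

    def electrode_norms(self) -> np.ndarray:
        """Vector norm of each neuron's waveform on each electrode (J, E)."""
        return np.linalg.norm(self.templates, axis=2)

    def norms_sq(self) -> np.ndarray:
        """Total squared norm per neuron, w.w (length J)."""
        return np.sum(self.templates ** 2, axis=(1, 2))

    def has_derivatives(self) -> bool:
        return self.d_time is not None

    def copy(self) -> "WaveformSet":
        return WaveformSet(
            self.templates.copy(), self.alignment_tap.copy(),
            self.support_mask.copy(),
            None if self.d_time is None else self.d_time.copy(),
            None if self.d_amp is None else self.d_amp.copy(),
            None if self.d_width is None else self.d_width.copy(),
        )


def _spike_design(events: SpikeEventSet, n_samples: int, taps: int):
    """Sparse (n_samples x n_neurons*taps) bank of shifted spike trains."""
    if np.any(events.bin + taps > n_samples):
        raise ValueError("spike too close to recording end for the template span")
    tap_idx = np.arange(taps)
    rows = (events.bin[:, None] + tap_idx[None, :]).ravel()
    cols = (events.neuron_id[:, None] * taps + tap_idx[None, :]).ravel()
    vals = np.ones(rows.size)
    return scipy.sparse.coo_matrix(
        (vals, (rows, cols)), shape=(n_samples, events.n_neurons * taps)
    ).tocsr()


def estimate_waveforms(
    data: np.ndarray,
    events: SpikeEventSet,
    taps: int,
    jitter: float = 1e-10,
    support_mask: np.ndarray | None = None,
) -> WaveformSet:
    """Jointly estimate all templates by least squares, V ~ X_toeplitz W.

    Solves the normal equations per electrode with a tiny diagonal jitter
    (``jitter`` x mean diagonal) for numerical robustness.  Overlapping
    spikes of different neurons are resolved exactly by the joint fit.
    A ``support_mask`` (neurons x electrodes) constrains the fit: a
    neuron's waveform is held at zero on masked-out electrodes (its
    design columns are dropped there), giving the exact constrained
    least-squares solution.

    Raises
    ------
    RankDeficiencyError
        If two neurons have identical spike trains (the design is then
        exactly singular), naming the offending neurons.
    ValueError
        If any neuron has no spikes.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if taps < 1:
        raise ValueError("taps must be >= 1")
    counts = events.counts()
    if np.any(counts == 0):
        raise ValueError(f"neurons without spikes: {np.where(counts == 0)[0].tolist()}")
    trains = [tuple(events.train(j)) for j in range(events.n_neurons)]
    seen = {}
    for j, tr in enumerate(trains):
        if tr in seen:
            raise RankDeficiencyError(
                f"neurons {seen[tr]} and {j} have identical spike trains; "
                "the template regression is singular"
            )
        seen[tr] = j
    J, E = events.n_neurons, data.shape[0]
    X = _spike_design(events, data.shape[1], taps)
    A = (X.T @ X).toarray()
    A[np.diag_indices_from(A)] += jitter * max(A.diagonal().mean(), 1e-300)
    B = X.T @ data.T  # (J*taps, E)
    if support_mask is None:
        W = scipy.linalg.solve(A, B, assume_a="pos")
        templates = W.reshape(J, taps, E).transpose(0, 2, 1)
    else:
        support_mask = np.asarray(support_mask, bool)
        templates = np.zeros((J, E, taps))
        for e in range(E):
            live = np.flatnonzero(support_mask[:, e])
            if live.size == 0:
                continue
            cols = (live[:, None] * taps + np.arange(taps)[None, :]).ravel()
            W_e = scipy.linalg.solve(A[np.ix_(cols, cols)], B[cols, e],
                                     assume_a="pos")
            templates[live, e, :] = W_e.reshape(live.size, taps)
    ws = WaveformSet(templates)
    if support_mask is not None:
        ws.support_mask = support_mask.copy()
    return ws


def predict(ws: WaveformSet, events: SpikeEventSet, n_samples: int) -> np.ndarray:
    """Superpose templates at their event bins: (W * X)(t).

    Events carrying nonzero Taylor coefficients contribute the corrected
    waveform w - tau*d_time + a*d_amp + sigma*d_width (a spike occurring
    tau bins *after* its lattice bin appears shifted forward in time,
    i.e. along -d_time).
    """
    out = np.zeros((ws.n_electrodes, n_samples))
    need_derivs = (
        np.any(events.subbin_offset != 0)
        or np.any(events.amp_coef != 0)
        or np.any(events.width_coef != 0)
    )
    if need_derivs and not ws.has_derivatives():
        ws = compute_derivatives(ws)
    for i in range(len(events)):
        j, b = events.neuron_id[i], events.bin[i]
        w = ws.templates[j]
        if need_derivs:
            w = (
                w
                - events.subbin_offset[i] * ws.d_time[j]
                + events.amp_coef[i] * ws.d_amp[j]
                + events.width_coef[i] * ws.d_width[j]
            )
        out[:, b:b + ws.n_taps] += w
    return out


def prune_waveforms(
    ws: WaveformSet, per_electrode_noise: np.ndarray, a: float = 1.0
) -> WaveformSet:
    """Subset-selection pruning: zero a neuron's waveform on electrodes
    where its vector norm falls below ``a`` times that electrode's noise
    scale.  Idempotent; ``a = 0`` is a no-op, ``a = inf`` empties the set.
    """
    if a < 0:
        raise ValueError("pruning constant a must be >= 0")
    noise = np.broadcast_to(np.asarray(per_electrode_noise, float),
                            (ws.n_electrodes,))
    out = ws.copy()
    keep = out.electrode_norms() >= a * noise[None, :]
    out.support_mask = out.support_mask & keep
    out.templates[~out.support_mask] = 0.0
    for t in (out.d_time, out.d_amp, out.d_width):
        if t is not None:
            t[~out.support_mask] = 0.0
    return out


def _shift(template: np.ndarray, delta: float) -> np.ndarray:
    """Evaluate w(t + delta) per electrode via cubic interpolation."""
    taps = template.shape[-1]
    t = np.arange(taps, dtype=float)
    out = np.empty_like(template, dtype=float)
    for e in range(template.shape[0]):
        out[e] = CubicSpline(t, template[e], bc_type="natural")(t + delta)
    return out


def _dilate(template: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Evaluate the template time-dilated by (1 + sigma) about ``center``,
    so the peak sample is unchanged while the width grows with sigma."""
    taps = template.shape[-1]
    t = np.arange(taps, dtype=float)
    warped = center + (t - center) / (1.0 + sigma)
    out = np.empty_like(template, dtype=float)
    for e in range(template.shape[0]):
        out[e] = CubicSpline(t, template[e], bc_type="natural")(warped)
    return out


def compute_derivatives(ws: WaveformSet, delta: float = 0.1) -> WaveformSet:
    """Attach numerical derivative tensors d_time, d_amp, d_width.

    Central finite differences of the cubic-interpolated template under a
    ``delta``-bin time shift and a ``delta`` time dilation about the
    alignment peak.  d_amp is the template itself.
    """
    if not (0 < delta <= 0.5):
        raise ValueError("delta must be in (0, 0.5] bins")
    if ws.n_taps < 8:
        raise ValueError("need at least 8 taps for smooth interpolation")
    out = ws.copy()
    J = ws.n_neurons
    d_time = np.empty_like(ws.templates)
    d_width = np.empty_like(ws.templates)
    for j in range(J):
        w = ws.templates[j]
        d_time[j] = (_shift(w, delta) - _shift(w, -delta)) / (2 * delta)
        c = float(ws.alignment_tap[j])
        d_width[j] = (_dilate(w, c, delta) - _dilate(w, c, -delta)) / (2 * delta)
    out.d_time = d_time
    out.d_amp = ws.templates.copy()
    out.d_width = d_width
    for t in (out.d_time, out.d_amp, out.d_width):
        t[~out.support_mask] = 0.0
    return out


def noise_mad_scale(data: np.ndarray) -> np.ndarray:
    """Robust per-electrode noise scale, median absolute deviation / 0.6745."""
    data = np.atleast_2d(data)
    med = np.median(data, axis=1, keepdims=True)
    return np.median(np.abs(data - med), axis=1) / 0.6745
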