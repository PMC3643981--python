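"""Greedy binary pursuit: MAP spike-train estimation on a binary lattice.

After whitening, the negative log-posterior over binary spike trains X is

    L(X) = 1/2 || V - W * X ||^2  +  sum_j theta_j sum_t X_j(t),

where ``*`` is convolution of templates with spike trains and
``theta_j = log((1 - p_j)/p_j)`` is the per-spike penalty implied by the
Bernoulli prior probability ``p_j`` of a spike per bin.  The change in L
for inserting a spike of neuron j at bin i is

    dL = w_j . r[i : i+N_w]  -  1/2 ||w_j||^2  -  theta_j,

using only samples in the template's spatiotemporal footprint; removing a
spike is the negation.  Binary pursuit starts from X = 0, repeatedly
flips the bin with the globally largest gain, and updates the residual
and the gain surface only where footprints overlap, until no single flip
improves the objective -- a local MAP optimum.

Each accepted insertion may be followed by the ridge-regularized Taylor
variability correction: the leftover residual in the footprint is
regressed onto the waveform's time/amplitude/width derivative columns,
recovering spike times below the sample lattice spacing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import next_fast_len

from .events import SpikeEventSet
from .waveforms import WaveformSet, compute_derivatives

log = logging.getLogger(__name__)

_COMPONENTS = ("time", "amp", "width")


def compute_prior_weights(p, multiplier: float = 1.0) -> np.ndarray:
    """Per-spike penalty theta_j = multiplier * log((1 - p_j) / p_j).

    Requires 0 < p < 0.5 (a spike must be a priori less likely than not);
    at 20 kHz a 40 sp/s neuron has p = 1/500 and theta ~ log(499).
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p <= 0) | (p > 0.5)):
        raise ValueError("prior spike probability must lie in (0, 0.5]")
    return multiplier * np.log((1 - p) / p)


def delta_loglik(residual: np.ndarray, template: np.ndarray,
                 theta: float, bin: int) -> float:
    """Gain in log-posterior for inserting one spike at ``bin``.

    ``residual`` must not already contain the candidate spike.  The gain
    uses only the samples inside the template's footprint (unit noise
    variance assumed, i.e. whitened data).
    """
    residual = np.atleast_2d(residual)
    template = np.atleast_2d(template)
    n_w = template.shape[1]
    if bin < 0 or bin + n_w > residual.shape[1]:
        raise ValueError("template footprint extends past the segment")
    c = float(np.sum(template * residual[:, bin:bin + n_w]))
    return c - 0.5 * float(np.sum(template ** 2)) - float(theta)


@dataclass
class PursuitConfig:
    """Tunables of the greedy solver.

    ``gain_tol_factor`` scales each neuron's squared template norm to give
    the termination tolerance.  ``correction`` lists the enabled Taylor
    derivative components (subset of 'time', 'amp', 'width'); empty
    disables the variability correction.  ``gamma_factor`` sets the ridge
    penalty as a fraction of trace(D'D)/n_components; ``coef_clamp``
    bounds every recovered coefficient.
    """

    block_s: float = 1.0
    gain_tol_factor: float = 1e-9
    correction: tuple = ("time",)
    gamma_factor: float = 0.1
    coef_clamp: float = 0.5
    max_flips_per_block: int | None = None

    def __post_init__(self):
        bad = [c for c in self.correction if c not in _COMPONENTS]
        if bad:
            raise ValueError(f"unknown correction components {bad}")
        if self.gamma_factor < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class FlipRecord:
    neuron: int
    bin: int
    insert: bool
    gain: float            # canonical (Eq.-style) gain for this flip
    total_gain: float      # gain including any variability correction
    coefs: np.ndarray      # correction coefficients actually applied


class PursuitEngine:
    """Precomputed state for running binary pursuit on many data blocks.

    Holds the whitened templates, per-spike penalties, pairwise template
    overlap kernels (for incremental gain updates) and, when the
    variability correction is enabled, the per-neuron ridge projection
    matrices (D'D + gamma I)^-1 D'.
    """

    def __init__(self, ws: WaveformSet, theta, config: PursuitConfig | None = None):
        self.config = config or PursuitConfig()
        if self.config.correction and not ws.has_derivatives():
            ws = compute_derivatives(ws)
        self.ws = ws
        self.w = np.ascontiguousarray(ws.templates)
        self.J, self.E, self.n_w = self.w.shape
        self.theta = np.broadcast_to(np.atleast_1d(np.asarray(theta, float)),
                                     (self.J,)).copy()
        self.b = ws.norms_sq()
        if not np.any(self.b > 0):
            raise ValueError("all templates are empty")
        self.tol = self.config.gain_tol_factor * self.b
        self.active = self.b > 0
        self._fft_cache: dict[int, np.ndarray] = {}
        self.K_ww = self._overlap_kernel(self.w)  # (J, J, 2n_w-1)
        self.n_comp = len(self.config.correction)
        if self.n_comp:
            cols = {"time": -ws.d_time, "amp": ws.d_amp, "width": ws.d_width}
            # (J, n_comp, E, n_w); 'time' column is the derivative along a
            # *later* spike time (-d/dt), so its coefficient is tau itself
            self.D = np.stack([cols[c] for c in self.config.correction], axis=1)
            self.P = np.empty((self.J, self.n_comp, self.E * self.n_w))
            self.DtD = np.empty((self.J, self.n_comp, self.n_comp))
            for j in range(self.J):
                Dj = self.D[j].reshape(self.n_comp, -1).T  # (E*n_w, n_comp)
                DtD = Dj.T @ Dj
                gamma = self.config.gamma_factor * np.trace(DtD) / self.n_comp
                if gamma == 0 and np.linalg.cond(DtD) > 1e12:
                    raise np.linalg.LinAlgError(
                        "singular D'D in variability correction; use gamma > 0")
                self.DtD[j] = DtD
                self.P[j] = np.linalg.solve(DtD + gamma * np.eye(self.n_comp), Dj.T)
            self.K_wd = np.stack([
                self._overlap_kernel(self.D[:, c]) for c in range(self.n_comp)
            ], axis=2)  # (J, J, n_comp, 2n_w-1)

    # -- kernels ---------------------------------------------------------
    def _overlap_kernel(self, other: np.ndarray) -> np.ndarray:
        """K[j1, j2, d + n_w - 1] = sum_e sum_k w[j1,e,k] * other[j2,e,k+d]."""
        n_w = self.n_w
        pad = np.zeros((other.shape[0], self.E, 3 * n_w - 2))
        pad[:, :, n_w - 1:2 * n_w - 1] = other
        win = sliding_window_view(pad, n_w, axis=-1)  # (J2, E, 2n_w-1, n_w)
        return np.einsum("aek,betk->abt", self.w, win, optimize=True)

    def _template_fft(self, n_fft: int) -> np.ndarray:
        Wf = self._fft_cache.get(n_fft)
        if Wf is None:
            Wf = np.fft.rfft(self.w[:, :, ::-1], n=n_fft, axis=2)
            self._fft_cache[n_fft] = Wf
        return Wf

    def correlate(self, data: np.ndarray) -> np.ndarray:
        """C[j, i] = template-j dot data over footprint starting at i."""
        L = data.shape[1]
        n_pos = L - self.n_w + 1
        n_fft = next_fast_len(L + self.n_w)
        Wf = self._template_fft(n_fft)
        C = np.zeros((self.J, n_pos))
        for e in range(self.E):
            Rf = np.fft.rfft(data[e], n=n_fft)
            conv = np.fft.irfft(Rf[None, :] * Wf[:, e, :], n=n_fft)
            C += conv[:, self.n_w - 1:self.n_w - 1 + n_pos]
        return C

    # -- single-segment solve -------------------------------------------
    def solve(self, data: np.ndarray, track_history: bool = False):
        """Run greedy binary pursuit to a local optimum on one segment.

        Returns ``(events, info)`` where events are relative to the
        segment start and ``info`` carries the objective before/after and
        (optionally) the full flip history.
        """
        data = np.atleast_2d(np.asarray(data, float))
        if not np.all(np.isfinite(data)):
            raise ValueError("non-finite voltage samples")
        cfg = self.config
        n_w, J = self.n_w, self.J
        r = data.astype(float).copy()
        n_pos = r.shape[1] - n_w + 1
        if n_pos <= 0:
            raise ValueError("segment shorter than one template")
        C = self.correlate(r)
        x = np.zeros((J, n_pos), dtype=bool)
        half_b = 0.5 * self.b[:, None]
        th = self.theta[:, None]
        G = C - half_b - th
        G[~self.active] = -np.inf
        # per-neuron running maximum of the gain surface: a flip touches
        # only a 2*n_w - 1 window, so the global argmax is maintained
        # incrementally instead of rescanned
        rowmax = G.max(axis=1)
        rowarg = G.argmax(axis=1)

        def refresh_rows(lo, hi):
            Gw = np.where(x[:, lo:hi], -C[:, lo:hi] - half_b + th,
                          C[:, lo:hi] - half_b - th)
            Gw[~self.active] = -np.inf
            G[:, lo:hi] = Gw
            wmax = Gw.max(axis=1)
            warg = lo + Gw.argmax(axis=1)
            better = wmax >= rowmax
            rowmax[better] = wmax[better]
            rowarg[better] = warg[better]
            stale = ~better & (rowarg >= lo) & (rowarg < hi)
            for jj in np.flatnonzero(stale):
                rowmax[jj] = G[jj].max()
                rowarg[jj] = G[jj].argmax()

        coefs: dict[tuple[int, int], np.ndarray] = {}
        obj0 = 0.5 * float(np.sum(r ** 2))
        obj = obj0
        history: list[FlipRecord] = []
        max_flips = cfg.max_flips_per_block or max(1000, 2 * n_pos)
        flips = 0
        while True:
            eligible = np.where(rowmax > self.tol, rowmax, -np.inf)
            j = int(np.argmax(eligible))
            g = eligible[j]
            if not np.isfinite(g):
                break
            i = int(rowarg[j])
            if flips >= max_flips:
                warnings.warn("binary pursuit flip cap reached; partial result",
                              RuntimeWarning)
                break
            flips += 1
            lo = max(0, i - n_w + 1)
            hi = min(n_pos, i + n_w)
            t0 = lo - i + n_w - 1
            t1 = hi - i + n_w - 1
            seg = r[:, i:i + n_w]
            if not x[j, i]:
                # ---- insertion -----------------------------------------
                seg -= self.w[j]
                x[j, i] = True
                C[:, lo:hi] -= self.K_ww[:, j, t0:t1]
                total = g
                beta = np.zeros(self.n_comp)
                if self.n_comp:
                    rseg = seg.ravel()
                    beta = self.P[j] @ rseg
                    np.clip(beta, -cfg.coef_clamp, cfg.coef_clamp, out=beta)
                    improve = float(beta @ (self.D[j].reshape(self.n_comp, -1)
                                            @ rseg)
                                    - 0.5 * beta @ self.DtD[j] @ beta)
                    if improve > 0:
                        seg -= np.einsum("c,cek->ek", beta, self.D[j])
                        C[:, lo:hi] -= np.einsum(
                            "c,jct->jt", beta, self.K_wd[:, j, :, t0:t1])
                        total += improve
                    else:
                        beta = np.zeros(self.n_comp)
                if np.any(beta):
                    coefs[(j, i)] = beta
                obj -= total
                if track_history:
                    history.append(FlipRecord(j, i, True, float(g),
                                              float(total), beta.copy()))
            else:
                # ---- deletion: restore exactly what was subtracted -----
                beta = coefs.get((j, i), np.zeros(self.n_comp))
                w_eff = self.w[j].copy()
                if np.any(beta):
                    w_eff += np.einsum("c,cek->ek", beta, self.D[j])
                exact = (self.theta[j] - float(np.sum(w_eff * seg))
                         - 0.5 * float(np.sum(w_eff ** 2)))
                if exact <= self.tol[j]:
                    # canonical surface overestimated the deletion gain;
                    # freeze this bin until its neighborhood changes
                    G[j, i] = -np.inf
                    if rowarg[j] == i:
                        rowmax[j] = G[j].max()
                        rowarg[j] = G[j].argmax()
                    continue
                seg += w_eff
                x[j, i] = False
                coefs.pop((j, i), None)
                C[:, lo:hi] += self.K_ww[:, j, t0:t1]
                if np.any(beta):
                    C[:, lo:hi] += np.einsum(
                        "c,jct->jt", beta, self.K_wd[:, j, :, t0:t1])
                obj -= exact
                if track_history:
                    history.append(FlipRecord(j, i, False, float(g),
                                              float(exact), beta.copy()))
            refresh_rows(lo, hi)
        events = self._collect(x, coefs)
        info = {"objective_start": obj0, "objective": obj,
                "n_flips": flips, "history": history,
                "residual": r}
        return events, info

    def _collect(self, x: np.ndarray, coefs) -> SpikeEventSet:
        js, bins = np.nonzero(x)
        n = js.size
        off = np.zeros(n)
        amp = np.zeros(n)
        wid = np.zeros(n)
        comp_idx = {c: k for k, c in enumerate(self.config.correction)}
        for m, (j, i) in enumerate(zip(js, bins)):
            beta = coefs.get((j, i))
            if beta is None:
                continue
            if "time" in comp_idx:
                off[m] = beta[comp_idx["time"]]
            if "amp" in comp_idx:
                amp[m] = beta[comp_idx["amp"]]
            if "width" in comp_idx:
                wid[m] = beta[comp_idx["width"]]
        return SpikeEventSet(js, bins, off, amp, wid,
                             n_neurons=self.J, n_bins=x.shape[1] + self.n_w - 1)


def greedy_solve(data: np.ndarray, ws: WaveformSet, theta,
                 config: PursuitConfig | None = None,
                 track_history: bool = False):
    """One-shot binary pursuit on a whitened segment.

    Convenience wrapper building a :class:`PursuitEngine` and solving the
    whole segment at once.  Returns ``(events, info)``.
    """
    engine = PursuitEngine(ws, theta, config)
    return engine.solve(data, track_history=track_history)


def plan_blocks(n_samples: int, sampling_rate_hz: float, block_s: float,
                n_taps: int):
    """Partition a recording into core blocks with one-template padding.

    Each block owns the core region ``[start, stop)``; the solver sees
    ``[max(0, start - n_taps), min(T, stop + n_taps))`` so spikes near
    boundaries have their full footprint in view, but only events whose
    start bin lies in the core are emitted -- every bin is owned by
    exactly one block, so no deduplication is needed.
    """
    block_len = int(round(block_s * sampling_rate_hz))
    if block_len <= 2 * n_taps:
        raise ValueError("block length must exceed two template durations")
    blocks = []
    for start in range(0, n_samples, block_len):
        stop = min(start + block_len, n_samples)
        blocks.append((start, stop,
                       max(0, start - n_taps), min(n_samples, stop + n_taps)))
    return blocks


def process_blocks(data: np.ndarray, ws: WaveformSet, theta,
                   sampling_rate_hz: float,
                   config: PursuitConfig | None = None):
    """Binary pursuit over a long recording in fixed-duration blocks.

    Blocks are solved independently on padded slices (see
    :func:`plan_blocks`); the result for isolated spikes is independent
    of the block size.  Returns ``(events, info)`` with the summed
    objective and per-block diagnostics.
    """
    data = np.atleast_2d(np.asarray(data, float))
    config = config or PursuitConfig()
    engine = PursuitEngine(ws, theta, config)
    blocks = plan_blocks(data.shape[1], sampling_rate_hz, config.block_s,
                         ws.n_taps)
    parts = []
    obj = obj0 = 0.0
    n_flips = 0
    for start, stop, lo, hi in blocks:
        if hi - lo < ws.n_taps:
            continue
        ev, info = engine.solve(data[:, lo:hi])
        keep = (ev.bin + lo >= start) & (ev.bin + lo < stop)
        ev = ev.select(keep)
        ev.bin = ev.bin + lo
        ev.n_bins = data.shape[1]
        parts.append(ev)
        obj0 += info["objective_start"]
        obj += info["objective"]
        n_flips += info["n_flips"]
    if parts:
        merged = SpikeEventSet(
            np.concatenate([p.neuron_id for p in parts]),
            np.concatenate([p.bin for p in parts]),
            np.concatenate([p.subbin_offset for p in parts]),
            np.concatenate([p.amp_coef for p in parts]),
            np.concatenate([p.width_coef for p in parts]),
            n_neurons=ws.n_neurons, n_bins=data.shape[1],
        ).sorted()
    else:
        merged = SpikeEventSet.empty(ws.n_neurons, data.shape[1])
    info = {"objective_start": obj0, "objective": obj,
            "n_flips": n_flips, "n_blocks": len(blocks)}
    return merged, info
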