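"""Clustering-based initializer: detection, snippets, PCA, k-means.

This is the conventional spike-sorting front end used to seed the
model-based sorter: threshold detection of negative-going voltage peaks,
extraction of fixed-length snippets from a small electrode neighborhood,
PCA dimensionality reduction, and seeded k-means clustering with
Mahalanobis outlier rejection.

The initializer deliberately inherits the known failure mode of
clustering sorters: temporally overlapping spikes produce superimposed
snippets that land far from every cluster and are left unassigned, so
near-synchronous spikes are systematically missed.  That bias is what
binary pursuit subsequently corrects, and what the diagnostics module
measures via the zero-lag cross-correlogram notch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal
from scipy.stats import chi2
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .events import SpikeEventSet
from .io import Recording, window_bins
from .waveforms import noise_mad_scale

log = logging.getLogger(__name__)


def detect_candidates(recording: Recording,
                      threshold_multiplier: float = 4.0,
                      window_ms: float = 1.5) -> pd.DataFrame:
    """Detect candidate spike peaks by per-electrode thresholding.

    Local minima of each electrode's trace deeper than
    ``threshold_multiplier`` times that electrode's robust noise scale
    (median absolute deviation / 0.6745) are kept, then deduplicated
    across electrodes within a dead time of one window, retaining the
    largest-amplitude detection.  Returns a DataFrame with columns
    ``electrode``, ``bin``, ``amplitude`` sorted by bin.
    """
    if threshold_multiplier <= 0:
        raise ValueError("threshold_multiplier must be > 0")
    scale = noise_mad_scale(recording.data)
    if not np.any(recording.data):
        # an identically zero recording has no local extrema at all
        return pd.DataFrame(columns=["electrode", "bin", "amplitude"])
    if np.any(scale == 0):
        raise ValueError(
            f"electrodes {np.where(scale == 0)[0].tolist()} have zero noise "
            "scale (constant trace); cannot threshold")
    w = window_bins(window_ms, recording.sampling_rate_hz)
    rows = []
    for e in range(recording.n_electrodes):
        peaks, props = scipy.signal.find_peaks(
            -recording.data[e], height=threshold_multiplier * scale[e],
            distance=w)
        for b, h in zip(peaks, props["peak_heights"]):
            rows.append((e, int(b), float(h)))
    if not rows:
        return pd.DataFrame(columns=["electrode", "bin", "amplitude"])
    df = pd.DataFrame(rows, columns=["electrode", "bin", "amplitude"])
    # cross-electrode dedup: greedily accept in decreasing amplitude
    df = df.sort_values("amplitude", ascending=False)
    accepted_bins: list[int] = []
    keep_idx = []
    for idx, b in zip(df.index, df["bin"].to_numpy()):
        pos = np.searchsorted(accepted_bins, b)
        near = []
        if pos > 0:
            near.append(accepted_bins[pos - 1])
        if pos < len(accepted_bins):
            near.append(accepted_bins[pos])
        if all(abs(b - nb) >= w for nb in near):
            accepted_bins.insert(pos, b)
            keep_idx.append(idx)
    return df.loc[keep_idx].sort_values("bin").reset_index(drop=True)


@dataclass
class SnippetMatrix:
    """Voltage snippets around detected events.

    ``snippets`` is (n_events, n_electrodes * window_bins): the window
    from the center electrode and its nearest neighbors, peak-aligned at
    the window center.  So that snippets from different center
    electrodes live in one comparable feature space, each channel is
    placed at its absolute electrode slot and channels outside the
    neighborhood are zero.
    """

    events: pd.DataFrame
    snippets: np.ndarray
    window_bins: int
    n_neighbors: int
    align_tap: int


def extract_snippets(recording: Recording, events: pd.DataFrame,
                     window_ms: float = 1.5,
                     n_neighbors: int = 6) -> SnippetMatrix:
    """Cut peak-aligned windows around each event.

    Each snippet holds the window from the event's center electrode and
    its ``n_neighbors`` nearest electrodes (by geometry), laid out at
    their absolute electrode positions (other channels zero) so events
    detected on different electrodes are directly comparable.  Events
    whose window would cross a recording edge are skipped with a logged
    warning.
    """
    w = window_bins(window_ms, recording.sampling_rate_hz)
    half = w // 2
    n_e = recording.n_electrodes
    n_neighbors = min(n_neighbors, n_e - 1)
    geom = recording.geometry
    order = np.argsort(
        np.linalg.norm(geom[:, None] - geom[None, :], axis=2), axis=1)
    rows, keep = [], []
    for idx, (e, b) in enumerate(zip(events["electrode"].to_numpy(),
                                     events["bin"].to_numpy())):
        lo = b - half
        if lo < 0 or lo + w > recording.n_samples:
            log.warning("event at bin %d too near the edge; skipped", b)
            continue
        chans = order[e, :1 + n_neighbors]
        snip = np.zeros((n_e, w))
        snip[chans] = recording.data[chans, lo:lo + w]
        rows.append(snip.ravel())
        keep.append(idx)
    snippets = (np.asarray(rows, dtype=float) if rows
                else np.zeros((0, n_e * w)))
    return SnippetMatrix(events.iloc[keep].reset_index(drop=True), snippets,
                         w, n_neighbors, half)


def reduce_pca(snippets: np.ndarray, n_dims: int = 5):
    """Project mean-centered snippets onto their top principal components.

    Returns ``(scores, pca)`` with component variances non-increasing.
    Raises if ``n_dims`` exceeds the effective rank of the snippet matrix.
    """
    snippets = np.asarray(snippets, float)
    n, d = snippets.shape
    if n < 2:
        raise ValueError("need at least 2 events for PCA")
    if n_dims > min(n, d):
        raise ValueError(f"n_dims={n_dims} exceeds feature dimension")
    pca = PCA(n_components=min(n - 1, d), svd_solver="full")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # zero-variance (all-identical) snippets trip a harmless divide
        warnings.simplefilter("ignore", RuntimeWarning)
        full_scores = pca.fit_transform(snippets)
    if pca.explained_variance_[0] <= 1e-30:
        # all snippets identical: every centered projection is zero
        return np.zeros((n, n_dims)), pca
    tol = 1e-10 * pca.explained_variance_[0]
    rank = int(np.sum(pca.explained_variance_ > tol))
    if n_dims > rank:
        raise ValueError(f"n_dims={n_dims} exceeds snippet rank {rank}")
    return full_scores[:, :n_dims], pca


def _mahalanobis_outliers(features: np.ndarray, labels: np.ndarray,
                          quantile: float = 0.9999, seed: int = 0) -> np.ndarray:
    """Unassign points beyond the chi-square Mahalanobis radius of every
    cluster; returns labels with outliers set to -1.

    Cluster location/scatter are estimated robustly (minimum covariance
    determinant) so that superposition events and spurious threshold
    crossings inside a cluster cannot inflate their own acceptance radius.
    """
    from sklearn.covariance import MinCovDet

    d = features.shape[1]
    radius_sq = chi2.ppf(quantile, df=d)
    out = labels.copy()
    for c in np.unique(labels):
        idx = labels == c
        pts = features[idx]
        if pts.shape[0] > 3 * d:
            mcd = MinCovDet(random_state=seed).fit(pts)
            mu, cov = mcd.location_, mcd.covariance_
        else:
            mu = pts.mean(axis=0)
            cov = np.atleast_2d(np.cov(pts.T)) if pts.shape[0] > d else np.eye(d)
        cov = cov + 1e-9 * max(np.trace(cov) / d, 1e-300) * np.eye(d)
        icov = np.linalg.pinv(cov)
        dx = pts - mu
        m2 = np.einsum("ni,ij,nj->n", dx, icov, dx)
        flag = np.where(idx)[0][m2 > radius_sq]
        out[flag] = -1
    return out


def cluster_events(features: np.ndarray, k: int | None = None,
                   k_range=(2, 10), seed: int = 0,
                   outlier_quantile: float = 0.9999):
    """Seeded k-means with optional silhouette-based choice of k.

    Returns ``(labels, report)`` where outliers (points beyond the
    Mahalanobis radius of every cluster) are labelled -1.  ``k`` may be
    given directly (the analogue of choosing the cluster count by eye) or
    selected by the best silhouette score over ``k_range``.
    """
    features = np.asarray(features, float)
    n = features.shape[0]
    if k is not None and (k < 1 or k > n):
        raise ValueError(f"k={k} invalid for {n} events")
    sil = None
    if k is None:
        best = (-np.inf, None)
        rng = np.random.default_rng(seed)
        sub = rng.choice(n, size=min(n, 2000), replace=False)
        for kk in range(max(2, k_range[0]), min(k_range[1], n - 1) + 1):
            lab = KMeans(kk, n_init=5, random_state=seed).fit_predict(features)
            if np.unique(lab[sub]).size < 2:
                continue
            s = silhouette_score(features[sub], lab[sub])
            if s > best[0]:
                best = (s, kk)
        if best[1] is None:
            raise ValueError("silhouette selection failed for every k")
        sil, k = best
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        labels = KMeans(k, n_init=5, random_state=seed).fit_predict(features)
    labels = _mahalanobis_outliers(features, labels, outlier_quantile, seed)
    report = {"k": int(k), "silhouette": sil,
              "n_outliers": int(np.sum(labels == -1)),
              "counts": np.bincount(labels[labels >= 0], minlength=k).tolist()}
    return labels, report


@dataclass
class InitResult:
    """Output of the clustering initializer."""

    events: SpikeEventSet
    labels: np.ndarray
    detections: pd.DataFrame
    p: np.ndarray
    report: dict


def cluster_initialize(recording: Recording, k: int | None = None,
                       threshold_multiplier: float = 4.0,
                       window_ms: float = 1.5, n_neighbors: int = 6,
                       n_dims: int = 5, k_range=(2, 10), seed: int = 0,
                       outlier_quantile: float = 0.9999) -> InitResult:
    """Full initializer: detect -> snippets -> PCA -> cluster -> spike trains.

    The returned event bins follow the sorter's convention (bin = sample
    at which waveform tap 0 is placed), assuming the waveform peak sits
    at the window center.  Per-neuron plug-in rates are
    ``p_j = n_j / n_bins``.
    """
    det = detect_candidates(recording, threshold_multiplier, window_ms)
    snip = extract_snippets(recording, det, window_ms, n_neighbors)
    feats, _ = reduce_pca(snip.snippets, n_dims)
    labels, report = cluster_events(feats, k, k_range, seed, outlier_quantile)
    w = snip.window_bins
    assigned = labels >= 0
    bins = snip.events["bin"].to_numpy()[assigned] - snip.align_tap
    nid = labels[assigned]
    ok = (bins >= 0) & (bins + w <= recording.n_samples)
    events = SpikeEventSet(nid[ok], bins[ok], n_neurons=report["k"],
                           n_bins=recording.n_samples)
    p = events.rates()
    report = dict(report, rates_hz=(p * recording.sampling_rate_hz).tolist(),
                  n_detections=len(snip.events))
    return InitResult(events, labels, snip.events, p, report)
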