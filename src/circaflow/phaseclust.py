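"""Phase clustering and circular statistics for rhythmic gene sets.

Rhythmic genes are z-scored across time points, partitioned into k temporal
profile clusters (k = 6 by default, Euclidean K-means with many seeded
restarts), and each cluster is summarised by the acrophase of a cosinor fit to
its centroid and by an amplitude class (medium vs high, split at the upper
tercile of the rhythmic genes' relative amplitudes).  Phase populations are
summarised by the Rayleigh mean resultant vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .rhythmdet import ExpressionMatrix, cosinor_fit

__all__ = [
    "CircularSummary",
    "ClusterAssignment",
    "normalize_profiles",
    "kmeans_phase_clusters",
    "circular_summary",
    "phase_histogram",
]


@dataclass
class CircularSummary:
    """Rayleigh vector summary of a set of circadian phases (hours mod 24)."""

    mean_phase: float
    R: float
    rayleigh_p: float
    n: int


@dataclass
class ClusterAssignment:
    labels: pd.Series               # gene_id -> cluster id in 1..k
    centroids: pd.DataFrame         # cluster id x time
    peak_ct: pd.Series              # cluster id -> acrophase of centroid (h)
    amplitude_class: pd.Series      # cluster id -> {"medium", "high"}
    inertia: float


def normalize_profiles(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene z-scoring across time points (mean 0, SD 1 per row)."""
    Y = matrix.values
    sd = Y.std(axis=1)
    if np.any(sd <= 0):
        bad = [g for g, s in zip(matrix.gene_ids, sd) if s <= 0]
        raise ValueError(f"cannot standardize constant genes: {bad[:5]}")
    Z = (Y - Y.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(Z, index=pd.Index(matrix.gene_ids, name="gene_id"),
                        columns=matrix.times)


def kmeans_phase_clusters(profiles: pd.DataFrame, k: int = 6, seed: int = 0,
                          n_init: int = 50,
                          rel_amplitudes: pd.Series | None = None,
                          amplitude_cut: float | None = None,
                          period_h: float = 24.0) -> ClusterAssignment:
    """Partition z-scored profiles into k temporal clusters.

    ``rel_amplitudes`` (gene -> floor-normalized amplitude) drives the
    medium/high class of each cluster: high when the median member amplitude
    exceeds ``amplitude_cut`` (default: the upper tercile over all genes).
    """
    if len(profiles) < k:
        raise ValueError("fewer profiles than clusters")
    times = np.asarray(profiles.columns, dtype=float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(profiles.values)

    # relabel clusters 1..k by ascending centroid acrophase for stable reporting
    peaks = np.array([cosinor_fit(times, c, period_h=period_h).phase_h % 24.0
                      for c in km.cluster_centers_])
    order = np.argsort(peaks)
    remap = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = pd.Series([remap[int(l)] for l in raw_labels],
                       index=profiles.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_[order],
                             index=pd.Index(range(1, k + 1), name="cluster"),
                             columns=profiles.columns)
    peak_ct = pd.Series(peaks[order], index=centroids.index, name="peak_ct")

    if rel_amplitudes is not None:
        amps = rel_amplitudes.reindex(profiles.index)
        if amplitude_cut is None:
            amplitude_cut = float(np.quantile(amps.dropna(), 2.0 / 3.0))
        med = amps.groupby(labels).median()
        amp_class = pd.Series(np.where(med > amplitude_cut, "high", "medium"),
                              index=med.index, name="amplitude_class")
        amp_class = amp_class.reindex(centroids.index)
    else:
        amp_class = pd.Series("medium", index=centroids.index,
                              name="amplitude_class")
    return ClusterAssignment(labels=labels, centroids=centroids, peak_ct=peak_ct,
                             amplitude_class=amp_class, inertia=float(km.inertia_))


def circular_summary(phases, period_h: float = 24.0) -> CircularSummary:
    """Rayleigh mean resultant vector of phases in hours (mod period).

    R = 1 means perfect synchrony, R near 0 a dispersed phase population; the
    Rayleigh test p-value uses the standard large-n approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - (nR)^2)) - (1 + 2n))``.
    """
    ph = np.asarray(phases, dtype=float)
    if ph.size == 0:
        raise ValueError("no phases given")
    ang = ph * 2.0 * np.pi / period_h
    C, S = np.cos(ang).sum(), np.sin(ang).sum()
    n = ph.size
    R = float(np.hypot(C, S) / n)
    mean_phase = float((np.arctan2(S, C) * period_h / (2.0 * np.pi)) % period_h)
    z = n * R * R
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - (n * R) ** 2))
                     - (1.0 + 2.0 * n)))
    return CircularSummary(mean_phase=mean_phase, R=R, rayleigh_p=min(p, 1.0), n=n)


def phase_histogram(phases, n_bins: int = 24, period_h: float = 24.0) -> pd.DataFrame:
    """Counts of phases over half-open bins covering [0, period)."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    ph = np.asarray(phases, dtype=float) % period_h
    if ph.size == 0:
        raise ValueError("no phases given")
    edges = np.linspace(0.0, period_h, n_bins + 1)
    counts, _ = np.histogram(ph, bins=edges)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "count": counts})
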