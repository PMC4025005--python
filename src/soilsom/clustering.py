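"""K-means clustering of the SOM codebook with Davies-Bouldin model selection.

The map's codebook vectors (not the raw cases) are clustered: each lattice
unit gets a cluster id, and cases inherit the cluster of their BMU. The
number of clusters is chosen by scanning a k range and taking the minimum
Davies-Bouldin index (DBI), the mean over clusters of the worst
(within-scatter sum / centroid separation) ratio — smaller is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, NumericalError
from .som import SOMModel, bmus

_MAX_ITER = 300


@dataclass
class ClusterQuality:
    """Result of clustering at one k: labels over codebook units, centroids, DBI."""

    k: int
    dbi: float
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float


def _plusplus_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy k-means++ seeding: sample 2 + floor(ln k) candidates per step
    and keep the one that most reduces the potential."""
    n = x.shape[0]
    n_cand = 2 + int(np.log(k))
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = np.sum((x - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = x[rng.integers(n)]
            continue
        cand = rng.choice(n, size=n_cand, p=d2 / total)
        pots = [np.minimum(d2, np.sum((x - x[c]) ** 2, axis=1)).sum() for c in cand]
        best = cand[int(np.argmin(pots))]
        centers[j] = x[best]
        d2 = np.minimum(d2, np.sum((x - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(x: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    k = centers.shape[0]
    labels = np.full(x.shape[0], -1)
    for _ in range(_MAX_ITER):
        d2 = cdist(x, centers, metric="sqeuclidean")
        new_labels = np.argmin(d2, axis=1)
        # empty-cluster repair: reseed at the point farthest from its centroid
        for j in range(k):
            if not np.any(new_labels == j):
                far = int(np.argmax(d2[np.arange(len(x)), new_labels]))
                centers[j] = x[far]
                new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centers[j] = x[labels == j].mean(axis=0)
    inertia = float(np.sum((x - centers[labels]) ** 2))
    return labels, centers, inertia


def kmeans(x, k: int, seed: int = 0, n_restarts: int = 10) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's algorithm with k-means++ seeding, best of ``n_restarts`` by inertia.

    Deterministic for a fixed seed. Returns (labels, centroids, inertia).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ConfigError("expected a 2-D vector table")
    if not (1 <= k <= x.shape[0]):
        raise ConfigError(f"k={k} out of range for {x.shape[0]} vectors")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_restarts, 1)):
        labels, centers, inertia = _lloyd(x, _plusplus_init(x, k, rng))
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia)
    return best


def davies_bouldin(vectors, labels) -> float:
    """Davies-Bouldin index: mean over clusters of max_{j!=i} (S_i+S_j)/M_ij.

    ``S`` is the mean Euclidean distance of members to their centroid and
    ``M`` the centroid-centroid distance. All-singleton clusterings score 0;
    coincident centroids make the ratio undefined and raise.
    """
    x = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    k = len(ids)
    if k < 2:
        raise ConfigError("need at least 2 clusters")
    centroids = np.stack([x[labels == c].mean(axis=0) for c in ids])
    s = np.array([np.linalg.norm(x[labels == c] - centroids[i], axis=1).mean()
                  for i, c in enumerate(ids)])
    m = cdist(centroids, centroids)
    off = ~np.eye(k, dtype=bool)
    if np.any(m[off] == 0):
        raise NumericalError("coincident centroids: Davies-Bouldin ratio undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (s[:, None] + s[None, :]) / m
    np.fill_diagonal(ratio, -np.inf)
    return float(np.mean(ratio.max(axis=1)))


def select_k(
    codebook,
    k_range=range(2, 11),
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[ClusterQuality, pd.DataFrame]:
    """Scan a k range, cluster at each k, and pick the minimum-DBI solution.

    Ties in the argmin go to the smaller k. Returns the winning
    :class:`ClusterQuality` and the full (k, dbi) scan table.
    """
    x = np.asarray(codebook, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ConfigError("empty k range")
    if ks[0] < 2 or ks[-1] > x.shape[0]:
        raise ConfigError(f"k range {ks[0]}..{ks[-1]} outside [2, {x.shape[0]}]")
    results: list[ClusterQuality] = []
    for k in ks:
        labels, centroids, inertia = kmeans(x, k, seed=seed, n_restarts=n_restarts)
        results.append(ClusterQuality(k=k, dbi=davies_bouldin(x, labels),
                                      labels=labels, centroids=centroids, inertia=inertia))
    scan = pd.DataFrame({"k": [r.k for r in results], "dbi": [r.dbi for r in results]})
    best = min(results, key=lambda r: (r.dbi, r.k))
    return best, scan


def project_labels(model: SOMModel, unit_labels, data) -> np.ndarray:
    """Label each case with the cluster of its best matching unit."""
    unit_labels = np.asarray(unit_labels)
    if unit_labels.shape[0] != model.n_units:
        raise ConfigError("unit labels must cover every lattice unit")
    return unit_labels[bmus(model, data)]
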