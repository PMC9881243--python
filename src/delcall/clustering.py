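"""Unsupervised calling: PCA embedding, Ward clustering, cluster filters.

Candidates on one chromosome are embedded by the top two principal
components of their (mean-centered, unscaled) LN feature matrix and
partitioned into four clusters by bottom-up agglomerative clustering with
the Euclidean metric and Ward linkage.  The four clusters are meant to
capture perfect homozygous deletions, noisy homozygous deletions, noisy
hemizygous deletions, and the mixture of marginal candidates with
wild-type intervals.

Each cluster is then labeled good or bad from the deletion-band mass of
its members: an ideal deletion has nearly all of its length in bands
T0-T2, so a cluster whose top-half averages THAvg_LN_0 + THAvg_LN_1 +
THAvg_LN_2 sum to at least 0.7 is good (mostly true deletions).  Within a
cluster, the feature with the largest THAvg is the principal feature i*,
and assuming the LN_{i*} values roughly follow the empirical rule, the
thresholds T_high/T_low = Avg +/- SD bound the bulk of the cluster.
Members of a good cluster are discarded only when both their principal
feature and the sum of the other two fall below T_low; members of a bad
cluster are kept only when either exceeds T_high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA

#: minimum total deletion-band mass defining a true deletion / good cluster
GOOD_THRESHOLD = 0.7
#: number of clusters cut from the dendrogram
DEFAULT_K = 4


@dataclass(frozen=True)
class ClusterStats:
    """Per-cluster order statistics over the deletion bands LN_0..LN_2.

    ``sr`` holds, per feature, the member indices sorted ascending by that
    feature's LN value.  ``thavg`` is the mean of the ceil(N/2) largest
    values.  ``principal`` is the feature index with the largest THAvg
    (ties to the smallest index); ``t_high``/``t_low`` are its mean +/- SD.
    """

    sr: tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]
    avg: tuple[float, float, float]
    std: tuple[float, float, float]
    thavg: tuple[float, float, float]
    principal: int
    t_high: float
    t_low: float


def embed_pca(feature_matrix: np.ndarray) -> np.ndarray:
    """Top-two principal-component coordinates of the LN matrix.

    Features are mean-centered but not variance-scaled: all LN features
    already share the [0, 1] scale.  With fewer than two candidates there
    is no covariance to decompose and the embedding is bypassed (zeros).
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D (candidates x features)")
    n = X.shape[0]
    if n < 2:
        return np.zeros((n, 2))
    pca = PCA(n_components=2, svd_solver="full")
    return pca.fit_transform(X)


def cluster_candidates(embeddings: np.ndarray, k: int = DEFAULT_K) -> np.ndarray:
    """Ward/Euclidean agglomerative clustering cut at ``k`` clusters.

    Returns one integer label per candidate.  Deterministic given the
    input; requires at least ``k`` candidates.
    """
    emb = np.asarray(embeddings, dtype=float)
    if emb.shape[0] < k:
        raise ValueError(f"need at least {k} candidates to cut {k} clusters")
    model = AgglomerativeClustering(n_clusters=k, metric="euclidean", linkage="ward")
    return model.fit_predict(emb)


def _top_half_mean(values: np.ndarray) -> float:
    n = values.size
    top = math.ceil(n / 2)
    return float(np.sort(values)[-top:].mean())


def compute_cluster_stats(ln_rows: np.ndarray) -> ClusterStats:
    """Order statistics of one cluster's members over LN_0..LN_2."""
    X = np.asarray(ln_rows, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("cluster must be a non-empty 2-D LN matrix")
    n = X.shape[0]
    sr = tuple(tuple(int(j) for j in np.argsort(X[:, i], kind="stable")) for i in range(3))
    avg = tuple(float(X[:, i].mean()) for i in range(3))
    std = tuple(float(X[:, i].std(ddof=1)) if n > 1 else 0.0 for i in range(3))
    thavg = tuple(_top_half_mean(X[:, i]) for i in range(3))
    principal = int(np.argmax(thavg))  # ties resolve to the smallest index
    return ClusterStats(
        sr=sr,
        avg=avg,
        std=std,
        thavg=thavg,
        principal=principal,
        t_high=avg[principal] + std[principal],
        t_low=avg[principal] - std[principal],
    )


def label_cluster(stats: ClusterStats) -> str:
    """"good" iff the summed top-half deletion-band mass reaches 0.7."""
    return "good" if sum(stats.thavg) >= GOOD_THRESHOLD else "bad"


def filter_cluster(
    ln_rows: np.ndarray, stats: ClusterStats, label: str
) -> np.ndarray:
    """Boolean keep-mask over the cluster's members.

    Good cluster: a member is discarded only when its principal feature
    AND the sum of the other two deletion-band features both fall strictly
    below T_low.  Bad cluster: a member is kept only when either quantity
    strictly exceeds T_high.
    """
    X = np.asarray(ln_rows, dtype=float)
    i = stats.principal
    others = [j for j in range(3) if j != i]
    primary = X[:, i]
    rest = X[:, others].sum(axis=1)
    if label == "good":
        return ~((primary < stats.t_low) & (rest < stats.t_low))
    if label == "bad":
        return (primary > stats.t_high) | (rest > stats.t_high)
    raise ValueError(f"unknown cluster label: {label!r}")


def call_from_features(
    ln_matrix: np.ndarray, k: int = DEFAULT_K
) -> tuple[np.ndarray, dict]:
    """Run the full unsupervised caller over one chromosome's LN matrix.

    Returns a boolean keep-mask over the candidates and a diagnostics dict
    with the embedding, cluster labels and per-cluster statistics.  With
    fewer than ``k`` candidates the clustering is bypassed and each
    candidate is called directly by the true-deletion definition
    sum(LN_0..LN_2) >= 0.7.
    """
    X = np.asarray(ln_matrix, dtype=float)
    n = X.shape[0]
    if n == 0:
        return np.zeros(0, dtype=bool), {"clusters": {}, "embedding": np.zeros((0, 2))}
    if n < k:
        keep = X[:, :3].sum(axis=1) >= GOOD_THRESHOLD
        return keep, {"clusters": {}, "embedding": np.zeros((n, 2)), "fallback": True}
    emb = embed_pca(X)
    labels = cluster_candidates(emb, k=k)
    keep = np.zeros(n, dtype=bool)
    diagnostics: dict = {"embedding": emb, "assignment": labels, "clusters": {}}
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        stats = compute_cluster_stats(X[idx])
        quality = label_cluster(stats)
        mask = filter_cluster(X[idx], stats, quality)
        keep[idx] = mask
        diagnostics["clusters"][c] = {
            "label": quality,
            "stats": stats,
            "size": int(idx.size),
            "kept": int(mask.sum()),
        }
    return keep, diagnostics
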