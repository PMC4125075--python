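"""Hierarchical classification of signature vectors and its quality metrics.

Strains (or promoters) are clustered by average-linkage agglomerative
clustering with the Euclidean metric on their feature vectors.  Cluster
quality is scored with the Davies-Bouldin index — the average, over clusters,
of the worst ratio of summed within-cluster scatters to between-centroid
distance; smaller is better.  The index drives the choice of the most
informative wavelet period, and a leave-one-out analysis quantifies the
stability of the classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment

from .exceptions import ParameterError, ValidationError

__all__ = [
    "ClusteringResult",
    "hcluster",
    "davies_bouldin",
    "choose_period",
    "loo_bootstrap",
    "misclassification_count",
    "export_dendrogram",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    """Outcome of one hierarchical clustering run.

    Attributes
    ----------
    linkage : ndarray, shape (n-1, 4)
        SciPy linkage matrix (merge pairs and heights).
    labels : ndarray of int
        Cluster assignment per sample (1..k).
    db_score : float
        Davies-Bouldin score of the cut (NaN for k=1).
    n_misclassified : int or None
        Permutation-minimal misclassification count against true groups,
        when true groups were supplied.
    names : list of str or None
        Leaf names, used for dendrogram export.
    """

    linkage: np.ndarray
    labels: np.ndarray
    db_score: float
    n_misclassified: int | None = None
    names: list | None = None


def _as_matrix(features) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValidationError("features must be a 2-D (n_samples, n_features) matrix")
    if not np.all(np.isfinite(X)):
        raise ValidationError("features must be finite")
    return X


def hcluster(features, k: int, true_groups=None, names=None) -> ClusteringResult:
    """Average-linkage Euclidean agglomerative clustering cut into ``k`` groups.

    Deterministic given the input.  ``k`` must not exceed the number of
    samples.  When ``true_groups`` is given, the permutation-minimal
    misclassification count is recorded on the result.
    """
    X = _as_matrix(features)
    n = X.shape[0]
    if n < 2:
        raise ValidationError("clustering requires at least 2 samples")
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    Z = linkage(X, method="average", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    db = davies_bouldin(X, labels) if len(np.unique(labels)) >= 2 else float("nan")
    n_mis = None
    if true_groups is not None:
        n_mis = misclassification_count(labels, true_groups)
    return ClusteringResult(
        linkage=Z, labels=labels, db_score=db, n_misclassified=n_mis, names=names
    )


def davies_bouldin(features, labels) -> float:
    """Davies-Bouldin score: ``(1/K) sum_i max_{j!=i} (S_i + S_j) / M_ij``.

    ``S_i`` is the mean Euclidean distance of cluster members to their
    centroid and ``M_ij`` the distance between centroids ``i`` and ``j``.
    Coincident centroids give an infinite score.
    """
    X = _as_matrix(features)
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValidationError("labels must match the number of samples")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("davies_bouldin requires at least 2 clusters")
    cents = np.array([X[labels == u].mean(axis=0) for u in uniq])
    scatter = np.array(
        [np.mean(np.linalg.norm(X[labels == u] - cents[i], axis=1)) for i, u in enumerate(uniq)]
    )
    K = len(uniq)
    total = 0.0
    for i in range(K):
        worst = 0.0
        for j in range(K):
            if i == j:
                continue
            m = float(np.linalg.norm(cents[i] - cents[j]))
            ratio = (scatter[i] + scatter[j]) / m if m > 0 else float("inf")
            worst = max(worst, ratio)
        total += worst
    return total / K


def choose_period(signatures, true_groups, exclude_mask=None):
    """Select the wavelet period whose signature rows best separate the groups.

    For every period on the (shared) grid, the per-sample coefficient rows at
    that period are scored with :func:`davies_bouldin` against the true
    groups; the period with the minimal score wins.  Degenerate (all-zero)
    rows score ``+inf``; an optional boolean ``exclude_mask`` over the period
    grid removes periods from consideration (scored ``+inf``), mirroring the
    practice of masking period ranges that are known not to produce tight
    clusters.

    Returns
    -------
    (period, scores) : (float, ndarray)
        The selected period and the full score-vs-period profile.
    """
    if len(signatures) < 2:
        raise ValidationError("choose_period requires at least 2 signatures")
    periods = signatures[0].periods
    for s in signatures[1:]:
        if len(s.periods) != len(periods) or not np.allclose(s.periods, periods):
            raise ValidationError("signatures must share one period grid")
    true_groups = np.asarray(true_groups)
    scores = np.empty(len(periods))
    for i in range(len(periods)):
        rows = np.array([s.coef[i] for s in signatures])
        if not np.any(rows != 0):
            scores[i] = float("inf")
            continue
        scores[i] = davies_bouldin(rows, true_groups)
    if exclude_mask is not None:
        scores = np.where(np.asarray(exclude_mask, dtype=bool), float("inf"), scores)
    if not np.any(np.isfinite(scores)):
        logger.warning("all periods scored +inf; returning the first grid period")
    best = int(np.argmin(scores))
    return float(periods[best]), scores


def loo_bootstrap(features, true_groups, k: int) -> np.ndarray:
    """Leave-one-out stability analysis of the clustering.

    Drops each sample in turn, re-clusters the remaining samples into ``k``
    groups and counts permutation-minimal misclassifications.  Returns the
    array of counts, one per left-out sample (its histogram is the usual
    summary).  Every group must have at least 2 members.
    """
    X = _as_matrix(features)
    groups = np.asarray(true_groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if np.any(counts < 2):
        raise ValidationError("every group needs >= 2 members for leave-one-out")
    out = np.empty(X.shape[0], dtype=int)
    for i in range(X.shape[0]):
        keep = np.arange(X.shape[0]) != i
        res = hcluster(X[keep], k)
        out[i] = misclassification_count(res.labels, groups[keep])
    return out


def misclassification_count(pred_labels, true_groups) -> int:
    """Minimal number of misassigned samples over all label permutations.

    Computed as an optimal assignment (Hungarian algorithm) on the confusion
    matrix, so the count is invariant to cluster renaming and conservative.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_groups)
    if len(pred) != len(true):
        raise ValidationError("label vectors must have equal length")
    pl = np.unique(pred)
    tl = np.unique(true)
    conf = np.zeros((len(pl), len(tl)))
    for i, p in enumerate(pl):
        for j, t in enumerate(tl):
            conf[i, j] = np.sum((pred == p) & (true == t))
    ri, ci = linear_sum_assignment(-conf)
    return int(len(pred) - conf[ri, ci].sum())


def export_dendrogram(result: ClusteringResult, names=None) -> str:
    """Render the merge tree as a Newick string with height-derived lengths.

    Branch lengths follow the ultrametric convention: a node merged at
    height ``h`` places its children at depth ``h/2`` below it, so the
    cophenetic distance between any two leaves equals their merge height.
    """
    Z = np.asarray(result.linkage)
    n = Z.shape[0] + 1
    if names is None:
        names = result.names if result.names is not None else [f"S{i}" for i in range(n)]
    if len(names) != n:
        raise ValidationError(f"need {n} leaf names, got {len(names)}")

    heights = {i: 0.0 for i in range(n)}
    # Iterative construction: subtree string and subtree height per node.
    text = {}
    for i in range(n):
        text[i] = str(names[i])
    for m in range(Z.shape[0]):
        a, b, h, _ = Z[m]
        a, b = int(a), int(b)
        node = n + m
        # each child's leaves sit at depth heights[child]/2 below the child root
        la = (h - heights[a]) / 2.0
        lb = (h - heights[b]) / 2.0
        text[node] = f"({text[a]}:{la:.10g},{text[b]}:{lb:.10g})"
        heights[node] = h
    return text[n + Z.shape[0] - 1] + ";"
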