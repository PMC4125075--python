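"""High-level workflows combining the library modules.

These are the end-to-end recipes a user would otherwise assemble by hand:
growth curves -> growth rates -> wavelet signatures -> period selection ->
hierarchical classification, and the expression-profile variant based on
the two-feature summary.  The command-line interface and the example
scripts are thin wrappers around these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import (ClusteringResult, choose_period, hcluster, loo_bootstrap,
                       misclassification_count)
from .exceptions import ValidationError
from .growth_io import GrowthCurve, compute_growth_rate
from .wavelet_sig import (default_period_grid, expression_features,
                          signature_vector, wavelet_transform)

__all__ = ["SignatureStudy", "signature_study", "expression_feature_matrix",
           "separation_ratio"]


@dataclass
class SignatureStudy:
    """Everything the growth-curve classification workflow produces."""

    curves: list
    growth_rates: list
    signatures: list
    periods: np.ndarray
    chosen_period: float
    db_by_period: np.ndarray
    features: np.ndarray          # signature rows at the chosen period
    raw_features: np.ndarray      # growth-rate vectors, the classical baseline
    clustering: ClusteringResult
    raw_clustering: ClusteringResult
    true_groups: np.ndarray
    loo_counts: np.ndarray | None = None

    @property
    def n_misclassified(self) -> int:
        return self.clustering.n_misclassified

    @property
    def n_misclassified_raw(self) -> int:
        return self.raw_clustering.n_misclassified


def signature_study(
    curves: list[GrowthCurve],
    k: int | None = None,
    n_periods: int = 64,
    group_by: str = "strain",
    run_loo: bool = False,
) -> SignatureStudy:
    """Classify growth curves by wavelet signatures and by raw growth rates.

    ``group_by`` ("strain", "condition" or "both") defines the true groups
    used for period selection and misclassification scoring; ``k`` defaults
    to the number of distinct groups.
    """
    if len(curves) < 2:
        raise ValidationError("need at least 2 curves")

    def group_label(c):
        if group_by == "strain":
            return c.strain
        if group_by == "condition":
            return c.condition
        return f"{c.strain}/{c.condition}"

    labels = [group_label(c) for c in curves]
    uniq = sorted(set(labels))
    groups = np.array([uniq.index(l) for l in labels])
    if k is None:
        k = len(uniq)

    rates = [compute_growth_rate(c) for c in curves]
    dt = rates[0].dt
    n = len(rates[0].mu)
    periods = default_period_grid(dt, n * dt, n_periods)
    sigs = [wavelet_transform(r, periods=periods) for r in rates]

    chosen, scores = choose_period(sigs, groups)
    features = np.array([signature_vector(s, chosen) for s in sigs])
    raw_features = np.array([r.mu for r in rates])

    names = [c.well or f"{c.strain}.{i}" for i, c in enumerate(curves)]
    clustering = hcluster(features, k, true_groups=groups, names=names)
    raw_clustering = hcluster(raw_features, k, true_groups=groups, names=names)
    loo = loo_bootstrap(features, groups, k) if run_loo else None
    return SignatureStudy(
        curves=curves, growth_rates=rates, signatures=sigs, periods=periods,
        chosen_period=chosen, db_by_period=scores, features=features,
        raw_features=raw_features, clustering=clustering,
        raw_clustering=raw_clustering, true_groups=groups, loo_counts=loo,
    )


def expression_feature_matrix(profiles, dt: float) -> np.ndarray:
    """Two wavelet features per condition, concatenated per promoter.

    ``profiles`` is a list (one entry per condition) of
    ``(n_promoters, n_points)`` matrices; the result has shape
    ``(n_promoters, 2 * n_conditions)`` with columns
    ``(t_star, p_star)`` per condition.
    """
    mats = [np.asarray(p, dtype=float) for p in profiles]
    n_prom = mats[0].shape[0]
    feats = np.empty((n_prom, 2 * len(mats)))
    for ci, mat in enumerate(mats):
        if mat.shape[0] != n_prom:
            raise ValidationError("conditions must cover the same promoters")
        for pi in range(n_prom):
            fp = expression_features(mat[pi], dt=dt)
            feats[pi, 2 * ci] = fp.t_star
            feats[pi, 2 * ci + 1] = fp.p_star
    return feats


def separation_ratio(features, groups) -> float:
    """Between-centroid distance over mean within-group scatter (2 groups).

    A simple separability index for a pair of groups: larger means the two
    clusters are farther apart relative to their spread.
    """
    X = np.asarray(features, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValidationError("separation_ratio is defined for exactly 2 groups")
    c0 = X[groups == uniq[0]].mean(axis=0)
    c1 = X[groups == uniq[1]].mean(axis=0)
    between = np.linalg.norm(c0 - c1)
    within = np.mean(
        [np.mean(np.linalg.norm(X[groups == u] - X[groups == u].mean(axis=0), axis=1))
         for u in uniq]
    )
    return float(between / within) if within > 0 else float("inf")
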