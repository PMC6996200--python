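"""Evaluation metrics: clustering accuracy, loading recovery, mixing,
separation, and the false-positive differential-accessibility rate."""
from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import (normalized_mutual_info_score, roc_auc_score,
                             silhouette_score)
from sklearn.neighbors import NearestNeighbors


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    return float(normalized_mutual_info_score(labels_a, labels_b,
                                              average_method="arithmetic"))


def auc_loading_recovery(W_est: np.ndarray, truth: np.ndarray) -> float:
    """Mean AUC of estimated loadings against binary block truth.

    Factor order in an NMF is arbitrary, so estimated factors are first
    matched to truth columns by a Hungarian assignment maximizing the
    summed AUC; the mean AUC over matched factors is returned. Truth
    columns that are all-ones or all-zeros are skipped with a warning.
    """
    W_est = np.asarray(W_est, dtype=float)
    truth = np.asarray(truth)
    valid = [k for k in range(truth.shape[1])
             if 0 < truth[:, k].sum() < truth.shape[0]]
    if len(valid) < truth.shape[1]:
        warnings.warn("skipping degenerate truth factors (all-ones or all-zeros)")
    if not valid:
        raise ValueError("no informative truth factors")
    aucs = np.zeros((W_est.shape[1], len(valid)))
    for i in range(W_est.shape[1]):
        for j, k in enumerate(valid):
            aucs[i, j] = roc_auc_score(truth[:, k], W_est[:, i])
    rows, cols = linear_sum_assignment(-aucs)
    return float(aucs[rows, cols].mean())


def entropy_batch_mixing(coords: np.ndarray, batch, k: int | None = None,
                         n_boot: int = 100, seed: int | None = 0) -> float:
    """Average local batch entropy in k-NN neighborhoods of bootstrapped
    query cells; higher means better mixing of the two batches.

    By default the neighborhood size is 100, capped at a tenth of the
    number of cells; an explicit ``k`` must be smaller than n.
    """
    coords = np.asarray(coords, dtype=float)
    batch = np.asarray(batch)
    n = coords.shape[0]
    groups = np.unique(batch)
    if len(groups) < 2:
        raise ValueError("need two nonempty batches")
    if k is None:
        k = min(100, max(1, n // 10))
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    queries = rng.integers(0, n, size=n_boot)
    _, idx = nn.kneighbors(coords[queries])
    ent = 0.0
    for row in idx:
        props = np.array([(batch[row] == g).mean() for g in groups])
        props = props[props > 0]
        ent += float(-(props * np.log(props)).sum())
    return ent / n_boot


def silhouette_coefficient(coords: np.ndarray, labels) -> float:
    """Mean silhouette over cells (Euclidean distance)."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least two groups")
    if (counts == 1).any():
        warnings.warn("singleton groups present; their cells score 0")
    return float(silhouette_score(np.asarray(coords, dtype=float), labels))


def false_positive_da_rate(calls_agg, calls_bulk) -> float:
    """Percentage of aggregated-data differential calls absent from the
    bulk-signal calls: ``100 * |agg \\ bulk| / |agg|`` (0 when no calls)."""
    calls_agg, calls_bulk = set(calls_agg), set(calls_bulk)
    if not calls_agg:
        return 0.0
    return 100.0 * len(calls_agg - calls_bulk) / len(calls_agg)
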