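"""Normalization, binarization and informative-feature selection.

Expression is normalized by median-library-size scaling followed by
``log(1 + x)``; the epigenome is reduced to presence/absence calls.
Informative genes are picked either by dispersion (bin-normalized Fano
factor) or, when cell groups are known, by a one-vs-rest rank-sum screen.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from ._utils import as_array, check_nonnegative, locus_midpoint
from .io import GenomicAnnotation


def normalize_expression(counts, cell_ids=None) -> np.ndarray:
    """Scale every cell to the median total count, then ``log1p``.

    Zero entries stay zero and the output is nonnegative, so the
    transform is safe upstream of the nonnegative factorization.

    Raises
    ------
    ValueError
        If a cell has zero total count (names the offending cell).
    """
    X = as_array(counts)
    check_nonnegative(X, "counts")
    totals = X.sum(axis=0)
    if np.any(totals == 0):
        j = int(np.argmax(totals == 0))
        name = cell_ids[j] if cell_ids is not None else f"column {j}"
        raise ValueError(f"cell {name} has zero total count")
    target = np.median(totals)
    return np.log1p(X * (target / totals))


def binarize_atac(counts):
    """Presence/absence calls: 1 where the input is positive, else 0.

    Idempotent and sparsity-preserving; sparse inputs stay sparse.
    """
    check_nonnegative(counts, "counts")
    if sp.issparse(counts):
        out = counts.tocsr(copy=True)
        out.data = (out.data > 0).astype(float)
        out.eliminate_zeros()
        return out
    return (np.asarray(counts) > 0).astype(float)


def select_genes_fano(X1, gene_ids=None, n_bins: int = 20,
                      fano_z_threshold: float = 0.5,
                      min_mean: float = 0.01) -> list:
    """Dispersion-based informative-gene selection.

    Genes are binned into ``n_bins`` evenly sized groups by mean
    expression; the Fano factor (variance/mean) is z-scored within each
    bin, and genes with normalized Fano factor above
    ``fano_z_threshold`` and mean above ``min_mean`` are returned.

    Genes with zero mean are excluded before binning (the Fano factor is
    undefined). With fewer distinct means than ``n_bins`` the bin count
    is reduced accordingly.
    """
    X = as_array(X1)
    p = X.shape[0]
    ids = list(gene_ids) if gene_ids is not None else list(range(p))
    means = X.mean(axis=1)
    variances = X.var(axis=1)
    ok = means > 0
    if not ok.any():
        return []
    fano = np.full(p, np.nan)
    fano[ok] = variances[ok] / means[ok]

    idx = np.flatnonzero(ok)
    n_distinct = len(np.unique(means[idx]))
    bins = min(n_bins, n_distinct)
    # rank-based qcut gives evenly sized bins even with heavy ties
    order = pd.Series(means[idx]).rank(method="first")
    bin_of = pd.qcut(order, q=bins, labels=False, duplicates="drop")

    z = np.full(p, -np.inf)
    for b in np.unique(bin_of):
        members = idx[bin_of == b]
        f = fano[members]
        sd = f.std(ddof=1) if len(f) > 1 else 0.0
        # relative floor so float round-off in near-constant bins is not
        # standardized into spurious z-scores
        if sd > 1e-12 * max(1.0, float(np.abs(f).max())):
            z[members] = (f - f.mean()) / sd
        else:
            z[members] = 0.0
    keep = (z > fano_z_threshold) & (means > min_mean)
    return [ids[i] for i in np.flatnonzero(keep)]


def _rank_sum_screen(X: np.ndarray, in_group: np.ndarray,
                     p_threshold: float, logfc_threshold: float,
                     min_pct: float):
    """One-vs-rest rank-sum screen for one group; returns a boolean mask."""
    Xa, Xb = X[:, in_group], X[:, ~in_group]
    const = X.ptp(axis=1) == 0 if hasattr(X, "ptp") else np.ptp(X, axis=1) == 0
    pvals = np.ones(X.shape[0])
    if (~const).any():
        res = mannwhitneyu(Xa[~const], Xb[~const], axis=1, method="asymptotic")
        pvals[~const] = res.pvalue
    logfc = np.log((Xa.mean(axis=1) + 1) / (Xb.mean(axis=1) + 1))
    pct = (Xa > 0).mean(axis=1)
    return (pvals < p_threshold) & (logfc > logfc_threshold) & (pct > min_pct), pvals, logfc, pct


def select_features_by_group_test(X, labels, feature_ids=None,
                                  p_threshold: float = 0.05,
                                  logfc_threshold: float = 0.25,
                                  min_pct: float = 0.25) -> list:
    """Union over groups of features passing the one-vs-rest screen.

    For each group, a feature qualifies when the Wilcoxon rank-sum
    p-value is below ``p_threshold``, the log fold-change (pseudo-count
    1) exceeds ``logfc_threshold``, and it is detected in more than
    ``min_pct`` of the group's cells.
    """
    X = as_array(X)
    labels = np.asarray(labels)
    ids = list(feature_ids) if feature_ids is not None else list(range(X.shape[0]))
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    selected = np.zeros(X.shape[0], dtype=bool)
    for g in groups:
        in_group = labels == g
        if in_group.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
        mask, *_ = _rank_sum_screen(X, in_group, p_threshold, logfc_threshold, min_pct)
        selected |= mask
    return [ids[i] for i in np.flatnonzero(selected)]


def filter_loci_near_genes(locus_ids, annotation: GenomicAnnotation,
                           genes, window: int = 50_000) -> list:
    """Keep loci whose interval midpoint lies within ``window`` bp of the
    TSS of any of the given genes (same chromosome, boundary inclusive)."""
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        chrom, tss, _ = annotation.tss(g)
        tss_by_chrom.setdefault(chrom, []).append(tss)
    for chrom in tss_by_chrom:
        tss_by_chrom[chrom] = np.asarray(sorted(tss_by_chrom[chrom]))
    kept = []
    for lid in locus_ids:
        chrom, mid = locus_midpoint(str(lid))
        sites = tss_by_chrom.get(chrom)
        if sites is None:
            continue
        j = np.searchsorted(sites, mid)
        near = []
        if j < len(sites):
            near.append(abs(sites[j] - mid))
        if j > 0:
            near.append(abs(mid - sites[j - 1]))
        if near and min(near) <= window:
            kept.append(lid)
    return kept
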