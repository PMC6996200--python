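"""Synthetic paired scRNA-seq / scATAC-seq generator with ground truth.

A parametric block model stands in for real co-assays: cells belong to
planted clusters (or move along a latent trajectory), each cluster
elevates a dedicated block of genes and of loci, RNA counts are drawn
from a negative binomial on the block means, chromatin accessibility is
drawn Bernoulli from a logistic open-probability, and dropout is applied
until a requested sparsity is reached. The dense pre-dropout,
pre-binarization accessibility signal ("bulk" signal) is retained so
that downstream analyses of the aggregated single-cell data can be
checked against a noise-free reference.

Eight scenarios cover the study conditions: sparsity and noise dials,
clusters invisible in one modality, purely discrete states, a continuous
trajectory, and imbalanced cluster sizes with or without a modality-
missing cluster.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import PairedOmics

SCENARIOS = ("sparsity", "noise", "missing_cluster_atac", "missing_cluster_rna",
             "discrete", "trajectory", "imbalanced", "imbalanced_missing")

#: cluster weights used by the imbalanced scenarios when none are given
IMBALANCED_WEIGHTS = (0.4, 0.3, 0.15, 0.1, 0.05)


@dataclass
class SyntheticTruth:
    """Ground truth for a generated scenario.

    ``labels`` holds integer cluster assignments (or latent pseudotime in
    [0, 1] for the trajectory scenario); ``gene_blocks`` / ``locus_blocks``
    are binary feature × cluster membership matrices; ``bulk_atac`` is the
    dense accessibility signal before dropout and binarization.
    """

    scenario: str
    labels: np.ndarray
    gene_blocks: np.ndarray
    locus_blocks: np.ndarray
    bulk_atac: np.ndarray
    rna_sparsity: float
    atac_sparsity: float
    seed: int | None

    @property
    def cluster_labels(self) -> np.ndarray:
        """Integer labels; the trajectory pseudotime is binned into anchors."""
        if self.scenario == "trajectory":
            k = self.gene_blocks.shape[1]
            return np.minimum((self.labels * k).astype(int), k - 1)
        return self.labels.astype(int)


def apply_dropout(matrix: np.ndarray, target_sparsity: float,
                  seed: int | None = None) -> np.ndarray:
    """Zero entries until the matrix reaches ``target_sparsity`` zeros.

    The retention probability is logistic in the log-signal, so strong
    entries survive preferentially (mimicking magnitude-dependent
    dropout); the logistic offset is calibrated by bisection so the
    expected zero fraction matches the target within ±0.02.
    """
    if not 0 <= target_sparsity < 1:
        raise ValueError("target_sparsity must lie in [0, 1)")
    X = np.asarray(matrix, dtype=float)
    nz = X > 0
    current = 1.0 - nz.mean()
    if target_sparsity <= current + 1e-12:
        if target_sparsity < current - 1e-12:
            warnings.warn(f"target sparsity {target_sparsity:.3f} below current "
                          f"zero fraction {current:.3f}; matrix unchanged")
        return X.copy()
    logx = np.log(X[nz])
    total = X.size

    def expected_sparsity(b: float) -> float:
        keep = 1.0 / (1.0 + np.exp(-(logx - b)))
        return ((~nz).sum() + (1 - keep).sum()) / total

    lo, hi = logx.min() - 20.0, logx.max() + 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected_sparsity(mid) < target_sparsity:
            lo = mid
        else:
            hi = mid
    b = 0.5 * (lo + hi)
    keep_prob = 1.0 / (1.0 + np.exp(-(logx - b)))
    rng = np.random.default_rng(seed)
    kept = rng.random(keep_prob.shape) < keep_prob
    out = X.copy()
    vals = out[nz]
    vals[~kept] = 0.0
    out[nz] = vals
    return out


def _block_logmeans(n_feats: int, n_clusters: int, frac_informative: float,
                    lo: float, hi: float, baseline_sd: float, rng
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Feature × cluster log-mean matrix with one elevated block per cluster.

    Besides the block effect, every feature receives a small per-cluster
    baseline offset (sd ``baseline_sd``), emulating profiles derived from
    real bulk samples, where essentially every feature varies somewhat
    between conditions.
    """
    blocks = np.zeros((n_feats, n_clusters), dtype=int)
    n_inf = int(round(frac_informative * n_feats))
    per = n_inf // n_clusters
    order = rng.permutation(n_feats)
    for k in range(n_clusters):
        blocks[order[k * per:(k + 1) * per], k] = 1
    logmeans = np.full((n_feats, n_clusters), lo)
    logmeans[blocks.astype(bool)] = hi
    logmeans = logmeans + rng.normal(0.0, baseline_sd, logmeans.shape)
    return logmeans, blocks


def _nb_sample(mean: np.ndarray, dispersion: float, rng) -> np.ndarray:
    """Negative binomial via gamma-Poisson; var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam).astype(float)


def generate_paired_dataset(scenario: str = "discrete", n_cells: int = 300,
                            n_genes: int = 500, n_loci: int = 1000,
                            n_clusters: int = 5, rna_sparsity: float = 0.9,
                            atac_sparsity: float = 0.97, noise_sd: float = 0.3,
                            cluster_weights=None, seed: int | None = 0,
                            frac_informative: float = 0.6,
                            cluster_baseline_sd: float = 0.3,
                            ) -> tuple[PairedOmics, SyntheticTruth]:
    """Generate a paired dataset with planted structure and ground truth.

    Cluster-specific blocks of genes and loci carry elevated means;
    Gaussian noise of sd ``noise_sd`` perturbs the log-means; dropout is
    calibrated so the realized zero fractions match ``rna_sparsity`` and
    ``atac_sparsity`` within about two percentage points. The
    ``missing_cluster_*`` scenarios collapse the block means of the last
    two clusters in exactly one modality; the imbalanced scenarios use
    skewed ``cluster_weights``; the trajectory scenario replaces labels
    with a latent time and interpolates block means between five anchors.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if scenario == "trajectory":
        if n_clusters < 1:
            raise ValueError("trajectory scenario needs at least one anchor state")
        n_anchors = max(n_clusters, 2)
    else:
        if n_clusters < 2:
            raise ValueError("need at least two clusters")
        n_anchors = n_clusters
    rng = np.random.default_rng(seed)

    if cluster_weights is None:
        if scenario in ("imbalanced", "imbalanced_missing") and n_anchors == 5:
            cluster_weights = np.asarray(IMBALANCED_WEIGHTS)
        else:
            cluster_weights = np.full(n_anchors, 1.0 / n_anchors)
    cluster_weights = np.asarray(cluster_weights, dtype=float)
    if len(cluster_weights) != n_anchors:
        raise ValueError("cluster_weights length must match the cluster count")
    if not np.isclose(cluster_weights.sum(), 1.0):
        raise ValueError("cluster_weights must sum to 1")

    # per-cluster log-means for RNA and logits for ATAC
    rna_lm, gene_blocks = _block_logmeans(n_genes, n_anchors, frac_informative,
                                          lo=np.log(0.3), hi=np.log(3.0),
                                          baseline_sd=cluster_baseline_sd, rng=rng)
    atac_lg, locus_blocks = _block_logmeans(n_loci, n_anchors, frac_informative,
                                            lo=-4.0, hi=-0.3,
                                            baseline_sd=cluster_baseline_sd, rng=rng)

    if scenario in ("missing_cluster_atac", "imbalanced_missing"):
        # the epigenome cannot tell the last two clusters apart
        atac_lg[:, -1] = atac_lg[:, -2]
        locus_blocks[:, -1] = locus_blocks[:, -2]
    elif scenario == "missing_cluster_rna":
        rna_lm[:, -1] = rna_lm[:, -2]
        gene_blocks[:, -1] = gene_blocks[:, -2]

    if scenario == "trajectory":
        t = np.sort(rng.random(n_cells))
        pos = t * (n_anchors - 1)
        left = np.minimum(pos.astype(int), n_anchors - 2)
        w = pos - left
        cell_rna_lm = (1 - w) * rna_lm[:, left] + w * rna_lm[:, left + 1]
        cell_atac_lg = (1 - w) * atac_lg[:, left] + w * atac_lg[:, left + 1]
        labels = t
    else:
        labels = rng.choice(n_anchors, size=n_cells, p=cluster_weights)
        cell_rna_lm = rna_lm[:, labels]
        cell_atac_lg = atac_lg[:, labels]

    cell_rna_lm = cell_rna_lm + rng.normal(0.0, noise_sd, cell_rna_lm.shape)
    cell_atac_lg = cell_atac_lg + rng.normal(0.0, noise_sd, cell_atac_lg.shape)

    rna_counts = _nb_sample(np.exp(cell_rna_lm), dispersion=0.5, rng=rng)
    open_prob = 1.0 / (1.0 + np.exp(-cell_atac_lg))
    atac_raw = (rng.random(open_prob.shape) < open_prob).astype(float)

    X1 = apply_dropout(rna_counts, rna_sparsity,
                       seed=None if seed is None else seed + 1)
    X2 = apply_dropout(atac_raw, atac_sparsity,
                       seed=None if seed is None else seed + 2)
    X2 = (X2 > 0).astype(float)

    realized_rna = float((X1 == 0).mean())
    realized_atac = float((X2 == 0).mean())
    if abs(realized_rna - rna_sparsity) > 0.02 and realized_rna < rna_sparsity:
        raise ValueError(f"requested RNA sparsity {rna_sparsity} unreachable "
                         f"(realized {realized_rna:.3f})")

    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    locus_ids = [f"chr1:{1_000_000 + 2_000 * i}-{1_000_000 + 2_000 * i + 500}"
                 for i in range(n_loci)]
    cell_ids = [f"cell{j:04d}" for j in range(n_cells)]
    data = PairedOmics(X1=X1, X2=X2, gene_ids=gene_ids,
                       locus_ids=locus_ids, cell_ids=cell_ids)
    truth = SyntheticTruth(scenario=scenario, labels=labels,
                           gene_blocks=gene_blocks, locus_blocks=locus_blocks,
                           bulk_atac=open_prob, rna_sparsity=realized_rna,
                           atac_sparsity=realized_atac, seed=seed)
    return data, truth
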