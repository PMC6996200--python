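"""Factor-specific cis-regulatory link inference and TF assignment.

For each factor-specific marker gene, candidate loci are the factor's
marker loci within 500 kb of the gene's TSS. A perturbation scheme then
separates genuine co-variation from background: the plain Pearson
correlation P1 between expression and accessibility is compared with two
weighted correlations computed after zeroing the signal in the factor's
own cell group (P2 perturbs expression, P3 perturbs accessibility;
weights are the factor's cell loadings). Links are called when the
perturbation moves the correlation by more than the baseline (the mean
P1 across the gene's candidate loci) and P1 itself exceeds the baseline.

Transcription factors are attached to linked genes by nonnegative least
squares of TF expression on the gene's expression within the factor's
cell group, restricted to TFs whose motifs are enriched in the linked
loci; enrichment is accepted as an external input (e.g., from chromVAR),
with a simple hypergeometric hit-count test available as a stand-in.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from scipy.stats import hypergeom

from ._utils import locus_midpoint
from .io import GenomicAnnotation

DEFAULT_WINDOW = 500_000


@dataclass
class RegulatoryLink:
    """A candidate gene-locus link with its perturbation statistics."""

    gene: str
    locus: str
    factor: int
    P1: float
    P2: float
    P3: float
    called: bool

    @property
    def dP1(self) -> float:
        return abs(self.P1 - self.P2)

    @property
    def dP2(self) -> float:
        return abs(self.P1 - self.P3)


@dataclass
class TFLink:
    """A gene-TF link with its nonnegative regression coefficient."""

    gene: str
    tf: str
    beta: float
    factor: int


def candidate_loci(gene: str, annotation: GenomicAnnotation, locus_ids,
                   AL_k, window: int = DEFAULT_WINDOW) -> list:
    """Factor marker loci within ``window`` bp of the gene's TSS.

    ``AL_k`` is the factor's candidate locus set (IDs or indices into
    ``locus_ids``); membership is intersected with the TSS window
    (interval midpoint, same chromosome, boundary inclusive).
    """
    chrom, tss, _ = annotation.tss(gene)
    locus_ids = list(locus_ids)
    al = {locus_ids[i] if isinstance(i, (int, np.integer)) else i for i in AL_k}
    kept = []
    for lid in locus_ids:
        if lid not in al:
            continue
        lchrom, mid = locus_midpoint(str(lid))
        if lchrom == chrom and abs(mid - tss) <= window:
            kept.append(lid)
    return kept


def weighted_pearson(x, y, w) -> float:
    """Pearson correlation with observation weights (normalized to sum 1).

    With uniform weights this reduces exactly to the plain Pearson
    correlation. Returns NaN when either variable has zero weighted
    variance.
    """
    x, y, w = (np.asarray(a, dtype=float) for a in (x, y, w))
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be nonnegative and not all zero")
    w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx, vy = w @ ((x - mx) ** 2), w @ ((y - my) ** 2)
    if vx == 0 or vy == 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


def _plain_pearson(x, y) -> float:
    return weighted_pearson(x, y, np.ones(len(x)))


def perturbation_link_calling(x_g, A, H_k, C1, gene: str = "gene",
                              locus_ids=None, factor: int = 0,
                              baseline: str = "per_gene",
                              global_baseline: float | None = None
                              ) -> list[RegulatoryLink]:
    """Call links between one gene and its candidate loci.

    Parameters
    ----------
    x_g
        Expression of the gene over all n cells.
    A
        Accessibility of the candidate loci (loci × n).
    H_k
        Factor-k cell loadings (the weights for the perturbed correlations).
    C1
        Indices of the factor's cell group (the cells being perturbed).
    baseline
        "per_gene" (default) compares against the mean P1 over this
        gene's candidate loci; "global" uses ``global_baseline``.
    """
    x_g = np.asarray(x_g, dtype=float)
    A = np.atleast_2d(np.asarray(A, dtype=float))
    H_k = np.asarray(H_k, dtype=float)
    n = len(x_g)
    if n < 3:
        raise ValueError("need at least three cells")
    C1 = np.asarray(C1, dtype=int)
    if C1.size == 0:
        raise ValueError("cell group C1 is empty")
    if np.any(H_k < 0) or not H_k.any():
        raise ValueError("weights must be nonnegative and not all zero")
    ids = list(locus_ids) if locus_ids is not None else [f"locus{i}" for i in range(A.shape[0])]

    x_pert = x_g.copy()
    x_pert[C1] = 0.0
    stats = []
    for i in range(A.shape[0]):
        a = A[i]
        if np.ptp(x_g) == 0 or np.ptp(a) == 0:
            warnings.warn(f"zero variance for pair ({gene}, {ids[i]}); skipped")
            continue
        a_pert = a.copy()
        a_pert[C1] = 0.0
        P1 = _plain_pearson(x_g, a)
        P2 = weighted_pearson(x_pert, a, H_k)
        P3 = weighted_pearson(x_g, a_pert, H_k)
        stats.append((ids[i], P1, P2, P3))
    if not stats:
        return []
    if baseline == "per_gene":
        base = float(np.mean([s[1] for s in stats]))
    elif baseline == "global":
        if global_baseline is None:
            raise ValueError("global baseline requested but not provided")
        base = float(global_baseline)
    else:
        raise ValueError("baseline must be 'per_gene' or 'global'")
    links = []
    for lid, P1, P2, P3 in stats:
        dP1 = abs(P1 - P2) if np.isfinite(P2) else 0.0
        dP2 = abs(P1 - P3) if np.isfinite(P3) else 0.0
        called = (dP1 > base or dP2 > base) and P1 > base
        links.append(RegulatoryLink(gene=gene, locus=lid, factor=factor,
                                    P1=P1, P2=float(P2), P3=float(P3),
                                    called=bool(called)))
    return links


def infer_tf_regulators(x_g, TF_expr, tf_ids=None, motif_mask=None,
                        gene: str = "gene", factor: int = 0,
                        orientation: str = "tf_on_gene") -> list[TFLink]:
    """Assign TFs to a linked gene by nonnegative least squares.

    Expression is restricted to the factor's cell group before calling.
    The default orientation regresses each motif-enriched TF's expression
    on the gene's expression (one nonnegative coefficient per TF);
    ``orientation="gene_on_tfs"`` jointly regresses the gene on all TFs
    instead. TFs with coefficient > 0 are returned.
    """
    x_g = np.asarray(x_g, dtype=float)
    TF_expr = np.atleast_2d(np.asarray(TF_expr, dtype=float))
    if x_g.size == 0:
        raise ValueError("no cells in the factor cell group")
    ids = list(tf_ids) if tf_ids is not None else [f"TF{i}" for i in range(TF_expr.shape[0])]
    if motif_mask is None:
        motif_mask = np.ones(TF_expr.shape[0], dtype=bool)
    motif_mask = np.asarray(motif_mask, dtype=bool)
    if not motif_mask.any():
        raise ValueError("motif mask selects no TFs")
    sel = np.flatnonzero(motif_mask)
    links: list[TFLink] = []
    if orientation == "tf_on_gene":
        design = x_g[:, None]
        for i in sel:
            beta, _ = nnls(design, TF_expr[i])
            if beta[0] > 0:
                links.append(TFLink(gene=gene, tf=ids[i], beta=float(beta[0]),
                                    factor=factor))
    elif orientation == "gene_on_tfs":
        beta, _ = nnls(TF_expr[sel].T, x_g)
        for b, i in zip(beta, sel):
            if b > 0:
                links.append(TFLink(gene=gene, tf=ids[i], beta=float(b),
                                    factor=factor))
    else:
        raise ValueError("orientation must be 'tf_on_gene' or 'gene_on_tfs'")
    return links


def motif_hit_enrichment(hits: np.ndarray, linked_loci: np.ndarray,
                         p_threshold: float = 0.05) -> np.ndarray:
    """Hypergeometric stand-in for motif enrichment in a locus set.

    ``hits`` is a binary TF × locus matrix; ``linked_loci`` indexes the
    loci of interest. Returns a boolean TF mask (enrichment p below
    ``p_threshold``).
    """
    hits = np.asarray(hits) > 0
    linked = np.zeros(hits.shape[1], dtype=bool)
    linked[np.asarray(linked_loci, dtype=int)] = True
    N, m = hits.shape[1], int(linked.sum())
    mask = np.zeros(hits.shape[0], dtype=bool)
    for t in range(hits.shape[0]):
        K = int(hits[t].sum())
        k = int((hits[t] & linked).sum())
        if K == 0 or m == 0:
            continue
        mask[t] = hypergeom.sf(k - 1, N, K, m) < p_threshold
    return mask


def validate_tf_links(tf_links, reference, background_tfs) -> dict:
    """Per-gene fold enrichment of predicted TF links in a reference.

    ``tf_links`` is an iterable of :class:`TFLink`; ``reference`` maps a
    gene to its set of known regulator TFs (or is an iterable of
    ``(tf, target)`` pairs, the two-column reference-table format);
    ``background_tfs`` is the set of TFs that could have been predicted.
    Returns ``{gene: fold_enrichment}`` for genes with at least one
    prediction and at least one known regulator in the background.
    """
    if not isinstance(reference, dict):
        ref: dict[str, set] = {}
        for tf, target in reference:
            ref.setdefault(str(target), set()).add(str(tf))
        reference = ref
    background = set(background_tfs)
    predicted: dict[str, set] = {}
    for link in tf_links:
        predicted.setdefault(link.gene, set()).add(link.tf)
    out = {}
    for gene, preds in predicted.items():
        known = reference.get(gene, set()) & background
        if not known:
            continue
        overlap = len(preds & known)
        out[gene] = fold_enrichment(overlap, len(preds), len(known),
                                    len(background))
    return out


def fold_enrichment(k_overlap: int, m_predicted: int, K_known: int,
                    N_background: int) -> float:
    """Fold enrichment ``(k/m) / (K/N)`` of predicted against known links.

    ``k_overlap`` of ``m_predicted`` predictions are known, out of
    ``K_known`` known positives among ``N_background`` candidates; values
    above 1 indicate over-representation.
    """
    if m_predicted <= 0 or K_known <= 0 or N_background <= 0:
        raise ValueError("counts m, K, N must be positive")
    if not 0 <= k_overlap <= min(m_predicted, K_known):
        raise ValueError("overlap must satisfy 0 <= k <= min(m, K)")
    return (k_overlap / m_predicted) / (K_known / N_background)
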