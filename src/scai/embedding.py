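"""VscAI: co-embedding of factors, cells, genes, and loci in one plane.

Factor coordinates come from a Sammon mapping of the cosine distances
between the (similarity-smoothed) rows of the cell loading matrix; cells
and features are then placed as power-weighted barycenters of the factor
coordinates, so every point lies in the convex hull of the factors. The
exponent ``alpha_embed`` (default 1.9) controls how tightly points pull
toward their dominant factor.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity

from ._utils import column_normalize


@dataclass
class EmbeddingLayout:
    """2-D coordinates of factors (C, scaled to [0,1] per axis), cells
    (E raw, Es similarity-smoothed), genes (F1), and loci (F2)."""

    C: np.ndarray
    E: np.ndarray
    Es: np.ndarray
    F1: np.ndarray | None = None
    F2: np.ndarray | None = None
    alpha_embed: float = 1.9
    stress: float = field(default=np.nan)


def _classical_mds(D: np.ndarray, ndim: int = 2) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:ndim]
    pos = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(pos)


def sammon(D: np.ndarray, n_iter: int = 500, tol: float = 1e-9,
           init: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Sammon mapping of a distance matrix to the plane.

    Minimizes the stress ``sum_{i<j} (D_ij - d_ij)^2 / D_ij`` (normalized
    by ``sum D_ij``) by gradient descent with step halving, starting from
    classical MDS. Zero-distance pairs are dropped from the stress with a
    warning. Returns ``(coords, stress)``.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    w = D[iu].copy()
    if np.any(w == 0):
        warnings.warn("identical items (zero distance) dropped from the Sammon stress")
    mask = w > 0
    if not mask.any():
        return (np.zeros((n, 2)) if init is None else init), 0.0
    c = w[mask].sum()
    Y = _classical_mds(D) if init is None else init.copy()

    def stress(Y):
        d = np.sqrt(((Y[iu[0]] - Y[iu[1]]) ** 2).sum(axis=1))
        return float((((w - d) ** 2 / np.maximum(w, 1e-300))[mask]).sum() / c)

    def gradient(Y):
        diff = Y[:, None, :] - Y[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
        np.fill_diagonal(d, 1.0)
        Dm = D.copy()
        np.fill_diagonal(Dm, 1.0)
        valid = (Dm > 0)
        coef = np.where(valid, (d - Dm) / np.maximum(Dm * d, 1e-300), 0.0)
        np.fill_diagonal(coef, 0.0)
        return (2.0 / c) * (coef[:, :, None] * diff).sum(axis=1)

    s = stress(Y)
    step = 1.0
    for _ in range(n_iter):
        g = gradient(Y)
        gnorm = np.linalg.norm(g)
        if gnorm == 0:
            break
        improved = False
        for _ in range(30):  # step halving
            Y_new = Y - step * g
            s_new = stress(Y_new)
            if s_new < s:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        rel = (s - s_new) / max(s, 1e-300)
        Y, s = Y_new, s_new
        step *= 1.2
        if rel < tol:
            break
    return Y, s


def _minmax_scale(C: np.ndarray) -> np.ndarray:
    out = np.empty_like(C)
    for ax in range(C.shape[1]):
        lo, hi = C[:, ax].min(), C[:, ax].max()
        out[:, ax] = 0.5 if hi == lo else (C[:, ax] - lo) / (hi - lo)
    return out


def factor_coordinates(H: np.ndarray, Z: np.ndarray,
                       n_iter: int = 500) -> tuple[np.ndarray, float]:
    """Factor coordinates in [0,1]^2 via cosine distance + Sammon mapping.

    ``H`` is smoothed by the (column-normalized) similarity matrix,
    pairwise cosine similarity ``S`` between factor rows is converted to
    the distance ``D = sqrt(2 (1 - S))``, and the Sammon projection is
    min-max scaled per axis. Returns ``(C, stress)``.
    """
    H = np.asarray(H, dtype=float)
    if H.shape[0] < 2:
        raise ValueError("need at least two factors")
    Hs = H @ column_normalize(np.asarray(Z, dtype=float))
    if np.any(Hs.sum(axis=1) == 0) and np.any((Hs != 0).sum(axis=1) == 0):
        raise ValueError("smoothed H has an all-zero factor row")
    S = cosine_similarity(Hs)
    D = np.sqrt(np.clip(2.0 * (1.0 - S), 0.0, None))
    D[D < 1e-7] = 0.0  # float noise in the cosine of (near-)identical rows
    np.fill_diagonal(D, 0.0)
    Y, stress = sammon(D, n_iter=n_iter)
    return _minmax_scale(Y), stress


def _barycenters(weights: np.ndarray, C: np.ndarray, alpha_embed: float,
                 ids=None, kind: str = "item") -> np.ndarray:
    """Power-weighted barycenters: rows of ``weights`` are K-vectors."""
    if not 1.0 <= alpha_embed <= 2.0:
        warnings.warn(f"alpha_embed={alpha_embed} outside [1, 2] may distort "
                      "the embedding")
    w = np.asarray(weights, dtype=float) ** alpha_embed
    tot = w.sum(axis=1)
    if np.any(tot == 0):
        i = int(np.argmax(tot == 0))
        name = ids[i] if ids is not None else i
        raise ValueError(f"{kind} {name!r} has zero loading on every factor")
    return (w @ C) / tot[:, None]


def embed_cells(H: np.ndarray, Z: np.ndarray, C: np.ndarray,
                alpha_embed: float = 1.9) -> tuple[np.ndarray, np.ndarray]:
    """Cell coordinates ``E`` and their smoothed version ``Es``.

    Each cell is the barycenter of the factor coordinates weighted by its
    loadings raised to ``alpha_embed``; ``Es`` additionally averages each
    cell's position with its similar cells through the column-normalized
    similarity matrix.
    """
    H = np.asarray(H, dtype=float)
    E = _barycenters(H.T, np.asarray(C, dtype=float), alpha_embed, kind="cell")
    Zn = column_normalize(np.asarray(Z, dtype=float))
    Es = (E.T @ Zn).T
    return E, Es


def embed_features(W: np.ndarray, C: np.ndarray, alpha_embed: float = 1.9,
                   feature_ids=None) -> np.ndarray:
    """Feature coordinates from loading rows (genes for W1, loci for W2)."""
    return _barycenters(np.asarray(W, dtype=float), np.asarray(C, dtype=float),
                        alpha_embed, ids=feature_ids, kind="feature")


def vscai_embedding(model, alpha_embed: float = 1.9,
                    gene_subset=None, locus_subset=None) -> EmbeddingLayout:
    """Full VscAI layout from a fitted model.

    ``gene_subset`` / ``locus_subset`` are index arrays selecting which
    features (typically markers) to embed; by default none are embedded.
    """
    C, stress = factor_coordinates(model.H, model.Z)
    E, Es = embed_cells(model.H, model.Z, C, alpha_embed)
    F1 = F2 = None
    if gene_subset is not None:
        F1 = embed_features(model.W1[np.asarray(gene_subset, dtype=int)], C, alpha_embed)
    if locus_subset is not None:
        F2 = embed_features(model.W2[np.asarray(locus_subset, dtype=int)], C, alpha_embed)
    return EmbeddingLayout(C=C, E=E, Es=Es, F1=F1, F2=F2,
                           alpha_embed=alpha_embed, stress=stress)
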