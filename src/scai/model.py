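"""Joint nonnegative matrix factorization of paired omics profiles.

The model couples a gene × cell expression matrix ``X1`` and a locus ×
cell epigenomic matrix ``X2`` through a shared cell loading matrix ``H``
and a learned cell-cell similarity matrix ``Z``:

    min_{W1,W2,H,Z >= 0}  alpha ||X1 - W1 H||_F^2
                        + ||X2 (Z o R) - W2 H||_F^2
                        + lambda ||Z - H^T H||_F^2
                        + gamma sum_j ||H_.j||_1^2

``R`` is a fixed binary mask drawn Bernoulli(s) that subsamples the
similarity matrix so that aggregation does not erase within-cluster
heterogeneity, and ``Z o R`` is column-normalized wherever it multiplies
``X2``, so each aggregated profile is a convex combination of similar
cells' profiles and the epigenomic term keeps a fixed leverage relative
to the expression term. The objective is minimized by four
multiplicative update rules (one per factor matrix) applied in
sequence.

Normalization conventions: the optimizer iterates the update rules on
raw matrices, which keeps the objective trace non-increasing in
practice; after every step the reported ``H`` is rescaled so each row
sums to one, with the row scales absorbed into the columns of ``W1``
and ``W2`` — a reparameterization that leaves ``W1 H`` and ``W2 H``
unchanged. Initialization draws every matrix uniformly on (0, 1) and
then brings ``H`` and ``Z`` to the scale these conventions imply
(row-stochastic ``H``; ``Z`` at the magnitude of within-cluster
``H^T H`` entries, K/n), so that the data-fit terms and the similarity
penalty compete at the intended relative weights from the first
iteration.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from ._utils import EPS, check_nonnegative, column_normalize

DEFAULT_S = 0.25
DEFAULT_ALPHA = 1.0
DEFAULT_LAMBDA = 10_000.0
DEFAULT_GAMMA = 1.0


@dataclass
class FactorModel:
    """The learned low-rank representation.

    ``W1`` (p × K gene loadings), ``W2`` (q × K locus loadings), ``H``
    (K × n cell loadings, rows summing to one after each iteration),
    ``Z`` (n × n cell-cell similarity) and the fixed binary mask ``R``,
    plus the hyperparameters and the per-iteration objective trace.
    """

    W1: np.ndarray
    W2: np.ndarray
    H: np.ndarray
    Z: np.ndarray
    R: np.ndarray
    K: int
    alpha: float = DEFAULT_ALPHA
    lam: float = DEFAULT_LAMBDA
    gamma: float = DEFAULT_GAMMA
    s: float = DEFAULT_S
    seed: int | None = None
    objective_trace: list = field(default_factory=list)
    converged: bool | None = None
    n_iter: int = 0
    # Raw (unrescaled) optimizer iterates; identical to the public
    # matrices at initialization and related to them by a per-factor
    # rescaling afterwards.
    raw_W1: np.ndarray | None = field(default=None, repr=False)
    raw_W2: np.ndarray | None = field(default=None, repr=False)
    raw_H: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.raw_W1 is None:
            self.raw_W1, self.raw_W2, self.raw_H = self.W1, self.W2, self.H

    @property
    def e(self) -> np.ndarray:
        """Length-K all-ones vector appearing in the H update."""
        return np.ones(self.K)

    @property
    def ZR_normalized(self) -> np.ndarray:
        """Column-normalized ``Z o R`` (the aggregation weights)."""
        return column_normalize(self.Z * self.R)

    def save(self, outdir) -> None:
        """Serialize the factor matrices and hyperparameters to a directory."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("W1", "W2", "H", "Z", "R"):
            np.savetxt(outdir / f"{name}.tsv", getattr(self, name), delimiter="\t")
        meta = {"K": self.K, "alpha": self.alpha, "lambda": self.lam,
                "gamma": self.gamma, "s": self.s, "seed": self.seed,
                "converged": self.converged, "n_iter": self.n_iter,
                "objective_trace": [float(v) for v in self.objective_trace]}
        (outdir / "model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, indir) -> "FactorModel":
        import json
        from pathlib import Path

        indir = Path(indir)
        mats = {name: np.loadtxt(indir / f"{name}.tsv", delimiter="\t", ndmin=2)
                for name in ("W1", "W2", "H", "Z", "R")}
        meta = json.loads((indir / "model.json").read_text())
        return cls(W1=mats["W1"], W2=mats["W2"], H=mats["H"], Z=mats["Z"],
                   R=mats["R"], K=int(meta["K"]), alpha=meta["alpha"],
                   lam=meta["lambda"], gamma=meta["gamma"], s=meta["s"],
                   seed=meta["seed"], converged=meta.get("converged"),
                   n_iter=int(meta.get("n_iter", 0)),
                   objective_trace=list(meta.get("objective_trace", [])))


def _validate_pair(X1, X2) -> tuple[int, int, int]:
    p, n = X1.shape
    q, n2 = X2.shape
    if n != n2:
        raise ValueError(f"X1 has {n} cells but X2 has {n2}")
    check_nonnegative(X1, "X1")
    check_nonnegative(X2, "X2")
    return p, q, n


def initialize_model(X1, X2, K: int, alpha: float = DEFAULT_ALPHA,
                     lam: float = DEFAULT_LAMBDA, gamma: float = DEFAULT_GAMMA,
                     s: float = DEFAULT_S, seed: int | None = None,
                     scale_init: bool = True) -> FactorModel:
    """Draw W1, W2, H, Z i.i.d. Uniform(0,1) and R i.i.d. Bernoulli(s).

    With ``scale_init`` (the default) the uniform draws of ``H`` and
    ``Z`` are brought to the model's working scale: rows of ``H`` are
    normalized to sum to one and ``Z`` is multiplied by K/n, the
    magnitude of within-cluster entries of ``H^T H`` for row-stochastic
    ``H``. At the raw uniform scale the similarity penalty (weight
    lambda) swamps the data-fit terms and the factorization converges to
    a structureless solution.
    """
    p, q, n = _validate_pair(X1, X2)
    if K < 1 or K > min(p, q, n):
        raise ValueError(f"rank K={K} must be in [1, min(p, q, n)={min(p, q, n)}]")
    if not 0 <= s <= 1:
        raise ValueError(f"mask probability s={s} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    W1 = rng.random((p, K))
    W2 = rng.random((q, K))
    H = rng.random((K, n))
    Z = rng.random((n, n))
    R = (rng.random((n, n)) < s).astype(float)
    if scale_init:
        H = H / H.sum(axis=1)[:, None]
        Z = Z * (K / n)
    return FactorModel(W1=W1, W2=W2, H=H, Z=Z, R=R, K=K,
                       alpha=alpha, lam=lam, gamma=gamma, s=s, seed=seed)


def objective(model: FactorModel, X1, X2, use_raw: bool = True):
    """Evaluate the four objective terms; returns ``(total, terms)``.

    ``Z o R`` is column-normalized in the second (aggregation) term,
    matching the convention used inside the updates. By default the raw
    optimizer iterates are used, which is the parameterization the
    multiplicative updates descend on.
    """
    if use_raw and model.raw_H is not None:
        W1, W2, H = model.raw_W1, model.raw_W2, model.raw_H
    else:
        W1, W2, H = model.W1, model.W2, model.H
    Z = model.Z
    for name, M in (("W1", W1), ("W2", W2), ("H", H), ("Z", Z)):
        if not np.all(np.isfinite(M)):
            raise ValueError(f"{name} contains NaN or Inf")
    A = X2 @ column_normalize(Z * model.R)
    t1 = model.alpha * float(np.linalg.norm(_dense(X1) - W1 @ H) ** 2)
    t2 = float(np.linalg.norm(A - W2 @ H) ** 2)
    t3 = model.lam * float(np.linalg.norm(Z - H.T @ H) ** 2)
    t4 = model.gamma * float(np.sum(H.sum(axis=0) ** 2))
    terms = {"expression": t1, "epigenome": t2, "similarity": t3, "sparsity": t4}
    return t1 + t2 + t3 + t4, terms


def _dense(X):
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)


def _update_once(X1, X2, W1, W2, H, Z, R, alpha, lam, gamma):
    """One sweep of the four multiplicative rules (raw parameterization)."""
    A = X2 @ column_normalize(Z * R)  # aggregated epigenome, q x n
    W1 = W1 * (X1 @ H.T) / np.maximum(W1 @ (H @ H.T), EPS)
    W2 = W2 * (A @ H.T) / np.maximum(W2 @ (H @ H.T), EPS)
    K = H.shape[0]
    num = alpha * (W1.T @ X1) + W2.T @ A + lam * (H @ (Z + Z.T))
    den = (alpha * (W1.T @ W1) + W2.T @ W2 + 2 * lam * (H @ H.T)
           + gamma * np.ones((K, K))) @ H
    H = H * num / np.maximum(den, EPS)
    num = np.asarray(X2.T @ (W2 @ H)) * R + lam * (H.T @ H)
    den = np.asarray(X2.T @ (X2 @ column_normalize(Z * R))) * R + lam * Z
    Z = Z * num / np.maximum(den, EPS)
    return W1, W2, H, Z


def _rescaled_views(W1, W2, H):
    """Row-stochastic H with the row scales absorbed into W columns."""
    rs = H.sum(axis=1)
    if np.any(rs <= 0):
        raise ValueError("degenerate all-zero factor: a row of H vanished")
    return W1 * rs, W2 * rs, H / rs[:, None]


def multiplicative_step(model: FactorModel, X1, X2) -> FactorModel:
    """Apply the four update rules once and refresh the normalized views.

    The rules are applied in the order W1, W2, H, Z on the raw iterates;
    the returned model exposes the row-stochastic ``H`` (scales absorbed
    into ``W1``/``W2``) and records the objective value.
    """
    X1 = X1 if sp.issparse(X1) else np.asarray(X1, dtype=float)
    rw1, rw2, rh, Z = _update_once(X1, X2, model.raw_W1, model.raw_W2,
                                   model.raw_H, model.Z, model.R,
                                   model.alpha, model.lam, model.gamma)
    W1, W2, H = _rescaled_views(rw1, rw2, rh)
    new = FactorModel(W1=W1, W2=W2, H=H, Z=Z, R=model.R, K=model.K,
                      alpha=model.alpha, lam=model.lam, gamma=model.gamma,
                      s=model.s, seed=model.seed,
                      objective_trace=list(model.objective_trace),
                      n_iter=model.n_iter + 1,
                      raw_W1=rw1, raw_W2=rw2, raw_H=rh)
    total, _ = objective(new, X1, X2)
    new.objective_trace.append(total)
    return new


def fit_scai(X1, X2, K: int, alpha: float = DEFAULT_ALPHA,
             lam: float = DEFAULT_LAMBDA, gamma: float = DEFAULT_GAMMA,
             s: float = DEFAULT_S, seed: int | None = None,
             max_iter: int = 500, tol: float = 1e-6,
             resample_R: bool = False) -> FactorModel:
    """Fit the joint factorization by iterating the multiplicative updates.

    Stops when the relative objective change drops below ``tol`` or after
    ``max_iter`` iterations (a warning is issued in the latter case).
    ``R`` is sampled once at initialization and held fixed unless
    ``resample_R`` is set.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    model = initialize_model(X1, X2, K, alpha, lam, gamma, s, seed)
    X1 = X1 if sp.issparse(X1) else np.asarray(X1, dtype=float)
    W1, W2, H, Z, R = (model.raw_W1, model.raw_W2, model.raw_H,
                       model.Z, model.R)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    trace: list[float] = []
    prev = np.inf
    rel = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if resample_R and it > 1:
            R = (rng.random(R.shape) < s).astype(float)
        W1, W2, H, Z = _update_once(X1, X2, W1, W2, H, Z, R, alpha, lam, gamma)
        probe = FactorModel(W1=W1, W2=W2, H=H, Z=Z, R=R, K=K, alpha=alpha,
                            lam=lam, gamma=gamma, s=s, seed=seed)
        total, _ = objective(probe, X1, X2)
        trace.append(total)
        rel = abs(prev - total) / max(prev, EPS) if prev < np.inf else np.inf
        if rel <= tol:
            converged = True
            break
        prev = total
    if not converged:
        warnings.warn(f"fit did not converge in {max_iter} iterations "
                      f"(relative change {rel:.2e})")
    vW1, vW2, vH = _rescaled_views(W1, W2, H)
    return FactorModel(W1=vW1, W2=vW2, H=vH, Z=Z, R=R, K=K, alpha=alpha,
                       lam=lam, gamma=gamma, s=s, seed=seed,
                       objective_trace=trace, converged=converged, n_iter=it,
                       raw_W1=W1, raw_W2=W2, raw_H=H)


def aggregate_epigenome(X2, Z: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Aggregated epigenomic profiles ``X2 @ colnorm(Z o R)``.

    Column ``i`` is a convex combination of the epigenomic profiles of
    cells similar to cell ``i`` (restricted to the cells sampled by the
    mask ``R``), which turns near-binary sparse signals into continuous
    per-cell profiles without manufacturing structure: a constant input
    aggregates to the same constant.
    """
    check_nonnegative(Z, "Z")
    ZR = Z * R
    colsums = ZR.sum(axis=0)
    if np.any(colsums <= 0):
        bad = int(np.argmax(colsums <= 0))
        raise ValueError(f"cell {bad} has no sampled neighbors (all-zero column in Z o R)")
    return np.asarray(X2 @ (ZR / colsums))


def select_rank(X1, X2, K_range, n_seeds: int = 5, seed: int = 0,
                max_iter: int = 100, stability_threshold: float = 0.95,
                **fit_kwargs):
    """Stability-based choice of the rank K.

    For each candidate K the model is fitted with ``n_seeds`` random
    initializations; cells are assigned to their dominant factor, the
    consensus co-clustering matrix across seeds is formed, and its
    cophenetic correlation measures stability. The largest K whose
    cophenetic coefficient stays at or above ``stability_threshold`` is
    returned; if no K is stable, the most stable K is returned (or the
    smallest candidate, with a warning, when stability is uniformly low).
    """
    K_range = sorted(int(k) for k in K_range)
    if len(K_range) < 2:
        raise ValueError("K_range must contain at least two candidate ranks")
    if min(K_range) < 2:
        raise ValueError("candidate ranks must be >= 2")
    if n_seeds < 2:
        raise ValueError("stability is undefined for n_seeds < 2")
    n = X1.shape[1]
    coph = {}
    for K in K_range:
        consensus = np.zeros((n, n))
        for i in range(n_seeds):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # short fits need not converge
                m = fit_scai(X1, X2, K, seed=seed + 1000 * i, max_iter=max_iter,
                             **fit_kwargs)
            labels = np.argmax(m.H, axis=0)
            consensus += labels[:, None] == labels[None, :]
        consensus /= n_seeds
        dist = squareform(1 - consensus, checks=False)
        if dist.max() == 0:  # all seeds agree on a single cluster
            coph[K] = 1.0
            continue
        link = linkage(dist, method="average")
        c, _ = cophenet(link, dist)
        coph[K] = float(c) if np.isfinite(c) else 0.0
    stable = [K for K in K_range if coph[K] >= stability_threshold]
    if stable:
        return max(stable), coph
    best = max(coph, key=coph.get)
    if coph[best] < 0.9:
        warnings.warn("low stability for every candidate rank; returning the "
                      "smallest candidate")
        return min(K_range), coph
    return best, coph
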