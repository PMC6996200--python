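"""Factor- and cluster-level marker discovery.

Per factor, features are ranked by their share of the factor's loading
mass (gene/locus scores); candidate markers and factor cell groups are
gated by a z-score threshold ``T`` and confirmed by a Wilcoxon rank-sum
test with log fold-change and detection-rate filters. Per cluster,
marker genes come from a two-part likelihood-ratio test (detection rate
plus log-expression among detected cells), the standard single-cell LRT
family; differential accessibility uses the rank-sum test on aggregated
profiles.

No multiple-testing correction is applied by default (features are
filtered at raw p < 0.05); Benjamini-Hochberg is available via
``correct="bh"``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, mannwhitneyu

from ._utils import as_array

P_THRESHOLD = 0.05
LOGFC_THRESHOLD = 0.25
MIN_PCT = 0.25
DEFAULT_T = 0.5


def factor_gene_scores(W: np.ndarray) -> np.ndarray:
    """Share of each factor's loading mass per feature.

    ``S[i, k] = W[i, k] / sum_j W[j, k]``; each column sums to one and is
    invariant to positive rescaling of the factor. Works for gene
    loadings (W1) and locus loadings (W2) alike.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("loadings must be nonnegative")
    colsums = W.sum(axis=0)
    if np.any(colsums == 0):
        raise ValueError(f"factor {int(np.argmax(colsums == 0))} has all-zero loadings")
    return W / colsums


def rank_features(W: np.ndarray, feature_ids, k: int) -> pd.DataFrame:
    """Features of factor ``k`` ordered by score (ties broken by ID)."""
    scores = factor_gene_scores(W)[:, k]
    df = pd.DataFrame({"feature": list(feature_ids), "score": scores})
    return df.sort_values(["score", "feature"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)


def _zscores(values: np.ndarray) -> np.ndarray | None:
    sd = values.std(ddof=1)
    if sd == 0:
        return None
    return (values - values.mean()) / sd


def factor_feature_and_cell_groups(W: np.ndarray, H: np.ndarray,
                                   T: float = DEFAULT_T):
    """Candidate features and the two cell groups for every factor.

    Feature z-scores are computed within each column of ``W`` and cell
    z-scores within each row of ``H``; entries with z > T join the
    candidate set (features) or group ``C1`` (cells), the remaining cells
    form ``C2``. A zero-variance column/row yields an empty candidate set
    (warning) or all cells in ``C2``.
    """
    W, H = np.asarray(W, dtype=float), np.asarray(H, dtype=float)
    K = W.shape[1]
    out = []
    for k in range(K):
        zf = _zscores(W[:, k])
        if zf is None:
            warnings.warn(f"factor {k}: zero variance in loadings; no candidates")
            cand = np.array([], dtype=int)
        else:
            cand = np.flatnonzero(zf > T)
        zc = _zscores(H[k])
        if zc is None:
            warnings.warn(f"factor {k}: zero variance in cell loadings")
            c1 = np.array([], dtype=int)
        else:
            c1 = np.flatnonzero(zc > T)
        c2 = np.setdiff1d(np.arange(H.shape[1]), c1)
        out.append({"candidates": cand, "C1": c1, "C2": c2})
    return out


def _wilcoxon_table(X: np.ndarray, in_group: np.ndarray) -> pd.DataFrame:
    """Rank-sum p, log fold-change and detection rate per feature."""
    Xa, Xb = X[:, in_group], X[:, ~in_group]
    pvals = np.ones(X.shape[0])
    # relative floor: float jitter on an (aggregated) constant feature must
    # not be rank-tested into significance
    scale = np.maximum(1.0, np.abs(X).max(axis=1))
    nonconst = np.ptp(X, axis=1) > 1e-10 * scale
    if nonconst.any():
        res = mannwhitneyu(Xa[nonconst], Xb[nonconst], axis=1, method="asymptotic")
        pvals[nonconst] = res.pvalue
    return pd.DataFrame({
        "p": pvals,
        "logfc": np.log((Xa.mean(axis=1) + 1) / (Xb.mean(axis=1) + 1)),
        "pct": (Xa > 0).mean(axis=1),
    })


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


def factor_specific_markers(X, candidates: np.ndarray, C1: np.ndarray,
                            C2: np.ndarray, feature_ids=None,
                            p_threshold: float = P_THRESHOLD,
                            logfc_threshold: float = LOGFC_THRESHOLD,
                            min_pct: float = MIN_PCT,
                            correct: str | None = None) -> pd.DataFrame:
    """Confirm candidate features of one factor against its cell groups.

    Candidates pass when the Wilcoxon rank-sum p-value (C1 vs C2) is
    below ``p_threshold``, the log fold-change of means (pseudo-count 1,
    natural log) exceeds ``logfc_threshold``, and detection in C1 exceeds
    ``min_pct``. An empty candidate set returns an empty table.
    """
    X = as_array(X)
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        return pd.DataFrame(columns=["feature", "p", "logfc", "pct", "marker"])
    if len(C1) == 0 or len(C2) == 0:
        raise ValueError("both cell groups must be nonempty")
    in_group = np.zeros(X.shape[1], dtype=bool)
    in_group[np.asarray(C1, dtype=int)] = True
    tab = _wilcoxon_table(X[candidates], in_group)
    if correct == "bh":
        tab["p"] = _bh(tab["p"].to_numpy())
    ids = list(feature_ids) if feature_ids is not None else list(range(X.shape[0]))
    tab.insert(0, "feature", [ids[i] for i in candidates])
    tab["marker"] = ((tab["p"] < p_threshold) & (tab["logfc"] > logfc_threshold)
                     & (tab["pct"] > min_pct))
    return tab


def _twopart_lrt(x: np.ndarray, in_group: np.ndarray) -> float:
    """Two-part LRT p-value: binomial detection + Gaussian log-expression.

    The detection component compares per-group detection rates under a
    binomial likelihood; the continuous component compares the means of
    log1p expression among detected cells under a pooled-variance
    Gaussian. The combined statistic is chi-square with 2 df.
    """
    det = x > 0
    n1, n2 = in_group.sum(), (~in_group).sum()
    d1, d2 = det[in_group].sum(), det[~in_group].sum()

    def binom_ll(d, n):
        if d == 0 or d == n:
            return 0.0
        p = d / n
        return d * np.log(p) + (n - d) * np.log(1 - p)

    dpooled = d1 + d2
    lr_det = 2 * (binom_ll(d1, n1) + binom_ll(d2, n2) - binom_ll(dpooled, n1 + n2))

    y1 = np.log1p(x[in_group & det])
    y2 = np.log1p(x[~in_group & det])
    lr_cont = 0.0
    if len(y1) >= 1 and len(y2) >= 1 and len(y1) + len(y2) >= 3:
        y = np.concatenate([y1, y2])
        var_pooled = y.var()
        # within-group sum of squares around group means
        ss_within = (((y1 - y1.mean()) ** 2).sum() + ((y2 - y2.mean()) ** 2).sum())
        var_within = ss_within / len(y)
        if var_within > 0 and var_pooled > 0:
            lr_cont = len(y) * (np.log(var_pooled) - np.log(var_within))
        elif var_pooled > 0:  # perfect within-group separation
            lr_cont = len(y) * np.log(var_pooled / 1e-12)
    lr = max(lr_det, 0.0) + max(lr_cont, 0.0)
    return float(chi2.sf(lr, df=2))


def subpop_marker_genes(X1, labels, gene_ids=None, test: str = "lrt",
                        p_threshold: float = P_THRESHOLD,
                        logfc_threshold: float = LOGFC_THRESHOLD,
                        min_pct: float = MIN_PCT,
                        correct: str | None = None) -> dict:
    """Per-cluster one-vs-rest marker genes.

    The default test is the two-part likelihood-ratio test; the same
    three filters as for factor markers apply (p < 0.05, log fold-change
    > 0.25, detection > 25%). ``test="wilcoxon"`` switches to the
    rank-sum test. Returns ``{cluster: DataFrame}``. Size-one clusters
    are skipped with a warning.
    """
    X = as_array(X1)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    ids = list(gene_ids) if gene_ids is not None else list(range(X.shape[0]))
    out = {}
    for c in clusters:
        in_group = labels == c
        if in_group.sum() < 2:
            warnings.warn(f"cluster {c!r} has a single cell; skipped")
            continue
        tab = _wilcoxon_table(X, in_group)
        if test == "lrt":
            tab["p"] = [_twopart_lrt(X[i], in_group) for i in range(X.shape[0])]
        elif test != "wilcoxon":
            raise ValueError("test must be 'lrt' or 'wilcoxon'")
        if correct == "bh":
            tab["p"] = _bh(tab["p"].to_numpy())
        tab.insert(0, "feature", ids)
        tab["marker"] = ((tab["p"] < p_threshold)
                         & (tab["logfc"] > logfc_threshold)
                         & (tab["pct"] > min_pct))
        out[c] = tab
    return out


def differential_accessibility(X2_agg, labels, locus_ids=None,
                               p_threshold: float = P_THRESHOLD,
                               correct: str | None = None) -> dict:
    """Per-cluster one-vs-rest Wilcoxon calls on aggregated accessibility.

    Returns ``{cluster: DataFrame}`` with a boolean ``called`` column
    (p < ``p_threshold``). Constant loci are never called.
    """
    X = as_array(X2_agg)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    ids = list(locus_ids) if locus_ids is not None else list(range(X.shape[0]))
    out = {}
    for c in clusters:
        in_group = labels == c
        if in_group.sum() < 2:
            warnings.warn(f"cluster {c!r} has a single cell; skipped")
            continue
        tab = _wilcoxon_table(X, in_group)
        if correct == "bh":
            tab["p"] = _bh(tab["p"].to_numpy())
        tab.insert(0, "feature", ids)
        tab["called"] = tab["p"] < p_threshold
        out[c] = tab
    return out


@dataclass
class FactorMarkers:
    """Bundle of per-factor marker results for one modality."""

    scores: np.ndarray
    groups: list = field(repr=False)
    tables: list = field(repr=False)

    def markers(self, k: int) -> pd.DataFrame:
        tab = self.tables[k]
        return tab[tab["marker"]].reset_index(drop=True)


def find_factor_markers(X, W: np.ndarray, H: np.ndarray, feature_ids=None,
                        T: float = DEFAULT_T, **kwargs) -> FactorMarkers:
    """Scores + z-gating + statistical confirmation for every factor."""
    groups = factor_feature_and_cell_groups(W, H, T=T)
    scores = factor_gene_scores(W)
    tables = []
    for k, g in enumerate(groups):
        if len(g["C1"]) == 0 or len(g["C2"]) == 0:
            warnings.warn(f"factor {k}: empty cell group; no marker test")
            tables.append(pd.DataFrame(
                columns=["feature", "p", "logfc", "pct", "marker"]))
            continue
        tables.append(factor_specific_markers(X, g["candidates"], g["C1"],
                                              g["C2"], feature_ids=feature_ids,
                                              **kwargs))
    return FactorMarkers(scores=scores, groups=groups, tables=tables)
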