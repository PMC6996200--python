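"""Small shared numerical helpers."""
from __future__ import annotations

import numpy as np
import scipy.sparse as sp

# Floor for multiplicative-update denominators; standard NMF practice.
EPS = 1e-16


def as_array(X) -> np.ndarray:
    """Densify a matrix-like input to a float ndarray."""
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def column_normalize(M: np.ndarray) -> np.ndarray:
    """Scale each column of ``M`` to sum to one.

    Columns summing to zero are left untouched (caller decides whether that
    is an error; see :func:`scai.model.aggregate_epigenome`).
    """
    s = M.sum(axis=0)
    safe = np.where(s > 0, s, 1.0)
    return M / safe


def check_nonnegative(X, name: str) -> None:
    lo = X.min() if not sp.issparse(X) else X.data.min() if X.nnz else 0.0
    if lo < 0:
        raise ValueError(f"{name} must be nonnegative (min entry {lo})")


def parse_locus(locus_id: str) -> tuple[str, int, int]:
    """Parse a peak identifier ``chr:start-end`` (1-based, inclusive).

    Returns ``(chrom, start0, end0)`` in 0-based half-open coordinates.
    """
    try:
        chrom, coords = locus_id.rsplit(":", 1)
        start_s, end_s = coords.split("-")
        start, end = int(start_s.replace(",", "")), int(end_s.replace(",", ""))
        if not chrom or start < 1 or end < start:
            raise ValueError
    except ValueError:
        raise ValueError(f"cannot parse locus ID {locus_id!r} as 'chr:start-end'") from None
    return chrom, start - 1, end


def locus_midpoint(locus_id: str) -> tuple[str, float]:
    """Chromosome and midpoint (1-based bp) of a locus interval."""
    chrom, start0, end0 = parse_locus(locus_id)
    return chrom, (start0 + 1 + end0) / 2.0
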