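"""Containers and readers for paired single-cell omics matrices.

The two central types are :class:`PairedOmics` — a gene × cell expression
matrix and a locus × cell epigenomic matrix measured in the *same* cells —
and :class:`GenomicAnnotation`, a gene → (chromosome, TSS, strand) lookup
used for window queries when linking loci to genes.

Matrices are accepted either as Matrix Market files with row/column ID
sidecar text files, or as dense delimited text with a header row of cell
IDs. Annotations are read from GTF or 6-column BED.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._utils import check_nonnegative, parse_locus


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids)
        dupes = sorted(dupes[dupes.duplicated()].unique())[:5]
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class PairedOmics:
    """Aligned gene × cell and locus × cell matrices from co-assayed cells.

    Attributes
    ----------
    X1
        Nonnegative expression matrix, ``p`` genes × ``n`` cells
        (dense ndarray or scipy sparse).
    X2
        Nonnegative epigenomic matrix, ``q`` loci × ``n`` cells; binary
        after :func:`scai.preprocess.binarize_atac`.
    gene_ids, locus_ids, cell_ids
        Row/row/column identifiers. Locus IDs must parse as
        ``chr:start-end`` intervals (1-based, inclusive).
    """

    X1: np.ndarray | sp.spmatrix
    X2: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    locus_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        p, n1 = self.X1.shape
        q, n2 = self.X2.shape
        if n1 != n2:
            raise ValueError(f"X1 has {n1} cells but X2 has {n2}; the assays must share cells")
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene IDs for {p} rows of X1")
        if len(self.locus_ids) != q:
            raise ValueError(f"{len(self.locus_ids)} locus IDs for {q} rows of X2")
        if len(self.cell_ids) != n1:
            raise ValueError(f"{len(self.cell_ids)} cell IDs for {n1} columns")
        _check_unique(self.gene_ids, "gene IDs")
        _check_unique(self.locus_ids, "locus IDs")
        _check_unique(self.cell_ids, "cell IDs")
        check_nonnegative(self.X1, "X1")
        check_nonnegative(self.X2, "X2")

    @property
    def n_cells(self) -> int:
        return self.X1.shape[1]

    @property
    def n_genes(self) -> int:
        return self.X1.shape[0]

    @property
    def n_loci(self) -> int:
        return self.X2.shape[0]

    def validate_locus_ids(self) -> None:
        """Check every locus ID parses as a genomic interval."""
        for lid in self.locus_ids:
            parse_locus(lid)

    def to_dir(self, outdir: str | Path) -> None:
        """Write both matrices in Matrix Market format with ID sidecars."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(outdir / "rna.mtx", sp.coo_matrix(self.X1))
        scipy.io.mmwrite(outdir / "atac.mtx", sp.coo_matrix(self.X2))
        for name, ids in (("genes", self.gene_ids), ("loci", self.locus_ids),
                          ("cells", self.cell_ids)):
            (outdir / f"{name}.txt").write_text("\n".join(ids) + "\n")

    @classmethod
    def from_dir(cls, indir: str | Path) -> "PairedOmics":
        indir = Path(indir)
        X1 = sp.csr_matrix(scipy.io.mmread(indir / "rna.mtx"))
        X2 = sp.csr_matrix(scipy.io.mmread(indir / "atac.mtx"))
        ids = {}
        for name in ("genes", "loci", "cells"):
            ids[name] = (indir / f"{name}.txt").read_text().splitlines()
        return cls(X1, X2, ids["genes"], ids["loci"], ids["cells"])


def read_matrix(path: str | Path, row_ids: str | Path | None = None,
                col_ids: str | Path | None = None):
    """Read a feature × cell matrix.

    ``.mtx`` files need ``row_ids``/``col_ids`` text files (one ID per
    line); dense CSV/TSV files carry cell IDs in the header row and
    feature IDs in the first column.

    Returns ``(matrix, row_ids, col_ids)``.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        M = sp.csr_matrix(scipy.io.mmread(path))
        if row_ids is None or col_ids is None:
            raise ValueError("Matrix Market input needs row_ids and col_ids files")
        rows = Path(row_ids).read_text().splitlines()
        cols = Path(col_ids).read_text().splitlines()
        return M, rows, cols
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


@dataclass
class GenomicAnnotation:
    """Gene → (chromosome, TSS, strand) lookup.

    The TSS is 1-based; for ``+`` genes it is the annotated start, for
    ``-`` genes the annotated end.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"chrom", "tss", "strand"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        if self.table.index.duplicated().any():
            raise ValueError("one record per gene ID required")
        if (self.table["tss"] < 1).any():
            raise ValueError("TSS positions must be >= 1")

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def tss(self, gene: str) -> tuple[str, int, str]:
        """Return ``(chromosome, tss, strand)`` for ``gene``."""
        try:
            row = self.table.loc[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in annotation") from None
        return str(row["chrom"]), int(row["tss"]), str(row["strand"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomicAnnotation":
        return cls(df[["chrom", "tss", "strand"]].copy())

    @classmethod
    def from_gtf(cls, path: str | Path, id_attr: str = "gene_name") -> "GenomicAnnotation":
        """Build the lookup from GTF ``gene`` records.

        ``id_attr`` selects the attribute used as the gene ID
        (``gene_name``, falling back to ``gene_id``).
        """
        import pyranges as pr

        gr = pr.read_gtf(str(path)).df
        genes = gr[gr["Feature"] == "gene"]
        if genes.empty:  # some GTFs only carry transcript records
            genes = gr[gr["Feature"] == "transcript"]
        if id_attr not in genes.columns or genes[id_attr].isna().all():
            id_attr = "gene_id"
        # pyranges exposes 0-based starts; TSS is strand dependent
        tss = np.where(genes["Strand"] == "-", genes["End"], genes["Start"] + 1)
        df = pd.DataFrame({
            "chrom": genes["Chromosome"].astype(str).to_numpy(),
            "tss": tss.astype(int),
            "strand": genes["Strand"].astype(str).to_numpy(),
        }, index=genes[id_attr].astype(str).to_numpy())
        dup = df.index.duplicated()
        if dup.any():
            warnings.warn(f"{dup.sum()} duplicate gene records in GTF; keeping the first")
            df = df[~dup]
        return cls(df)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GenomicAnnotation":
        """Build the lookup from a 6-column BED file (name = gene ID)."""
        import pyranges as pr

        bed = pr.read_bed(str(path)).df
        if "Strand" not in bed.columns or "Name" not in bed.columns:
            raise ValueError("6-column BED (chrom start end name score strand) required")
        tss = np.where(bed["Strand"] == "-", bed["End"], bed["Start"] + 1)
        df = pd.DataFrame({
            "chrom": bed["Chromosome"].astype(str).to_numpy(),
            "tss": tss.astype(int),
            "strand": bed["Strand"].astype(str).to_numpy(),
        }, index=bed["Name"].astype(str).to_numpy())
        return cls(df)
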