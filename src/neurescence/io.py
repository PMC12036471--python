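"""On-disk formats and the shared in-memory data model.

The canonical in-memory orientation is cells x genes. Matrix-Market files
written by this package are genes x cells (the common 10x convention) with
a header comment declaring the orientation; readers accept either
orientation when it is declared in the file or passed explicitly.

Formats handled here:

* sparse counts: Matrix-Market coordinate file + ``genes.tsv`` + ``barcodes.tsv``
* dense counts: TSV/CSV with a header row of gene symbols and cell ids in
  the first column
* cell metadata: TSV with columns ``cell_id``, ``cell_type`` (optional
  ``dataset``)
* gene panels: plain text, one symbol per line
* gene-set collections: GMT (set name, description, member genes)
* results: TSV tables with a JSON run-metadata sidecar
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "GenePanel",
    "GeneSetCollection",
    "FormatError",
    "read_counts",
    "write_counts",
    "read_counts_dense",
    "read_cell_meta",
    "write_cell_meta",
    "read_panel",
    "write_panel",
    "read_gmt",
    "write_gmt",
    "write_table",
    "write_run_metadata",
]

ORIENTATION_COMMENT = "%orientation:"


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


def _check_unique(values, what: str, path=None) -> None:
    values = np.asarray(values, dtype=object)
    uniq, counts = np.unique(values, return_counts=True)
    dup = uniq[counts > 1]
    if dup.size:
        where = f" in {path}" if path else ""
        raise FormatError(f"duplicate {what}{where}: {list(dup[:5])!r}")


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, cells x genes.

    ``cells`` and ``genes`` are ordered identifier arrays; ``X`` is a CSR
    matrix of shape ``(len(cells), len(genes))``.
    """

    cells: np.ndarray
    genes: np.ndarray
    X: sp.csr_matrix

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=object)
        self.genes = np.asarray(self.genes, dtype=object)
        if not sp.issparse(self.X):
            self.X = sp.csr_matrix(np.asarray(self.X))
        self.X = self.X.tocsr()
        if self.X.shape != (len(self.cells), len(self.genes)):
            raise FormatError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        _check_unique(self.cells, "cell identifiers")
        _check_unique(self.genes, "gene symbols")
        data = self.X.data
        if data.size:
            if np.issubdtype(data.dtype, np.floating):
                if not np.all(data == np.round(data)):
                    raise FormatError("counts must be integers")
                self.X = self.X.astype(np.int64)
            if self.X.data.size and self.X.data.min() < 0:
                raise FormatError("counts must be non-negative")
        self.X = self.X.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def gene_index(self, symbols) -> np.ndarray:
        """Positions of *symbols* in the gene axis (error on missing)."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [s for s in symbols if s not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]!r}")
        return np.array([lookup[s] for s in symbols], dtype=int)

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.cells[idx], self.genes.copy(), self.X[idx])

    def subset_genes(self, symbols) -> "CountMatrix":
        idx = self.gene_index(symbols)
        return CountMatrix(self.cells.copy(), self.genes[idx], self.X[:, idx])

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())


@dataclass
class ExpressionMatrix:
    """Real-valued expression (e.g. log2(CPM+1)), cells x genes, sparse."""

    cells: np.ndarray
    genes: np.ndarray
    X: sp.csr_matrix

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=object)
        self.genes = np.asarray(self.genes, dtype=object)
        if not sp.issparse(self.X):
            self.X = sp.csr_matrix(np.asarray(self.X, dtype=float))
        self.X = self.X.tocsr().astype(np.float64)
        if self.X.shape != (len(self.cells), len(self.genes)):
            raise FormatError("expression shape does not match labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    gene_index = CountMatrix.gene_index

    def dense_genes(self, symbols) -> np.ndarray:
        """Dense cells x len(symbols) block for a small gene subset."""
        idx = self.gene_index(symbols)
        return np.asarray(self.X[:, idx].todense())


@dataclass
class GenePanel:
    """A named ordered gene list (e.g. CSP, SIP, SenMayo)."""

    name: str
    genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene panel {self.name!r} is empty")
        seen, out = set(), []
        for g in self.genes:
            if g in seen:
                logger.warning("panel %s: dropping duplicate symbol %s", self.name, g)
                continue
            seen.add(g)
            out.append(g)
        self.genes = out

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (a parsed GMT file)."""

    sets: dict = field(default_factory=dict)  # name -> list of genes
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# counts


def _read_labels(path) -> np.ndarray:
    lines = [ln.strip().split("\t")[0] for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise FormatError(f"empty label file: {path}")
    return np.asarray(lines, dtype=object)


def _detect_orientation(matrix_path) -> str | None:
    with open(matrix_path) as fh:
        for line in fh:
            if not line.startswith("%"):
                break
            if ORIENTATION_COMMENT in line:
                return line.split(ORIENTATION_COMMENT, 1)[1].strip()
    return None


def read_counts(
    matrix_path,
    genes_path,
    cells_path,
    orientation: str | None = None,
) -> CountMatrix:
    """Read a Matrix-Market triplet file plus gene/cell label files.

    The on-disk orientation must be declared either by a header comment
    ``%orientation: genes-by-cells`` (or ``cells-by-genes``) inside the
    matrix file or through the *orientation* argument. The returned matrix
    is always cells x genes.
    """
    orientation = orientation or _detect_orientation(matrix_path)
    if orientation not in ("genes-by-cells", "cells-by-genes"):
        raise FormatError(
            f"{matrix_path}: orientation not declared; pass orientation="
            "'genes-by-cells' or 'cells-by-genes' or add a header comment"
        )
    try:
        M = scipy.io.mmread(matrix_path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{matrix_path}: not a valid Matrix-Market file: {exc}") from exc
    M = sp.coo_matrix(M)
    if M.data.size and (np.any(M.data < 0) or not np.all(M.data == np.round(M.data))):
        raise FormatError(f"{matrix_path}: counts must be non-negative integers")
    genes = _read_labels(genes_path)
    cells = _read_labels(cells_path)
    if orientation == "genes-by-cells":
        M = M.T
    if M.shape != (len(cells), len(genes)):
        raise FormatError(
            f"{matrix_path}: matrix is {M.shape} but label files give "
            f"{len(cells)} cells ({cells_path}) x {len(genes)} genes ({genes_path})"
        )
    genes, cells, M = _dedup_axes(genes, cells, M.tocsr())
    return CountMatrix(cells, genes, M)


def _dedup_axes(genes, cells, X):
    """Keep the first occurrence of duplicate symbols, with a warning."""
    _, first = np.unique(cells, return_index=True)
    if len(first) < len(cells):
        logger.warning("dropping %d duplicate cell ids", len(cells) - len(first))
        keep = np.sort(first)
        cells, X = cells[keep], X[keep]
    _, first = np.unique(genes, return_index=True)
    if len(first) < len(genes):
        logger.warning("dropping %d duplicate gene symbols", len(genes) - len(first))
        keep = np.sort(first)
        genes, X = genes[keep], X[:, keep]
    return genes, cells, X


def write_counts(cm: CountMatrix, directory) -> dict:
    """Write matrix.mtx (genes x cells, with orientation comment),
    genes.tsv and barcodes.tsv into *directory*; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mtx = directory / "matrix.mtx"
    scipy.io.mmwrite(
        mtx,
        sp.coo_matrix(cm.X.T),
        comment="orientation: genes-by-cells",
        field="integer",
    )
    (directory / "genes.tsv").write_text("\n".join(map(str, cm.genes)) + "\n")
    (directory / "barcodes.tsv").write_text("\n".join(map(str, cm.cells)) + "\n")
    return {
        "matrix": mtx,
        "genes": directory / "genes.tsv",
        "cells": directory / "barcodes.tsv",
    }


def read_counts_dense(path, orientation: str = "cells-by-genes") -> CountMatrix:
    """Dense TSV/CSV fallback: header row = genes, first column = cell ids."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "genes-by-cells":
        df = df.T
    X = df.to_numpy()
    if np.any(X < 0) or not np.allclose(X, np.round(X)):
        raise FormatError(f"{path}: counts must be non-negative integers")
    return CountMatrix(
        np.asarray(df.index, dtype=object),
        np.asarray(df.columns, dtype=object),
        sp.csr_matrix(X.astype(np.int64)),
    )


# ---------------------------------------------------------------------------
# cell metadata


def read_cell_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_id", "cell_type"):
        if col not in meta.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if meta["cell_type"].isna().any() or (meta["cell_type"] == "").any():
        raise FormatError(f"{path}: empty cell_type values")
    _check_unique(meta["cell_id"].to_numpy(), "cell ids", path)
    return meta


def write_cell_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# panels and gene-set collections


def read_panel(path, name: str | None = None, uppercase: bool = False) -> GenePanel:
    """One gene symbol per line; blank lines and duplicates are dropped."""
    lines = Path(path).read_text().splitlines()
    genes = [ln.strip() for ln in lines]
    genes = [g.upper() if uppercase else g for g in genes if g]
    if not genes:
        raise FormatError(f"empty gene panel: {path}")
    return GenePanel(name or Path(path).stem, genes)


def write_panel(panel: GenePanel, path) -> None:
    Path(path).write_text("\n".join(panel.genes) + "\n")


def read_gmt(path, uppercase: bool = False) -> GeneSetCollection:
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            genes = [g.upper() if uppercase else g for g in genes]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                logger.warning("%s:%d: duplicate set %s, keeping first", path, lineno, name)
                continue
            seen: set = set()
            sets[name] = [g for g in genes if not (g in seen or seen.add(g))]
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"empty GMT file: {path}")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# results


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_run_metadata(path, *, config: dict, seed: int | None, extra: dict | None = None) -> None:
    """JSON sidecar with the config echo, seed and package version."""
    from . import __version__

    payload = {"package": "neurescence", "version": __version__, "seed": seed, "config": config}
    if extra:
        payload.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
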