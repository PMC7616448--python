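"""Core containers: gene-by-cell count matrices, gene sets, cell annotations.

The count matrix is stored genes x cells, mirroring the on-disk 10x triplet
layout.  Raw counts are integer and sparse; the optional ``normalized`` layer
holds log1p library-size-normalized expression (see
:func:`iegactivity.preprocess.log_normalize`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

ANNOTATION_COLUMNS = ("cell_id", "cluster", "sample", "condition")


def _as_sparse(matrix) -> sp.csr_matrix:
    if sp.issparse(matrix):
        return matrix.tocsr()
    return sp.csr_matrix(np.asarray(matrix))


@dataclass
class CountMatrix:
    """Genes x cells unique-molecule counts with an optional normalized layer.

    Parameters
    ----------
    gene_symbols:
        Unique gene symbols, one per row. Matching everywhere in the package
        is by exact, case-sensitive symbol equality.
    cell_ids:
        Unique cell barcodes / identifiers, one per column.
    counts:
        Non-negative integer matrix of shape ``(n_genes, n_cells)``; dense
        arrays are converted to CSR.
    normalized:
        Optional same-shape matrix of log1p-normalized expression. For every
        cell with nonzero raw total, ``expm1`` of its column sums to
        ``norm_scale``.
    norm_scale:
        Per-cell target sum of the back-transformed normalized layer.
    """

    gene_symbols: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix
    normalized: sp.csr_matrix | None = None
    norm_scale: float = 1e4
    _gene_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.counts = _as_sparse(self.counts)
        if self.counts.shape != (len(self.gene_symbols), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_symbols)} genes x {len(self.cell_ids)} cells"
            )
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError("duplicate gene symbols (aggregate before constructing)")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if self.norm_scale <= 0:
            raise ValueError("norm_scale must be positive")
        if self.normalized is not None:
            self.normalized = _as_sparse(self.normalized).astype(np.float64)
            if self.normalized.shape != self.counts.shape:
                raise ValueError("normalized layer shape mismatch")
        self._gene_index = {g: i for i, g in enumerate(self.gene_symbols)}

    # ------------------------------------------------------------------ views
    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_indices(self, symbols: Iterable[str], strict: bool = True) -> np.ndarray:
        """Row indices for ``symbols``; unknown symbols raise unless ``strict=False``."""
        idx = []
        for s in symbols:
            i = self._gene_index.get(s)
            if i is None:
                if strict:
                    raise KeyError(f"gene symbol not in matrix: {s!r}")
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)

    def has_gene(self, symbol: str) -> bool:
        return symbol in self._gene_index

    def require_normalized(self) -> sp.csr_matrix:
        if self.normalized is None:
            raise ValueError("normalized layer missing; run log_normalize first")
        return self.normalized

    def normalized_dense(self, genes: Sequence[str] | None = None) -> np.ndarray:
        """Dense (genes x cells) float array of the normalized layer."""
        norm = self.require_normalized()
        if genes is not None:
            norm = norm[self.gene_indices(genes)]
        return np.asarray(norm.todense(), dtype=np.float64)

    def to_frame(self, layer: str = "normalized") -> pd.DataFrame:
        """Cells x genes DataFrame of ``layer`` ('normalized' or 'counts')."""
        if layer == "normalized":
            mat = self.require_normalized()
        elif layer == "counts":
            mat = self.counts
        else:
            raise ValueError(f"unknown layer {layer!r}")
        return pd.DataFrame(
            np.asarray(mat.T.todense()), index=list(self.cell_ids), columns=list(self.gene_symbols)
        )

    # ------------------------------------------------------------- subsetting
    def subset_cells(self, keep: Sequence[str] | np.ndarray) -> "CountMatrix":
        """New matrix restricted to the given cell ids or boolean mask (gene axis unchanged)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            mask = keep
            if mask.shape != (self.n_cells,):
                raise ValueError("boolean mask length mismatch")
            cols = np.flatnonzero(mask)
        else:
            pos = {c: j for j, c in enumerate(self.cell_ids)}
            try:
                cols = np.asarray([pos[c] for c in keep], dtype=int)
            except KeyError as exc:
                raise KeyError(f"cell id not in matrix: {exc.args[0]!r}") from None
        return CountMatrix(
            gene_symbols=list(self.gene_symbols),
            cell_ids=[self.cell_ids[j] for j in cols],
            counts=self.counts[:, cols],
            normalized=None if self.normalized is None else self.normalized[:, cols],
            norm_scale=self.norm_scale,
        )

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        rows = self.gene_indices(genes)
        return CountMatrix(
            gene_symbols=[self.gene_symbols[i] for i in rows],
            cell_ids=list(self.cell_ids),
            counts=self.counts[rows],
            normalized=None if self.normalized is None else self.normalized[rows],
            norm_scale=self.norm_scale,
        )


@dataclass(frozen=True)
class GeneSet:
    """Named, ordered collection of unique gene symbols."""

    name: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(str(s) for s in self.symbols))
        if not self.symbols:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"gene set {self.name!r} contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def present_in(self, matrix: CountMatrix) -> list[str]:
        """Symbols found in ``matrix`` (exact, case-sensitive), in set order."""
        return [s for s in self.symbols if matrix.has_gene(s)]


def validate_annotation(ann: pd.DataFrame, matrix: CountMatrix | None = None) -> pd.DataFrame:
    """Validate a per-cell annotation table (cell_id, cluster, sample, condition).

    Cell ids must be unique; labels must be non-empty. When ``matrix`` is
    given, every annotated cell id must be present in it.
    """
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise ValueError(f"annotation is missing columns: {missing_cols}")
    ann = ann.loc[:, list(ANNOTATION_COLUMNS)].astype(str)
    dup = ann["cell_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate cell_id in annotation: {ann.loc[dup, 'cell_id'].iloc[0]!r}")
    for col in ("cluster", "sample", "condition"):
        if (ann[col].str.len() == 0).any() or ann[col].isin(["nan"]).any():
            raise ValueError(f"annotation column {col!r} contains empty values")
    if matrix is not None:
        known = set(matrix.cell_ids)
        unknown = [c for c in ann["cell_id"] if c not in known]
        if unknown:
            raise KeyError(f"annotated cell id not found in count matrix: {unknown[0]!r}")
    return ann.reset_index(drop=True)
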