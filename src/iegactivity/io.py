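"""File I/O: 10x-style MatrixMarket triplets, annotation tables, gene lists.

All readers accept plain or gzip-compressed files transparently. On-disk
MatrixMarket indices are 1-based (format standard); in memory everything is
0-based.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import ANNOTATION_COLUMNS, CountMatrix, GeneSet, validate_annotation

logger = logging.getLogger(__name__)


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {directory}")


def _open_maybe_gzip(path: Path, mode: str = "rb"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_tsv_column(path: Path, column: int) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    col = min(column, df.shape[1] - 1)
    return df.iloc[:, col].tolist()


def read_10x_mtx(directory: str | Path) -> CountMatrix:
    """Read a 10x triplet directory (matrix.mtx + features.tsv + barcodes.tsv).

    Genes come back in features-file order, cells in barcodes order.
    Duplicate gene symbols are aggregated by summing their rows; the first
    occurrence keeps the position in the gene order.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    mtx_path = _find(directory, "matrix.mtx")
    features_path = _find(directory, "features.tsv")
    barcodes_path = _find(directory, "barcodes.tsv")

    with _open_maybe_gzip(mtx_path) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except ValueError as exc:
            raise ValueError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)

    # second column of features.tsv is the gene symbol in CellRanger output;
    # single-column files are accepted as bare symbol lists
    symbols = _read_tsv_column(features_path, 1)
    barcodes = _read_tsv_column(barcodes_path, 0)
    if mat.shape != (len(symbols), len(barcodes)):
        raise ValueError(
            f"matrix dimensions {mat.shape} do not match {len(symbols)} features "
            f"x {len(barcodes)} barcodes in {directory}"
        )
    symbols_arr = np.asarray(symbols, dtype=object)
    if len(set(symbols)) != len(symbols):
        mat, symbols_arr = _aggregate_duplicate_genes(mat, symbols_arr)
        logger.warning("aggregated duplicate gene symbols by summation in %s", directory)
    return CountMatrix(gene_symbols=list(symbols_arr), cell_ids=barcodes, counts=mat)


def _aggregate_duplicate_genes(mat: sp.csr_matrix, symbols: np.ndarray):
    order: dict[str, int] = {}
    for s in symbols:
        order.setdefault(s, len(order))
    groups = np.asarray([order[s] for s in symbols])
    indicator = sp.csr_matrix(
        (np.ones(len(symbols)), (groups, np.arange(len(symbols)))),
        shape=(len(order), len(symbols)),
    )
    return sp.csr_matrix(indicator @ mat), np.asarray(list(order), dtype=object)


def write_10x_mtx(matrix: CountMatrix, directory: str | Path, compress: bool = False) -> None:
    """Write the raw counts of ``matrix`` as a 10x triplet directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""
    with _open_maybe_gzip(directory / f"matrix.mtx{suffix}", "wb") as fh:
        scipy.io.mmwrite(fh, matrix.counts.tocoo(), field="integer")
    with _open_maybe_gzip(directory / f"features.tsv{suffix}", "wb") as fh:
        body = "".join(f"{g}\t{g}\tGene Expression\n" for g in matrix.gene_symbols)
        fh.write(body.encode())
    with _open_maybe_gzip(directory / f"barcodes.tsv{suffix}", "wb") as fh:
        fh.write(("".join(c + "\n" for c in matrix.cell_ids)).encode())


def read_dense_table(path: str | Path) -> CountMatrix:
    """Read a dense tab-separated genes x cells count table (genes as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.groupby(level=0, sort=False).sum()
    return CountMatrix(
        gene_symbols=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
        counts=df.to_numpy(),
    )


def read_annotation(path: str | Path, matrix: CountMatrix | None = None) -> pd.DataFrame:
    """Read a header-row TSV with columns cell_id, cluster, sample, condition."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    ann = pd.read_csv(path, sep="\t", dtype=str)
    return validate_annotation(ann, matrix)


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table as TSV (gzip if the path ends in .gz)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    write_table(ann.loc[:, list(ANNOTATION_COLUMNS)], path)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene list: one symbol per line, or a TSV whose first column is the symbol."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene list not found: {path}")
    with _open_maybe_gzip(path, "rb") as fh:
        lines = [ln.strip() for ln in fh.read().decode().splitlines()]
    symbols = []
    for ln in lines:
        if not ln or ln.startswith("#"):
            continue
        symbols.append(ln.split("\t")[0])
    return GeneSet(name=name or path.stem, symbols=tuple(dict.fromkeys(symbols)))
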