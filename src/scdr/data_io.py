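"""Readers, writers, single-cell QC and library-size normalization.

Dense expression lives in delimited text (header row of sample ids, first
column of gene ids); sparse single-cell counts come as a 10x-style
MatrixMarket triplet (matrix.mtx + features/barcodes lists).  QC follows the
common scRNA-seq recipe: drop low-complexity and high-mitochondrial cells
first, then genes detected in too few of the remaining cells.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import DrugResponseTable, ExpressionMatrix, SampleGrouping

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_dense",
    "write_expression_dense",
    "read_expression_mtx",
    "write_expression_mtx",
    "qc_filter_cells_genes",
    "normalize_counts",
    "read_drug_response",
    "write_drug_response",
    "read_grouping",
    "write_grouping",
]


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_dense(
    path: str | Path,
    orientation: str = "genes_in_rows",
    log_flag: bool = False,
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a dense expression table into genes × samples orientation.

    Parameters
    ----------
    orientation
        ``"genes_in_rows"`` (default) or ``"samples_in_rows"`` describing the
        on-disk layout; the returned matrix is always genes × samples.
    log_flag
        Sets ``is_log_scale`` on the result.
    delimiter
        Explicit field delimiter; by default inferred from the extension
        (``.csv`` → comma, anything else → tab).

    Duplicate gene rows are collapsed by their mean with a warning; duplicate
    sample ids are an error.
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"cannot parse expression table {path}: {exc}") from exc
    if df.empty:
        raise ValueError(f"expression table {path} has no data rows")
    # pandas mangles duplicate header tokens (x, x.1, ...); restore the raw
    # header so duplicates can be detected (samples) or collapsed (genes)
    with open(path) as fh:
        raw_header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(raw_header) == len(df.columns):
        df.columns = raw_header
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if orientation == "samples_in_rows":
        df = df.T
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicate sample ids in {path}: {dups[:10]}")
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        logger.warning(
            "collapsing %d duplicated gene ids by mean (e.g. %s)",
            len(dups), dups[:5],
        )
        df = df.groupby(level=0, sort=False).mean()
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-numeric or non-finite values in {path}")
    return ExpressionMatrix(list(df.index), list(df.columns), values, log_flag)


def write_expression_dense(expr: ExpressionMatrix, path: str | Path,
                           delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    expr.to_frame().to_csv(path, sep=sep, index_label="gene_id",
                           float_format="%.10g")


def read_expression_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> ExpressionMatrix:
    """Read a MatrixMarket coordinate triplet (genes × cells raw counts).

    ``genes_path`` / ``barcodes_path`` are newline-delimited id lists (for a
    multi-column features.tsv the first column is used).  Counts stay
    sparse-backed.
    """
    mat = scipy.io.mmread(str(matrix_path))
    genes = [
        line.split("\t")[0].strip()
        for line in Path(genes_path).read_text().splitlines()
        if line.strip()
    ]
    barcodes = [
        line.split("\t")[0].strip()
        for line in Path(barcodes_path).read_text().splitlines()
        if line.strip()
    ]
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes "
            f"and {len(barcodes)} barcodes"
        )
    return ExpressionMatrix(genes, barcodes, sp.csr_matrix(mat), is_log_scale=False)


def write_expression_mtx(expr: ExpressionMatrix, out_dir: str | Path) -> None:
    """Write matrix.mtx / features.tsv / barcodes.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = expr.values if sp.issparse(expr.values) else sp.coo_matrix(expr.values)
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat)
    (out / "features.tsv").write_text("".join(g + "\n" for g in expr.gene_ids))
    (out / "barcodes.tsv").write_text("".join(b + "\n" for b in expr.sample_ids))


def qc_filter_cells_genes(
    counts: ExpressionMatrix,
    mito_prefix: str = "MT-",
    min_genes_per_cell: int = 200,
    max_mito_fraction: float = 0.20,
    min_cells_per_gene: int = 3,
) -> ExpressionMatrix:
    """Standard two-pass single-cell QC on raw counts.

    Pass 1 removes cells with fewer than ``min_genes_per_cell`` detected
    genes or a mitochondrial count fraction above ``max_mito_fraction``
    (mitochondrial genes are identified by id prefix).  Pass 2 then removes
    genes detected in fewer than ``min_cells_per_gene`` of the *remaining*
    cells.  Values are never altered, only rows/columns dropped.
    """
    dense = counts.values
    sparse = sp.issparse(dense)
    detected = (
        np.asarray((dense > 0).sum(axis=0)).ravel() if sparse
        else (dense > 0).sum(axis=0)
    )
    mito_mask = np.array(
        [g.upper().startswith(mito_prefix.upper()) for g in counts.gene_ids]
    )
    totals = np.asarray(dense.sum(axis=0)).ravel()
    mito_counts = (
        np.asarray(dense[mito_mask].sum(axis=0)).ravel()
        if mito_mask.any() else np.zeros_like(totals)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-300), 1.0)
    keep_cells = (detected >= min_genes_per_cell) & (mito_frac <= max_mito_fraction)
    if not keep_cells.any():
        raise ValueError("empty after QC: every cell failed the cell filters")
    sub = dense[:, keep_cells]
    det_genes = (
        np.asarray((sub > 0).sum(axis=1)).ravel() if sparse
        else (sub > 0).sum(axis=1)
    )
    keep_genes = det_genes >= min_cells_per_gene
    n_cells_dropped = int((~keep_cells).sum())
    n_genes_dropped = int((~keep_genes).sum())
    if n_cells_dropped or n_genes_dropped:
        logger.info("QC removed %d cells and %d genes", n_cells_dropped, n_genes_dropped)
    if not keep_genes.any():
        raise ValueError("empty after QC: every gene failed the gene filter")
    return ExpressionMatrix(
        [g for g, k in zip(counts.gene_ids, keep_genes) if k],
        [s for s, k in zip(counts.sample_ids, keep_cells) if k],
        sub[keep_genes],
        counts.is_log_scale,
    )


def normalize_counts(counts: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalization: counts / cell total × scale, then ln(1+x).

    Mirrors the standard normalization step of single-cell toolkits.  Cells
    with zero total raise, pointing the user at QC.
    """
    if counts.is_log_scale:
        raise ValueError("normalize_counts expects raw counts, got log-scale input")
    dense = counts.dense()
    totals = dense.sum(axis=0)
    if np.any(totals == 0):
        bad = [s for s, t in zip(counts.sample_ids, totals) if t == 0]
        raise ValueError(
            f"cells with zero total counts ({bad[:5]}...); run QC filtering first"
        )
    norm = np.log1p(dense / totals * scale)
    return ExpressionMatrix(
        list(counts.gene_ids), list(counts.sample_ids), norm, is_log_scale=True
    )


def read_drug_response(path: str | Path) -> DrugResponseTable:
    """Read a delimited file with columns cell_line, drug, auc."""
    path = Path(path)
    sep = _delimiter_for(path, None)
    df = pd.read_csv(path, sep=sep)
    required = {"cell_line", "drug", "auc"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path} must have columns cell_line, drug, auc; got {list(df.columns)}"
        )
    bad = pd.to_numeric(df["auc"], errors="coerce").isna() & df["auc"].notna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"non-numeric auc values at lines {lines[:10]} of {path}")
    return DrugResponseTable(df)


def write_drug_response(table: DrugResponseTable, path: str | Path) -> None:
    table.records.to_csv(path, index=False, float_format="%.10g")


def read_grouping(path: str | Path) -> SampleGrouping:
    """Read a two-column sample_id<TAB>group table (header optional)."""
    path = Path(path)
    assignment: dict[str, str] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected 2 tab-separated fields")
        key, val = parts[0].strip(), parts[1].strip()
        if i == 1 and key.lower() in ("sample_id", "sample", "cell", "cell_id"):
            continue
        if key in assignment:
            raise ValueError(f"{path}:{i}: duplicate sample id {key!r}")
        assignment[key] = val
    return SampleGrouping(assignment)


def write_grouping(grouping: SampleGrouping, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in grouping.assignment.items():
            fh.write(f"{sample}\t{group}\n")
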