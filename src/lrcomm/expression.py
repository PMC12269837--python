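"""Single-cell expression input: loading, log-normalization, sample splits.

The pipeline consumes a cells × genes matrix of log-normalized expression
(``log1p`` of library-size-scaled counts) together with per-cell metadata
assigning each cell a cell type and, optionally, a sample label. Matrices
load from MatrixMarket sparse triplets with companion gene/barcode lists,
or from a dense delimited table carrying its own row/column labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)


class ExpressionFormatError(ValueError):
    """Input files do not conform to the expected layout."""


@dataclass
class ExpressionDataset:
    """Log-normalized cells × genes expression with per-cell labels.

    Attributes
    ----------
    matrix
        Dense float array, shape ``(n_cells, n_genes)``, non-negative.
    cell_ids, gene_ids
        Unique string identifiers matching the matrix axes.
    cell_type
        Per-cell label array (non-empty strings), length ``n_cells``.
    sample
        Optional per-cell sample label array, length ``n_cells``.
    """

    matrix: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    cell_type: np.ndarray
    sample: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        if self.sample is not None:
            self.sample = np.asarray(self.sample, dtype=object)
        self.validate()

    def validate(self) -> None:
        n_cells, n_genes = self.matrix.shape
        if len(self.cell_ids) != n_cells:
            raise ExpressionFormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ExpressionFormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.cell_type) != n_cells:
            raise ExpressionFormatError(
                f"{len(self.cell_type)} cell_type labels for {n_cells} cells"
            )
        if self.sample is not None and len(self.sample) != n_cells:
            raise ExpressionFormatError(
                f"{len(self.sample)} sample labels for {n_cells} cells"
            )
        if any(not t for t in self.cell_type):
            raise ExpressionFormatError("every cell needs a non-empty cell_type")
        if not np.all(np.isfinite(self.matrix)):
            raise ExpressionFormatError("matrix contains non-finite values")
        if (self.matrix < 0).any():
            raise ExpressionFormatError(
                "matrix contains negative values; expected log-normalized expression"
            )

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def cell_types(self) -> list[str]:
        """Distinct cell-type labels, sorted."""
        return sorted(set(self.cell_type))

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        """New dataset restricted to cells where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return ExpressionDataset(
            matrix=self.matrix[mask],
            cell_ids=[c for c, m in zip(self.cell_ids, mask) if m],
            gene_ids=list(self.gene_ids),
            cell_type=self.cell_type[mask],
            sample=None if self.sample is None else self.sample[mask],
        )


def lognormalize(raw: np.ndarray, scale: float = 10_000.0) -> np.ndarray:
    """Library-size normalize counts and apply ``log1p``.

    Each cell's counts are divided by that cell's total, multiplied by
    ``scale`` (counts-per-10k by default, the convention of standard
    single-cell toolkits), then transformed with the natural ``log1p``.

    Raises
    ------
    ValueError
        If any count is negative or any cell has zero total counts
        (the offending cell indices are listed).
    """
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError("counts must be non-negative")
    totals = raw.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cells with zero total counts: {zero.tolist()}")
    return np.log1p(raw / totals[:, None] * scale)


def load_expression(
    matrix_path,
    genes_path=None,
    cells_path=None,
    metadata_path=None,
    *,
    cell_type_col: str = "cell_type",
    sample_col: str = "sample",
    normalize: bool = False,
    scale: float = 10_000.0,
) -> ExpressionDataset:
    """Load an expression matrix plus per-cell metadata.

    ``matrix_path`` may be a MatrixMarket ``.mtx`` file (with companion
    ``genes_path`` / ``cells_path`` id lists, one per line) or a dense
    TSV/CSV whose header row and first column carry gene and cell ids.
    Orientation is auto-detected: a matrix arriving genes × cells is
    transposed (logged).

    Metadata is a delimited table with a cell-id column (first column or
    ``cell_id``) and a ``cell_type`` column; a ``sample`` column, when
    present, populates per-sample labels. Cells in the matrix but absent
    from metadata are an error; metadata rows without a matrix cell are
    ignored with a warning.

    Set ``normalize=True`` when the matrix holds raw counts; otherwise the
    values are taken verbatim as already log-normalized.
    """
    if metadata_path is None:
        raise ValueError("metadata_path is required (cell_type assignments)")
    path = str(matrix_path)
    if path.endswith((".mtx", ".mtx.gz")):
        if genes_path is None or cells_path is None:
            raise ValueError("MTX input needs companion genes_path and cells_path")
        mat = scipy.io.mmread(path)
        mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        gene_ids = _read_id_list(genes_path)
        cell_ids = _read_id_list(cells_path)
        if mat.shape == (len(cell_ids), len(gene_ids)):
            pass
        elif mat.shape == (len(gene_ids), len(cell_ids)):
            logger.info("matrix is genes x cells; transposing")
            mat = mat.T
        else:
            raise ExpressionFormatError(
                f"matrix shape {mat.shape} matches neither (cells={len(cell_ids)}, "
                f"genes={len(gene_ids)}) nor its transpose"
            )
    else:
        sep = "," if path.endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        meta_ids = set(_read_metadata_ids(metadata_path))
        # orientation: cells can sit on rows or columns of a dense table
        row_hits = len(meta_ids.intersection(df.index.astype(str)))
        col_hits = len(meta_ids.intersection(df.columns.astype(str)))
        if col_hits > row_hits:
            logger.info("dense table is genes x cells; transposing")
            df = df.T
        if not np.issubdtype(np.asarray(df.values).dtype, np.number):
            raise ExpressionFormatError("dense matrix contains non-numeric entries")
        mat = df.values.astype(float)
        cell_ids = [str(c) for c in df.index]
        gene_ids = [str(g) for g in df.columns]

    meta = pd.read_csv(metadata_path, sep=None, engine="python", dtype=str)
    id_col = "cell_id" if "cell_id" in meta.columns else meta.columns[0]
    if cell_type_col not in meta.columns:
        raise ExpressionFormatError(
            f"metadata {metadata_path} is missing column {cell_type_col!r}"
        )
    meta = meta.set_index(id_col)
    missing = [c for c in cell_ids if c not in meta.index]
    if missing:
        raise ExpressionFormatError(
            f"cells present in matrix but absent from metadata: {missing[:10]}"
            + (" ..." if len(missing) > 10 else "")
        )
    extra = meta.index.difference(cell_ids)
    if len(extra):
        logger.warning("%d metadata rows have no matrix cell; ignored", len(extra))
    meta = meta.loc[cell_ids]

    if normalize:
        mat = lognormalize(mat, scale=scale)

    sample = None
    if sample_col in meta.columns and meta[sample_col].notna().any():
        sample = meta[sample_col].to_numpy(dtype=object)
    return ExpressionDataset(
        matrix=mat,
        cell_ids=list(cell_ids),
        gene_ids=gene_ids,
        cell_type=meta[cell_type_col].to_numpy(dtype=object),
        sample=sample,
    )


def split_by_sample(ds: ExpressionDataset) -> dict[str, ExpressionDataset]:
    """Partition a dataset into one dataset per sample label.

    Every sub-dataset keeps the full gene list; cells partition exactly.
    """
    if ds.sample is None:
        raise ValueError(
            "dataset has no sample labels; run in single-sample mode instead"
        )
    out: dict[str, ExpressionDataset] = {}
    for label in sorted(set(ds.sample)):
        out[label] = ds.subset_cells(ds.sample == label)
    return out


def write_expression(ds: ExpressionDataset, matrix_path, genes_path, cells_path,
                     metadata_path) -> None:
    """Write a dataset in the MTX + id lists + metadata layout the loader reads."""
    scipy.io.mmwrite(str(matrix_path), scipy.sparse.csr_matrix(ds.matrix))
    with open(genes_path, "w") as fh:
        fh.write("\n".join(ds.gene_ids) + "\n")
    with open(cells_path, "w") as fh:
        fh.write("\n".join(ds.cell_ids) + "\n")
    meta = pd.DataFrame({"cell_id": ds.cell_ids, "cell_type": ds.cell_type})
    if ds.sample is not None:
        meta["sample"] = ds.sample
    meta.to_csv(metadata_path, sep="\t", index=False)


def _read_id_list(path) -> list[str]:
    with open(path) as fh:
        ids = [line.strip().split("\t")[0] for line in fh if line.strip()]
    if len(set(ids)) != len(ids):
        raise ExpressionFormatError(f"duplicate identifiers in {path}")
    return ids


def _read_metadata_ids(path) -> list[str]:
    meta = pd.read_csv(path, sep=None, engine="python", dtype=str)
    col = "cell_id" if "cell_id" in meta.columns else meta.columns[0]
    return meta[col].tolist()


__all__ = [
    "ExpressionDataset",
    "ExpressionFormatError",
    "lognormalize",
    "load_expression",
    "split_by_sample",
    "write_expression",
]
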