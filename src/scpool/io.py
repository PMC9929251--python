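"""Readers/writers for 10x-style sparse count triplets and tabular results.

The on-disk format is the plain MatrixMarket triplet (``matrix.mtx`` plus
``barcodes.tsv`` and ``features.tsv``/``genes.tsv``, optionally gzipped) used
by droplet scRNA-seq pipelines.  Matrices are held in memory as cells x genes
regardless of the on-disk orientation, which is auto-detected from the lengths
of the barcode and feature lists.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("scpool")

STIMULUS_LEVELS = ("Null", "TNF")
STATUS_LEVELS = ("Control", "JIA")

__all__ = [
    "GeneExpressionMatrix",
    "CellAnnotation",
    "read_10x_mtx",
    "write_10x_mtx",
    "read_annotation",
    "write_table",
    "STIMULUS_LEVELS",
    "STATUS_LEVELS",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class GeneExpressionMatrix:
    """Sparse non-negative integer UMI counts, cells x genes.

    Parameters
    ----------
    counts
        Sparse matrix of shape ``(n_cells, n_genes)`` with non-negative
        integral entries.
    cell_ids, gene_ids
        Unique string identifiers matching the matrix dimensions.  Genes are
        keyed by feature id; the (possibly non-unique) symbol is carried as
        metadata in :attr:`gene_symbols`.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    gene_symbols: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.gene_symbols is not None:
            self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("cell_ids are not unique")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene_ids are not unique")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValidationError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integral counts")

    # -- conveniences -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cell_index(self) -> dict:
        return {c: i for i, c in enumerate(self.cell_ids)}

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def total_counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def detected_genes_per_cell(self) -> np.ndarray:
        return np.diff(self.counts.indptr) if sp.issparse(self.counts) else None

    def subset_cells(self, mask: np.ndarray) -> "GeneExpressionMatrix":
        mask = np.asarray(mask)
        return GeneExpressionMatrix(
            self.counts[mask], self.cell_ids[mask], self.gene_ids,
            self.gene_symbols,
        )

    def to_anndata(self):
        """Return an :class:`anndata.AnnData` view of the counts (interop)."""
        import anndata as ad

        var = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        if self.gene_symbols is not None:
            var["symbol"] = self.gene_symbols
        return ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=var,
        )


REQUIRED_ANNOTATION_COLUMNS = ("cell_id", "donor", "batch", "stimulus", "status", "cluster")


@dataclass
class CellAnnotation:
    """Per-cell experimental factors.

    One row per cell, aligned with the matched matrix.  ``donor`` maps to
    exactly one ``batch`` and one ``status`` (donors are nested in batch and
    disease status); each (donor, stimulus) pair is one sample.
    ``batch_label_columns`` name optional columns holding per-batch-run
    cluster calls used by the label-consistency QC filter.
    """

    table: pd.DataFrame
    batch_label_columns: tuple = ()

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        self.batch_label_columns = tuple(self.batch_label_columns)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing required columns: {missing}")
        if self.table["cell_id"].duplicated().any():
            dup = self.table.loc[self.table["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValidationError(f"duplicate cell_id in annotation: {dup!r}")
        bad_stim = set(self.table["stimulus"].astype(str)) - set(STIMULUS_LEVELS)
        if bad_stim:
            raise ValidationError(
                f"unknown stimulus level(s) {sorted(bad_stim)}; expected {STIMULUS_LEVELS}"
            )
        bad_status = set(self.table["status"].astype(str)) - set(STATUS_LEVELS)
        if bad_status:
            raise ValidationError(
                f"unknown status level(s) {sorted(bad_status)}; expected {STATUS_LEVELS}"
            )
        for col in ("batch", "status"):
            per_donor = self.table.groupby("donor", observed=True)[col].nunique()
            offenders = per_donor[per_donor > 1]
            if len(offenders):
                raise ValidationError(
                    f"donor(s) {list(offenders.index)} map to multiple {col} levels"
                )
        for col in self.batch_label_columns:
            if col not in self.table.columns:
                raise ValidationError(f"batch label column {col!r} not in table")

    @property
    def cell_ids(self) -> np.ndarray:
        return self.table["cell_id"].to_numpy(dtype=object)

    @property
    def n_cells(self) -> int:
        return len(self.table)

    def sample_labels(self) -> pd.Series:
        """Sample key ``<donor>_<stimulus>`` for every cell."""
        return self.table["donor"].astype(str) + "_" + self.table["stimulus"].astype(str)

    def donor_factors(self) -> pd.DataFrame:
        """One row per donor with its batch and status."""
        return (
            self.table.groupby("donor", observed=True)[["batch", "status"]]
            .first()
            .reset_index()
        )

    def subset(self, mask: np.ndarray) -> "CellAnnotation":
        return CellAnnotation(self.table.loc[np.asarray(mask)], self.batch_label_columns)

    def reorder(self, cell_ids: Sequence) -> "CellAnnotation":
        idx = self.table.set_index("cell_id").loc[list(cell_ids)].reset_index()
        return CellAnnotation(idx, self.batch_label_columns)


# ---------------------------------------------------------------------------
# 10x triplet reading / writing
# ---------------------------------------------------------------------------

def _find_file(directory: Path, stems: Iterable[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FileNotFoundError(
        f"none of {list(stems)} (or .gz) found in {directory}"
    )


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_10x_mtx(path, orientation: str = "auto") -> GeneExpressionMatrix:
    """Read a MatrixMarket triplet directory into a cells x genes matrix.

    Parameters
    ----------
    path
        Directory containing ``matrix.mtx[.gz]``, ``barcodes.tsv[.gz]`` and
        ``features.tsv[.gz]`` (or the older ``genes.tsv``).
    orientation
        ``"auto"`` detects genes x cells vs cells x genes by matching the id
        list lengths against the matrix shape; for a square matrix pass
        ``"cells_by_genes"`` or ``"genes_by_cells"`` explicitly.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    mtx_path = _find_file(directory, ["matrix.mtx"])
    barcodes_path = _find_file(directory, ["barcodes.tsv"])
    features_path = _find_file(directory, ["features.tsv", "genes.tsv"])

    mat = sp.coo_matrix(scipy.io.mmread(str(mtx_path)))
    barcodes = _read_lines(barcodes_path)
    feature_rows = [line.split("\t") for line in _read_lines(features_path)]
    gene_ids = [row[0] for row in feature_rows]
    gene_symbols = [row[1] if len(row) > 1 else row[0] for row in feature_rows]

    n_bc, n_ft = len(barcodes), len(gene_ids)
    if orientation == "auto":
        if mat.shape == (n_ft, n_bc) and mat.shape != (n_bc, n_ft):
            mat = mat.T
        elif mat.shape == (n_bc, n_ft) and mat.shape != (n_ft, n_bc):
            pass
        elif mat.shape == (n_bc, n_ft):  # square with n_bc == n_ft
            raise ValidationError(
                "square matrix with equal id list lengths: orientation is "
                "ambiguous, pass orientation='cells_by_genes' or "
                "'genes_by_cells'"
            )
        else:
            raise ValidationError(
                f"matrix shape {mat.shape} matches neither "
                f"(cells={n_bc}, genes={n_ft}) nor its transpose"
            )
    elif orientation == "genes_by_cells":
        if mat.shape != (n_ft, n_bc):
            raise ValidationError(
                f"matrix shape {mat.shape} != (genes={n_ft}, cells={n_bc})"
            )
        mat = mat.T
    elif orientation == "cells_by_genes":
        if mat.shape != (n_bc, n_ft):
            raise ValidationError(
                f"matrix shape {mat.shape} != (cells={n_bc}, genes={n_ft})"
            )
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    return GeneExpressionMatrix(
        counts=sp.csr_matrix(mat),
        cell_ids=np.array(barcodes, dtype=object),
        gene_ids=np.array(gene_ids, dtype=object),
        gene_symbols=np.array(gene_symbols, dtype=object),
    )


def write_10x_mtx(matrix: GeneExpressionMatrix, path) -> None:
    """Write ``matrix`` as a plain (uncompressed) triplet directory.

    The matrix is stored genes x cells, the 10x on-disk convention.
    """
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(directory / "matrix.mtx"), sp.coo_matrix(matrix.counts.T), field="integer"
    )
    (directory / "barcodes.tsv").write_text(
        "".join(f"{c}\n" for c in matrix.cell_ids)
    )
    symbols = (
        matrix.gene_symbols if matrix.gene_symbols is not None else matrix.gene_ids
    )
    (directory / "features.tsv").write_text(
        "".join(f"{g}\t{s}\n" for g, s in zip(matrix.gene_ids, symbols))
    )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def read_annotation(path, matrix: GeneExpressionMatrix) -> CellAnnotation:
    """Read a delimited per-cell factor table and align it with ``matrix``.

    Cells present in the matrix but absent from the table are an error; extra
    table rows are dropped with a logged count.  The returned annotation is
    ordered exactly as ``matrix.cell_ids``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, dtype=str)
    missing_cols = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"annotation missing required columns: {missing_cols}")

    have = set(table["cell_id"])
    wanted = list(matrix.cell_ids)
    absent = [c for c in wanted if c not in have]
    if absent:
        raise ValidationError(
            f"{len(absent)} matrix cells missing from annotation, first "
            f"offenders: {absent[:5]}"
        )
    n_extra = len(have - set(wanted))
    if n_extra:
        logger.info("dropping %d annotation rows not present in matrix", n_extra)
    aligned = table.set_index("cell_id").loc[wanted].reset_index()
    batch_label_cols = tuple(
        c for c in aligned.columns if c.startswith("cluster_run")
    )
    return CellAnnotation(aligned, batch_label_cols)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_table(result, path) -> None:
    """Write any of the package's tabular results as TSV with header.

    ``result`` may be a DataFrame or any object exposing ``to_frame()``.
    Round-tripping through :func:`pandas.read_csv` reproduces the values to
    full float precision (values are written with ``repr`` precision).
    """
    if hasattr(result, "to_frame") and not isinstance(result, pd.DataFrame):
        frame = result.to_frame()
    elif isinstance(result, pd.DataFrame):
        frame = result
    else:
        raise TypeError(f"cannot write object of type {type(result).__name__}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
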