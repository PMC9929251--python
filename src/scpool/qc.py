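"""Cell-level quality-control filters.

Three filters, each computed independently on the *original* input so their
flags are order-independent:

1. mitochondrial fraction strictly greater than a threshold (default 15%);
2. detected-gene count more than ``k`` sample standard deviations above the
   mean (default 3 SD, one-sided upper — high outliers are possible
   multiplets);
3. cluster-label consistency — a cell must receive its total-dataset cluster
   label in at least ``min_matches`` of its per-batch-run clusterings
   (default 2 of 4).

The :class:`QcReport` attributes every removed cell to exactly one reason by
the fixed order mito -> outlier -> consistency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellAnnotation, GeneExpressionMatrix

logger = logging.getLogger("scpool")

__all__ = [
    "QcReport",
    "filter_mito",
    "filter_gene_count_outliers",
    "filter_label_consistency",
    "run_qc",
    "mito_gene_mask",
]


@dataclass
class QcReport:
    """Counts of removed cells per filter plus per-cell flags.

    ``flags`` has one row per input cell with boolean ``pass_mito``,
    ``pass_outlier``, ``pass_consistency``, ``retained`` and a ``reason``
    column naming the first failing rule (mito -> outlier -> consistency),
    empty for retained cells.
    """

    n_input: int
    n_removed_mito: int
    n_removed_outlier: int
    n_removed_consistency: int
    n_retained: int
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_mito + self.n_removed_outlier + self.n_removed_consistency
        )
        if self.n_retained + removed != self.n_input:
            raise ValueError("QcReport counts do not add up to n_input")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "n_input",
                    "n_removed_mito",
                    "n_removed_outlier",
                    "n_removed_consistency",
                    "n_retained",
                ],
                "value": [
                    self.n_input,
                    self.n_removed_mito,
                    self.n_removed_outlier,
                    self.n_removed_consistency,
                    self.n_retained,
                ],
            }
        )


def mito_gene_mask(matrix: GeneExpressionMatrix, prefix: str = "MT-") -> np.ndarray:
    """Boolean gene mask for mitochondrial genes by symbol prefix."""
    symbols = (
        matrix.gene_symbols if matrix.gene_symbols is not None else matrix.gene_ids
    )
    return np.array([str(s).startswith(prefix) for s in symbols])


def filter_mito(
    matrix: GeneExpressionMatrix,
    mito_gene_ids,
    threshold: float = 0.15,
) -> np.ndarray:
    """Pass flags for the mitochondrial-fraction filter.

    A cell fails iff mito counts / total counts is *strictly* greater than
    ``threshold``; a cell with exactly the threshold fraction is retained.
    Zero-total cells fail (their fraction is undefined).
    """
    mito_set = set(mito_gene_ids)
    if not mito_set:
        raise ValueError("empty mitochondrial gene set: cannot compute fraction")
    unknown = mito_set - set(matrix.gene_ids)
    if unknown:
        raise ValueError(f"mito gene ids not in matrix: {sorted(unknown)[:5]}")
    gene_idx = matrix.gene_index()
    cols = np.array([gene_idx[g] for g in mito_set])
    totals = matrix.total_counts_per_cell().astype(float)
    mito_counts = np.asarray(matrix.counts[:, cols].sum(axis=1)).ravel().astype(float)
    passes = np.zeros(matrix.n_cells, dtype=bool)
    ok = totals > 0
    passes[ok] = (mito_counts[ok] / totals[ok]) <= threshold
    if (~ok).any():
        logger.warning("%d zero-count cells fail the mito filter", int((~ok).sum()))
    return passes


def filter_gene_count_outliers(
    matrix: GeneExpressionMatrix,
    k_sd: float = 3.0,
    metric: str = "detected_genes",
) -> np.ndarray:
    """Pass flags for the high-gene-count outlier filter.

    ``metric="detected_genes"`` (default) counts genes with count > 0 per
    cell; ``metric="total_counts"`` uses the UMI total instead.  The mean and
    sample standard deviation are computed once over all input cells before
    any removal; a cell fails iff its value exceeds ``mean + k_sd * sd``.
    With zero spread nothing is removed.
    """
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells to compute outlier statistics")
    if metric == "detected_genes":
        values = np.asarray((matrix.counts > 0).sum(axis=1)).ravel().astype(float)
    elif metric == "total_counts":
        values = matrix.total_counts_per_cell().astype(float)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    sd = values.std(ddof=1)
    cutoff = values.mean() + k_sd * sd
    if sd == 0:
        return np.ones(matrix.n_cells, dtype=bool)
    return values <= cutoff


def filter_label_consistency(
    annotation: CellAnnotation,
    min_matches: int = 2,
    missing: str = "fail",
) -> np.ndarray:
    """Pass flags for the cluster-label consistency filter.

    A cell passes iff at least ``min_matches`` of its per-batch-run labels
    (columns ``annotation.batch_label_columns``) equal its total-dataset
    ``cluster`` label.  Cells with no batch labels fail by default
    (``missing="fail"``); ``missing="pass"`` passes them through with a
    warning.
    """
    cols = list(annotation.batch_label_columns)
    if not cols:
        if missing == "pass":
            logger.warning("no batch label columns: passing all cells through")
            return np.ones(annotation.n_cells, dtype=bool)
        raise ValueError(
            "annotation has no per-batch-run label columns (cluster_run*)"
        )
    table = annotation.table
    total = table["cluster"].to_numpy(dtype=object)
    labels = table[cols].to_numpy(dtype=object)
    observed = pd.notna(labels)
    matches = ((labels == total[:, None]) & observed).sum(axis=1)
    passes = matches >= min_matches
    none_observed = ~observed.any(axis=1)
    if none_observed.any():
        if missing == "pass":
            logger.warning(
                "%d cells have no batch labels: passed through", int(none_observed.sum())
            )
            passes = passes | none_observed
        else:
            passes = passes & ~none_observed
    return passes


def run_qc(
    matrix: GeneExpressionMatrix,
    annotation: CellAnnotation,
    mito_gene_ids=None,
    mito_threshold: float = 0.15,
    k_sd: float = 3.0,
    outlier_metric: str = "detected_genes",
    min_matches: int = 2,
    consistency: bool = True,
) -> QcReport:
    """Apply all filters and build the attribution report.

    ``mito_gene_ids`` defaults to genes whose symbol starts with ``MT-``;
    when no such gene exists the mito filter is skipped (all cells pass it).
    ``consistency=False`` skips the label-consistency filter (for annotations
    without per-batch-run labels).
    """
    if list(annotation.cell_ids) != list(matrix.cell_ids):
        raise ValueError("annotation and matrix cell ids are not aligned")
    if mito_gene_ids is None:
        mask = mito_gene_mask(matrix)
        mito_gene_ids = list(matrix.gene_ids[mask])
    if mito_gene_ids:
        pass_mito = filter_mito(matrix, mito_gene_ids, mito_threshold)
    else:
        logger.info("no mitochondrial genes found: skipping mito filter")
        pass_mito = np.ones(matrix.n_cells, dtype=bool)
    pass_outlier = filter_gene_count_outliers(matrix, k_sd, outlier_metric)
    if consistency and annotation.batch_label_columns:
        pass_consistency = filter_label_consistency(annotation, min_matches)
    else:
        pass_consistency = np.ones(matrix.n_cells, dtype=bool)

    reason = np.full(matrix.n_cells, "", dtype=object)
    reason[~pass_consistency] = "consistency"
    reason[~pass_outlier] = "outlier"
    reason[~pass_mito] = "mito"  # fixed attribution order: mito first
    retained = pass_mito & pass_outlier & pass_consistency
    flags = pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "pass_mito": pass_mito,
            "pass_outlier": pass_outlier,
            "pass_consistency": pass_consistency,
            "retained": retained,
            "reason": reason,
        }
    )
    return QcReport(
        n_input=matrix.n_cells,
        n_removed_mito=int((reason == "mito").sum()),
        n_removed_outlier=int((reason == "outlier").sum()),
        n_removed_consistency=int((reason == "consistency").sum()),
        n_retained=int(retained.sum()),
        flags=flags,
    )
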