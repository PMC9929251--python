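"""Per-gene variance partitioning of pseudocell expression.

For each expressed gene of a cell type the (log-transformed) CP100K values
across pseudocells are decomposed into crossed random-intercept components —
Stimulus, Status, Batch, Donor and the Stimulus:Status interaction — plus
residual, and reported as fractions of total variance.  Estimation is REML
with a method-of-moments fallback (see :mod:`scpool.lmm`).

With only two levels each for Stimulus and Status, those variance estimates
are intrinsically noisy; that is a property of the experimental design, not
of the estimator, and is documented rather than corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lmm
from .concordance import RankedGeneList
from .pooling import PseudocellMatrix

logger = logging.getLogger("scpool")

EFFECTS = ("Stimulus", "Status", "Batch", "Donor", "Stimulus:Status")
ALL_COMPONENTS = EFFECTS + (lmm.RESIDUAL,)

__all__ = [
    "EFFECTS",
    "ALL_COMPONENTS",
    "VarianceComponents",
    "VarPartSummary",
    "filter_expressed_genes",
    "transform_expression",
    "fit_variance_components",
    "partition_cell_type",
    "rank_genes",
    "results_to_frame",
]


@dataclass
class VarianceComponents:
    """Per-gene variance decomposition."""

    gene_id: str
    sigma2: dict
    fraction: dict
    converged: bool
    backend: str

    def __post_init__(self) -> None:
        total = sum(self.fraction.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"{self.gene_id}: fractions sum to {total}")
        for name, f in self.fraction.items():
            if not -1e-12 <= f <= 1 + 1e-12:
                raise ValueError(f"{self.gene_id}: fraction {name}={f} outside [0,1]")


@dataclass
class VarPartSummary:
    """Cell-type level summary over expressed genes."""

    cell_type: str
    pool_size: int
    iteration: int
    n_genes: int
    mean_fraction: dict
    frac_genes_gt5: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for effect in ALL_COMPONENTS:
            rows.append(
                {
                    "cell_type": self.cell_type,
                    "pool_size": self.pool_size,
                    "iteration": self.iteration,
                    "n_genes": self.n_genes,
                    "effect": effect,
                    "mean_fraction": self.mean_fraction.get(effect, np.nan),
                    "frac_genes_gt5": self.frac_genes_gt5.get(effect, np.nan),
                }
            )
        return pd.DataFrame(rows)


def filter_expressed_genes(pm: PseudocellMatrix, min_mean_cp100k: float = 1.0):
    """Genes with mean CP100K >= 1 (inclusive) across the pseudocells.

    ``pm`` should already be restricted to a single cell type.
    """
    if pm.n_pseudocells == 0:
        logger.warning("no pseudocells: expressed gene set is empty")
        return np.array([], dtype=object)
    means = pm.cp100k.mean(axis=0)
    return np.asarray(pm.gene_ids, dtype=object)[means >= min_mean_cp100k]


def transform_expression(pm: PseudocellMatrix, mode: str = "log2p1") -> np.ndarray:
    """Expression matrix for model fitting.

    ``log2p1`` (default): ``log2(CP100K + 1)``; ``raw``: identity.
    """
    if mode == "log2p1":
        return np.log2(pm.cp100k + 1.0)
    if mode == "raw":
        return pm.cp100k.copy()
    raise ValueError(f"unknown transform {mode!r}")


def fit_variance_components(
    y: np.ndarray,
    factors: pd.DataFrame,
    gene_id: str = "",
    effects=EFFECTS,
) -> VarianceComponents:
    """Decompose one gene's pseudocell expression into variance fractions.

    ``factors`` must carry per-pseudocell ``stimulus``, ``status``,
    ``batch`` and ``donor`` labels.  ``effects`` selects the random effects
    fitted (default: all five); effects not fitted are reported with zero
    variance.  With few donors, donor-level factors (Status, Batch) compete
    for the same between-donor variance, so validation against known
    generative fractions is best done with the balanced Donor + Stimulus
    subset.  A constant response returns the flagged degenerate record with
    residual fraction 1.
    """
    y = np.asarray(y, dtype=float)
    labels = _effect_labels(factors, effects)
    names, zs = lmm.build_random_design(labels)
    if np.std(y) == 0:
        fraction = {name: 0.0 for name in ALL_COMPONENTS}
        fraction[lmm.RESIDUAL] = 1.0
        return VarianceComponents(
            gene_id=gene_id,
            sigma2={name: 0.0 for name in ALL_COMPONENTS},
            fraction=fraction,
            converged=False,
            backend="degenerate",
        )
    fit = lmm.reml_fit(y, zs, names)
    return _as_components(gene_id, fit)


def _as_components(gene_id: str, fit) -> VarianceComponents:
    """Expand a fit over a subset of effects to the full component map."""
    sigma2 = {name: 0.0 for name in ALL_COMPONENTS}
    fraction = {name: 0.0 for name in ALL_COMPONENTS}
    sigma2.update(fit.sigma2_dict())
    fraction.update(fit.fractions())
    return VarianceComponents(
        gene_id=gene_id,
        sigma2=sigma2,
        fraction=fraction,
        converged=fit.converged,
        backend=fit.backend,
    )


def _effect_labels(factors: pd.DataFrame, effects=EFFECTS) -> dict:
    stim = factors["stimulus"].astype(str).to_numpy()
    status = factors["status"].astype(str).to_numpy()
    all_labels = {
        "Stimulus": stim,
        "Status": status,
        "Batch": factors["batch"].astype(str).to_numpy(),
        "Donor": factors["donor"].astype(str).to_numpy(),
        "Stimulus:Status": np.char.add(np.char.add(stim, ":"), status),
    }
    unknown = set(effects) - set(all_labels)
    if unknown:
        raise ValueError(f"unknown effects {sorted(unknown)}")
    return {e: all_labels[e] for e in effects}


def partition_cell_type(
    pm: PseudocellMatrix,
    cell_type: str,
    transform: str = "log2p1",
    min_mean_cp100k: float = 1.0,
    effects=EFFECTS,
) -> tuple[list, VarPartSummary]:
    """Run the full per-gene decomposition for one cell type.

    Applies the expressed-gene filter, the expression transform and the
    per-gene mixed-model fit; the summary averages fractions over exactly
    the expressed genes and reports, per effect, the proportion of genes
    whose fraction exceeds 0.05 (strictly).
    """
    clusters = set(pm.factors["cluster"])
    if cell_type not in clusters:
        raise ValueError(f"cell type {cell_type!r} not in pseudocell matrix")
    sub = pm.subset_cluster(cell_type)
    expressed = filter_expressed_genes(sub, min_mean_cp100k)
    pool_size = int(sub.factors["pool_size"].iloc[0])
    iteration = int(sub.factors["iteration"].iloc[0])
    if len(expressed) == 0:
        logger.warning("%s: no expressed genes", cell_type)
        empty = VarPartSummary(
            cell_type=cell_type,
            pool_size=pool_size,
            iteration=iteration,
            n_genes=0,
            mean_fraction={},
            frac_genes_gt5={},
        )
        return [], empty

    gene_idx = {g: i for i, g in enumerate(sub.gene_ids)}
    expr = transform_expression(sub, transform)
    labels = _effect_labels(sub.factors, effects)
    names, zs = lmm.build_random_design(labels)

    results = []
    for g in expressed:
        y = expr[:, gene_idx[g]]
        if np.std(y) == 0:
            results.append(
                fit_variance_components(y, sub.factors, gene_id=g, effects=effects)
            )
            continue
        fit = lmm.reml_fit(y, zs, names)
        results.append(_as_components(g, fit))

    summary = summarize_components(results, cell_type, pool_size, iteration)
    return results, summary


def summarize_components(
    results: list, cell_type: str, pool_size: int, iteration: int
) -> VarPartSummary:
    """Mean fraction per effect and proportion of genes with fraction > 5%."""
    mean_fraction = {
        e: float(np.mean([r.fraction.get(e, 0.0) for r in results]))
        for e in ALL_COMPONENTS
    }
    frac_gt5 = {
        e: float(np.mean([r.fraction.get(e, 0.0) > 0.05 for r in results]))
        for e in ALL_COMPONENTS
    }
    return VarPartSummary(
        cell_type=cell_type,
        pool_size=pool_size,
        iteration=iteration,
        n_genes=len(results),
        mean_fraction=mean_fraction,
        frac_genes_gt5=frac_gt5,
    )


def rank_genes(
    results: list,
    effect: str,
    top_k: int = 100,
    by: str = "fraction",
    label: str | None = None,
) -> RankedGeneList:
    """Top genes for one effect, ranked by descending variance fraction.

    Ties are broken by descending raw variance, then lexicographic gene id.
    ``by="sigma2"`` ranks by the raw component instead.
    """
    if not results:
        raise ValueError("no variance component results to rank")
    if effect not in ALL_COMPONENTS:
        raise ValueError(f"unknown effect {effect!r}; expected one of {ALL_COMPONENTS}")
    if by not in ("fraction", "sigma2"):
        raise ValueError(f"unknown ranking key {by!r}")
    keyed = sorted(
        results,
        key=lambda r: (
            -(r.fraction[effect] if by == "fraction" else r.sigma2[effect]),
            -r.sigma2[effect],
            str(r.gene_id),
        ),
    )
    genes = [r.gene_id for r in keyed[:top_k]]
    return RankedGeneList(label or effect, tuple(genes))


def pooled_fraction(results: list, effect: str) -> float:
    """Pooled variance fraction of an effect across a block of genes.

    Ratio of the mean raw component to the mean total variance.  For genes
    sharing one generative fraction this pooled estimator avoids the
    downward Jensen bias that averaging per-gene ratios incurs when the
    effect has few levels (e.g. 8 donors), and is the quantity to compare
    against a known generative fraction.
    """
    if not results:
        raise ValueError("no results")
    if effect not in ALL_COMPONENTS:
        raise ValueError(f"unknown effect {effect!r}")
    num = float(np.mean([r.sigma2[effect] for r in results]))
    tot = float(np.mean([sum(r.sigma2.values()) for r in results]))
    return num / tot if tot > 0 else 0.0


def results_to_frame(results: list) -> pd.DataFrame:
    """Long-to-wide table of per-gene fractions and raw components."""
    rows = []
    for r in results:
        row = {"gene_id": r.gene_id, "converged": r.converged, "backend": r.backend}
        for e in ALL_COMPONENTS:
            row[f"fraction_{e}"] = r.fraction.get(e, np.nan)
            row[f"sigma2_{e}"] = r.sigma2.get(e, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
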