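"""Cell-type proportions per sample and the mixed ANOVA on them.

Each sample (one donor under one stimulus) contributes one row of cell-type
fractions.  Per cell type, a linear mixed model with fixed Stimulus, Status
and Stimulus:Status effects (sum-to-zero coding, so each 1-df F test is the
Type-III main effect) and random Donor and Batch intercepts is fitted by
REML; F tests use Satterthwaite denominator degrees of freedom.  Donor and
batch variance fractions are their components over the total variance.

The default response is the raw proportion; a logit option (with a
small-count-safe offset) is available for boundedness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lmm
from .io import CellAnnotation

logger = logging.getLogger("scpool")

__all__ = [
    "ProportionTable",
    "MixedAnovaResult",
    "compute_proportions",
    "fit_proportion_model",
    "fit_all_proportion_models",
    "summarize_donor_variance",
    "benjamini_hochberg",
]


@dataclass
class ProportionTable:
    """Samples x cell types fractions with per-sample factors.

    ``fractions`` rows sum to 1; ``factors`` has columns sample, donor,
    stimulus, status, batch aligned with the rows.
    """

    fractions: pd.DataFrame
    factors: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.fractions.to_numpy(dtype=float)
        if vals.size:
            if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
                raise ValueError("proportions outside [0, 1]")
            row_sums = vals.sum(axis=1)
            if not np.allclose(row_sums, 1.0, atol=1e-8):
                raise ValueError("proportion rows do not sum to 1")
        if len(self.fractions) != len(self.factors):
            raise ValueError("fractions and factors row counts differ")

    @property
    def cell_types(self) -> list:
        return list(self.fractions.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.factors.reset_index(drop=True), self.fractions.reset_index(drop=True)],
            axis=1,
        )


@dataclass
class MixedAnovaResult:
    """Fixed-effect F tests and random-effect variance fractions."""

    cell_type: str
    F_stimulus: float
    F_status: float
    F_interaction: float
    df_stimulus: float
    df_status: float
    df_interaction: float
    p_stimulus: float
    p_status: float
    p_interaction: float
    var_donor_fraction: float
    var_batch_fraction: float
    converged: bool
    backend: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def compute_proportions(annotation: CellAnnotation) -> ProportionTable:
    """Fraction of each sample's cells in each cluster.

    Only pass QC-retained cells.  Cell types absent from a sample get 0; a
    sample with zero cells is an error.
    """
    table = annotation.table.copy()
    table["sample"] = annotation.sample_labels()
    counts = (
        table.groupby(["sample", "cluster"], observed=True)
        .size()
        .unstack(fill_value=0)
        .sort_index(axis=1)
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("sample with zero cells")
    fractions = counts.div(totals, axis=0)
    meta = (
        table.groupby("sample", observed=True)[["donor", "stimulus", "status", "batch"]]
        .first()
        .loc[fractions.index]
        .reset_index()
    )
    return ProportionTable(
        fractions=fractions.reset_index(drop=True), factors=meta
    )


def _fixed_design(factors: pd.DataFrame) -> np.ndarray:
    """Sum-to-zero coded design: intercept, stimulus, status, interaction."""
    stim = np.where(factors["stimulus"].astype(str) == "TNF", 1.0, -1.0)
    status = np.where(factors["status"].astype(str) == "JIA", 1.0, -1.0)
    return np.column_stack([np.ones(len(factors)), stim, status, stim * status])


def fit_proportion_model(
    pt: ProportionTable,
    cell_type: str,
    transform: str = "identity",
) -> MixedAnovaResult:
    """Mixed ANOVA for one cell type's proportions.

    ``transform="logit"`` uses ``log(p* / (1 - p*))`` with the empirical
    shrinkage ``p* = (p n + 0.5) / (n + 1)`` (n = number of samples) to keep
    boundary proportions finite.
    """
    if cell_type not in pt.fractions.columns:
        raise ValueError(f"cell type {cell_type!r} not in proportion table")
    factors = pt.factors
    for col in ("stimulus", "status", "donor", "batch"):
        if factors[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has a single level")
    per_status = factors.groupby("status", observed=True)["donor"].nunique()
    if (per_status < 2).any():
        raise ValueError("need at least 2 donors per status level")

    y = pt.fractions[cell_type].to_numpy(dtype=float)
    if transform == "logit":
        n = len(y)
        p = (y * n + 0.5) / (n + 1.0)
        y = np.log(p / (1.0 - p))
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")

    X = _fixed_design(factors)
    names, zs = lmm.build_random_design(
        {
            "Donor": factors["donor"].astype(str).to_numpy(),
            "Batch": factors["batch"].astype(str).to_numpy(),
        }
    )
    fit = lmm.reml_fit(y, zs, names, X=X)
    if fit.backend == "MoM":
        logger.warning("%s: REML did not converge, method-of-moments fallback", cell_type)

    tests = {}
    for name, idx in (("stimulus", 1), ("status", 2), ("interaction", 3)):
        contrast = np.zeros(X.shape[1])
        contrast[idx] = 1.0
        tests[name] = lmm.wald_f_test(fit, zs, X, y, contrast)

    sigma2 = fit.sigma2_dict()
    total = sum(max(v, 0.0) for v in sigma2.values())
    donor_frac = max(sigma2.get("Donor", 0.0), 0.0) / total if total > 0 else 0.0
    batch_frac = max(sigma2.get("Batch", 0.0), 0.0) / total if total > 0 else 0.0
    return MixedAnovaResult(
        cell_type=cell_type,
        F_stimulus=tests["stimulus"][0],
        F_status=tests["status"][0],
        F_interaction=tests["interaction"][0],
        df_stimulus=tests["stimulus"][1],
        df_status=tests["status"][1],
        df_interaction=tests["interaction"][1],
        p_stimulus=tests["stimulus"][2],
        p_status=tests["status"][2],
        p_interaction=tests["interaction"][2],
        var_donor_fraction=donor_frac,
        var_batch_fraction=batch_frac,
        converged=fit.converged,
        backend=fit.backend,
    )


def fit_all_proportion_models(
    pt: ProportionTable, transform: str = "identity", bh_adjust: bool = False
) -> pd.DataFrame:
    """Univariate mixed ANOVA per cell type, one row each.

    ``bh_adjust=True`` appends Benjamini-Hochberg adjusted p-values per
    effect across cell types (off by default).
    """
    rows = [
        fit_proportion_model(pt, ct, transform).__dict__ for ct in pt.cell_types
    ]
    out = pd.DataFrame(rows)
    if bh_adjust:
        for eff in ("stimulus", "status", "interaction"):
            out[f"q_{eff}"] = benjamini_hochberg(out[f"p_{eff}"].to_numpy())
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def summarize_donor_variance(results: list) -> pd.DataFrame:
    """Per-cell-type donor/batch variance fractions with a >50% donor flag."""
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    for r in results:
        rows.append(
            {
                "cell_type": r.cell_type,
                "var_donor_fraction": r.var_donor_fraction,
                "var_batch_fraction": r.var_batch_fraction,
                "donor_majority": r.var_donor_fraction > 0.5,
            }
        )
    return pd.DataFrame(rows)
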