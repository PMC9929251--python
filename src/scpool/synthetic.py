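"""Synthetic datasets with the statistical structure the pooling pipeline
assumes.

The generator emulates a stimulation study design: 8 donors (6 cases, 2
controls), each cultured with and without stimulus (16 samples), processed
in 4 batches of 2 donors, with ~2,900 cells per sample spread over up to 17
cell types and sparse negative-binomial UMI counts.

Expression effects are drawn per gene on the log2 scale as zero-mean normal
donor / batch / stimulus / status / interaction intercepts whose variances
realize configured *variance fractions*.  Fractions are defined at the level
the downstream analysis operates on — pooled pseudocell expression for pools
of ``pool_size_ref`` cells: the per-cell residual variance is scaled up so
that averaging over a pool brings it back to the configured residual share,
and the predicted count-sampling noise at the reference pool size is
deducted from it.  The ground-truth record stores every drawn effect and
both the configured and the predicted realized fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellAnnotation, GeneExpressionMatrix
from .proportions import ProportionTable

__all__ = [
    "BlockConfig",
    "ProportionSimConfig",
    "SimulationConfig",
    "simulate_dataset",
    "simulate_proportions",
    "simulate_pseudocell_expression",
    "expected_log2_mean",
]

LN2 = np.log(2.0)
EFFECTS = ("donor", "batch", "stimulus", "status", "interaction")


@dataclass(frozen=True)
class BlockConfig:
    """A block of genes sharing effect fractions and dispersion."""

    n_genes: int
    fractions: dict = field(default_factory=dict)  # effect -> fraction of sigma2_base
    dispersion: float = 0.1                        # NB dispersion alpha

    def __post_init__(self) -> None:
        bad = set(self.fractions) - set(EFFECTS)
        if bad:
            raise ValueError(f"unknown effects in block: {sorted(bad)}")
        total = sum(self.fractions.values())
        if any(v < 0 for v in self.fractions.values()) or total > 1:
            raise ValueError(
                f"block fractions must be >= 0 and sum <= 1 (got sum {total})"
            )


@dataclass(frozen=True)
class ProportionSimConfig:
    """Parameters for per-sample cell-type composition.

    Shifts are differences on the proportion scale for the gaussian
    simulator (stimulated minus unstimulated, case minus control) and on the
    logit scale for the multinomial simulator.  Donor/batch heterogeneity is
    zero-mean normal on the matching scale.
    """

    baseline: tuple | None = None           # per-cell-type proportions
    stimulus_shift: dict = field(default_factory=dict)   # cell type -> delta
    status_shift: dict = field(default_factory=dict)
    interaction_shift: dict = field(default_factory=dict)
    sd_donor: float = 0.02
    sd_batch: float = 0.01
    sd_noise: float = 0.01
    sd_donor_logit: float = 0.15
    sd_batch_logit: float = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Full study-design configuration.

    Defaults mirror the emulated design: 8 donors split 6 cases / 2
    controls, 4 batches of 2 donors, stimulus crossed within donor, ~2,900
    cells per sample (Poisson-dispersed), 17 cell types, 2,000 genes.
    """

    n_donors: int = 8
    n_cases: int = 6
    n_batches: int = 4
    stimuli: tuple = ("Null", "TNF")
    n_cell_types: int = 17
    cells_per_sample: float = 2900.0
    n_genes: int = 2000
    blocks: tuple | None = None
    sigma2_base: float = 0.5        # total pseudocell-level log2 variance of a variable gene
    pool_size_ref: int = 10
    library_size: float = 1500.0    # mean UMI per cell
    baseline_sd: float = 1.5        # log2 spread of gene abundances
    n_mito_genes: int = 0
    mito_high_frac: float = 0.0     # fraction of cells corrupted to high mito content
    label_noise_frac: float = 0.0   # fraction of cells given inconsistent run labels
    proportions: ProportionSimConfig = field(default_factory=ProportionSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_cases < self.n_donors:
            raise ValueError("need at least one case and one control donor")
        if self.n_donors % self.n_batches:
            raise ValueError("n_donors must be divisible by n_batches")

    def resolved_blocks(self) -> tuple:
        """Default gene blocks: mostly invariant genes plus donor-,
        stimulus-, status- and interaction-driven blocks in proportions
        loosely echoing an immune stimulation experiment."""
        if self.blocks is not None:
            blocks = tuple(self.blocks)
        else:
            n = self.n_genes
            n_donor = int(0.15 * n)
            n_stim = int(0.10 * n)
            n_status = int(0.025 * n)
            n_inter = int(0.025 * n)
            n_null = n - n_donor - n_stim - n_status - n_inter
            blocks = (
                BlockConfig(n_null, {}),
                BlockConfig(n_donor, {"donor": 0.4, "batch": 0.1}),
                BlockConfig(n_stim, {"stimulus": 0.4, "donor": 0.1}),
                BlockConfig(n_status, {"status": 0.3}),
                BlockConfig(n_inter, {"interaction": 0.3}),
            )
        if sum(b.n_genes for b in blocks) != self.n_genes:
            raise ValueError("block gene counts do not sum to n_genes")
        return blocks

    def donor_table(self) -> pd.DataFrame:
        """Donor -> status / batch maps (round-robin batches, so statuses
        are spread over batches rather than confounded with one)."""
        donors, statuses = [], []
        for i in range(self.n_donors):
            if i < self.n_cases:
                donors.append(f"J-{i + 1:02d}")
                statuses.append("JIA")
            else:
                donors.append(f"C-{i - self.n_cases + 1:02d}")
                statuses.append("Control")
        batches = [str(i % self.n_batches + 1) for i in range(self.n_donors)]
        return pd.DataFrame({"donor": donors, "status": statuses, "batch": batches})

    def cell_type_names(self) -> list:
        return [f"CT{i + 1:02d}" for i in range(self.n_cell_types)]

    def baseline_proportions(self) -> np.ndarray:
        if self.proportions.baseline is not None:
            base = np.asarray(self.proportions.baseline, dtype=float)
            if len(base) != self.n_cell_types:
                raise ValueError("baseline proportions length != n_cell_types")
        else:
            base = 0.85 ** np.arange(self.n_cell_types)
        return base / base.sum()


# ---------------------------------------------------------------------------
# Count-level simulation
# ---------------------------------------------------------------------------

def _residual_cell_variance(
    r_target_log2, sampling_log2: np.ndarray, k: int
) -> np.ndarray:
    """Per-cell log2 residual variance whose pool-of-k average, plus the
    predicted sampling noise, realizes the target pseudocell residual.

    Inverts the lognormal pooled-mean variance approximation
    ``var(log mean of k) = log1p((e^v - 1) / k)``.
    """
    bio_log2 = np.clip(np.asarray(r_target_log2, dtype=float) - sampling_log2, 0.0, None)
    bio_ln = bio_log2 * LN2**2
    v_ln = np.log1p(k * np.expm1(bio_ln))
    return v_ln / LN2**2


def simulate_dataset(cfg: SimulationConfig):
    """Generate ``(GeneExpressionMatrix, CellAnnotation, ground_truth)``.

    Counts are negative binomial around per-cell means
    ``library_size * p_g * 2**(effects + cell noise)``; all randomness flows
    from ``cfg.seed``.  The ground-truth dict records the donor maps, every
    per-gene effect draw, the per-gene variance parameters and the predicted
    pseudocell-level fractions at ``pool_size_ref``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    blocks = cfg.resolved_blocks()
    donors = cfg.donor_table()
    n_genes = cfg.n_genes + cfg.n_mito_genes
    cell_types = cfg.cell_type_names()

    gene_ids = np.array(
        [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
        + [f"MT-{i + 1:02d}" for i in range(cfg.n_mito_genes)],
        dtype=object,
    )
    gene_symbols = gene_ids.copy()

    # gene relative abundances (log-normal over genes); mitochondrial genes
    # are given extra weight so the typical mito fraction is ~5%
    base_log2 = rng.normal(0.0, cfg.baseline_sd, size=n_genes)
    weights = 2.0 ** base_log2
    if cfg.n_mito_genes:
        w_main = weights[: cfg.n_genes].sum()
        weights[cfg.n_genes:] *= 0.05 * w_main / (0.95 * weights[cfg.n_genes:].sum())
    p_gene = weights / weights.sum()

    # per-gene variance parameters from the block structure
    k_ref = cfg.pool_size_ref
    sigma2 = {e: np.zeros(n_genes) for e in EFFECTS}
    dispersion = np.full(n_genes, 0.1)
    block_idx = np.zeros(n_genes, dtype=int)
    pos = 0
    for bi, block in enumerate(blocks):
        sl = slice(pos, pos + block.n_genes)
        for e in EFFECTS:
            sigma2[e][sl] = block.fractions.get(e, 0.0) * cfg.sigma2_base
        dispersion[sl] = block.dispersion
        block_idx[sl] = bi
        pos += block.n_genes
    resid_target = cfg.sigma2_base - sum(sigma2[e] for e in EFFECTS)

    m_pooled = k_ref * cfg.library_size * p_gene  # expected pooled count
    sampling_log2 = (1.0 / m_pooled + dispersion / k_ref) / LN2**2
    sigma2_cell = _residual_cell_variance(resid_target, sampling_log2, k_ref)

    # drawn level effects, one row per gene
    n_donor_lv, n_batch_lv = cfg.n_donors, cfg.n_batches
    u = {
        "donor": rng.normal(0, 1, (n_genes, n_donor_lv)) * np.sqrt(sigma2["donor"])[:, None],
        "batch": rng.normal(0, 1, (n_genes, n_batch_lv)) * np.sqrt(sigma2["batch"])[:, None],
        "stimulus": rng.normal(0, 1, (n_genes, 2)) * np.sqrt(sigma2["stimulus"])[:, None],
        "status": rng.normal(0, 1, (n_genes, 2)) * np.sqrt(sigma2["status"])[:, None],
        "interaction": rng.normal(0, 1, (n_genes, 4)) * np.sqrt(sigma2["interaction"])[:, None],
    }
    status_levels = ["Control", "JIA"]

    prop_cfg = cfg.proportions
    base_prop = cfg.baseline_proportions()
    logit_base = np.log(base_prop)

    counts_parts, ann_rows = [], []
    record_small = cfg.n_genes * int(cfg.cells_per_sample) <= 200_000
    log2_mean_rows = [] if record_small else None
    eps_rows = [] if record_small else None
    cell_counter = 0
    for di, drow in donors.iterrows():
        for si, stim in enumerate(cfg.stimuli):
            st_i = status_levels.index(drow["status"])
            inter_i = si * 2 + st_i
            dev_sample = (
                u["donor"][:, di]
                + u["batch"][:, int(drow["batch"]) - 1]
                + u["stimulus"][:, si]
                + u["status"][:, st_i]
                + u["interaction"][:, inter_i]
            )
            n_cells = int(rng.poisson(cfg.cells_per_sample))
            n_cells = max(n_cells, 1)
            # cell types from sample-specific multinomial (logit-scale shifts)
            logits = logit_base.copy()
            for c, ct in enumerate(cell_types):
                if stim == cfg.stimuli[1]:
                    logits[c] += prop_cfg.stimulus_shift.get(ct, 0.0)
                if drow["status"] == "JIA":
                    logits[c] += prop_cfg.status_shift.get(ct, 0.0)
                    if stim == cfg.stimuli[1]:
                        logits[c] += prop_cfg.interaction_shift.get(ct, 0.0)
            probs = np.exp(logits - logits.max())
            probs /= probs.sum()
            ct_draw = rng.choice(cfg.n_cell_types, size=n_cells, p=probs)

            eps = rng.normal(0, 1, (n_cells, n_genes)) * np.sqrt(sigma2_cell)[None, :]
            log2_mean = dev_sample[None, :] + eps
            mu = cfg.library_size * p_gene[None, :] * 2.0 ** log2_mean
            shape = 1.0 / np.clip(dispersion, 1e-9, None)
            lam = rng.gamma(shape[None, :], mu / shape[None, :])
            sample_counts = rng.poisson(lam)
            counts_parts.append(sp.csr_matrix(sample_counts))
            if log2_mean_rows is not None:
                log2_mean_rows.append(log2_mean)
                eps_rows.append(eps)

            for j in range(n_cells):
                ann_rows.append(
                    {
                        "cell_id": f"cell{cell_counter + j + 1:06d}",
                        "donor": drow["donor"],
                        "batch": drow["batch"],
                        "stimulus": stim,
                        "status": drow["status"],
                        "cluster": cell_types[ct_draw[j]],
                    }
                )
            cell_counter += n_cells

    counts = sp.vstack(counts_parts).tocsr()
    ann = pd.DataFrame(ann_rows)
    for col in ("cluster_run1", "cluster_run2", "cluster_run3", "cluster_run4"):
        ann[col] = ann["cluster"]

    # optional corruptions exercising the QC module
    n_cells_total = len(ann)
    corrupt = {}
    if cfg.mito_high_frac > 0 and cfg.n_mito_genes > 0:
        n_bad = int(round(cfg.mito_high_frac * n_cells_total))
        bad = rng.choice(n_cells_total, size=n_bad, replace=False)
        counts = counts.tolil()
        mito_cols = np.arange(cfg.n_genes, n_genes)
        for i in bad:
            row_total = counts[i].sum()
            boost = max(int(0.4 * row_total), 1)
            counts[i, mito_cols[0]] = counts[i, mito_cols[0]] + boost
        counts = counts.tocsr()
        corrupt["high_mito_cells"] = ann["cell_id"].iloc[bad].tolist()
    if cfg.label_noise_frac > 0:
        n_bad = int(round(cfg.label_noise_frac * n_cells_total))
        bad = rng.choice(n_cells_total, size=n_bad, replace=False)
        other = {ct: cell_types[(i + 1) % len(cell_types)] for i, ct in enumerate(cell_types)}
        for col in ("cluster_run1", "cluster_run2", "cluster_run3"):
            ann.loc[ann.index[bad], col] = ann.loc[ann.index[bad], "cluster"].map(other)
        corrupt["inconsistent_cells"] = ann["cell_id"].iloc[bad].tolist()

    matrix = GeneExpressionMatrix(
        counts=counts,
        cell_ids=ann["cell_id"].to_numpy(dtype=object),
        gene_ids=gene_ids,
        gene_symbols=gene_symbols,
    )
    annotation = CellAnnotation(
        ann, ("cluster_run1", "cluster_run2", "cluster_run3", "cluster_run4")
    )

    realized_resid = np.clip(resid_target, sampling_log2, None)
    total_pred = sum(sigma2[e] for e in EFFECTS) + realized_resid
    truth = {
        "config": cfg,
        "donor_table": donors,
        "gene_ids": gene_ids,
        "base_log2": base_log2,
        "p_gene": p_gene,
        "sigma2": sigma2,
        "sigma2_cell": sigma2_cell,
        "dispersion": dispersion,
        "block_index": block_idx,
        "effects": u,
        "sampling_log2_pred": sampling_log2,
        "fraction_pred": {e: sigma2[e] / total_pred for e in EFFECTS},
        "residual_fraction_pred": realized_resid / total_pred,
        "corruptions": corrupt,
    }
    if log2_mean_rows is not None:
        truth["log2_mean"] = np.vstack(log2_mean_rows)
        truth["cell_eps"] = np.vstack(eps_rows)
    return matrix, annotation, truth


def expected_log2_mean(truth, annotation: CellAnnotation) -> np.ndarray:
    """Recompute every cell x gene generative log2 deviation from the
    ground-truth record: drawn factor effects plus the recorded per-cell
    noise (available only for small simulations).

    The generative count mean is then
    ``library_size * p_gene * 2 ** expected_log2_mean``.
    """
    if "cell_eps" not in truth:
        raise ValueError("per-cell effects were not recorded for this simulation")
    cfg: SimulationConfig = truth["config"]
    donors = truth["donor_table"]
    u = truth["effects"]
    donor_idx = {d: i for i, d in enumerate(donors["donor"])}
    status_levels = ["Control", "JIA"]
    table = annotation.table
    dev = np.zeros((len(table), len(truth["gene_ids"])))
    for i, row in table.iterrows():
        di = donor_idx[row["donor"]]
        si = list(cfg.stimuli).index(row["stimulus"])
        st = status_levels.index(row["status"])
        dev[i] = (
            u["donor"][:, di]
            + u["batch"][:, int(row["batch"]) - 1]
            + u["stimulus"][:, si]
            + u["status"][:, st]
            + u["interaction"][:, si * 2 + st]
        )
    return dev + truth["cell_eps"]


# ---------------------------------------------------------------------------
# Pseudocell-level Gaussian simulation (direct variance-component test bed)
# ---------------------------------------------------------------------------

def simulate_pseudocell_expression(
    fractions: dict,
    n_genes: int = 200,
    pseudocells_per_sample: int = 10,
    sigma2_total: float = 1.0,
    n_donors: int = 8,
    n_cases: int = 6,
    n_batches: int = 4,
    seed: int = 0,
):
    """Gaussian pseudocell expression with exact generative fractions.

    Draws ``y = u_donor + u_batch + u_stimulus + u_status + u_interaction +
    eps`` directly at the pseudocell level for the standard crossed design;
    effect variances are ``fractions[e] * sigma2_total`` and the residual is
    the complement.  Returns ``(Y, factors, truth)`` with ``Y`` of shape
    (pseudocells, genes).
    """
    bad = set(fractions) - set(EFFECTS)
    if bad:
        raise ValueError(f"unknown effects: {sorted(bad)}")
    total_frac = sum(fractions.values())
    if total_frac > 1 or any(v < 0 for v in fractions.values()):
        raise ValueError("fractions must be >= 0 and sum <= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cfg = SimulationConfig(n_donors=n_donors, n_cases=n_cases, n_batches=n_batches)
    donors = cfg.donor_table()
    rows = []
    for di, drow in donors.iterrows():
        for si, stim in enumerate(("Null", "TNF")):
            for p in range(pseudocells_per_sample):
                rows.append(
                    {
                        "donor": drow["donor"],
                        "batch": drow["batch"],
                        "stimulus": stim,
                        "status": drow["status"],
                        "donor_i": di,
                        "stim_i": si,
                        "status_i": 0 if drow["status"] == "Control" else 1,
                        "batch_i": int(drow["batch"]) - 1,
                    }
                )
    factors = pd.DataFrame(rows)
    n = len(factors)
    var = {e: fractions.get(e, 0.0) * sigma2_total for e in EFFECTS}
    resid = (1.0 - total_frac) * sigma2_total
    u = {
        "donor": rng.normal(0, np.sqrt(var["donor"]) if var["donor"] else 0, (n_genes, n_donors)),
        "batch": rng.normal(0, np.sqrt(var["batch"]) if var["batch"] else 0, (n_genes, n_batches)),
        "stimulus": rng.normal(0, np.sqrt(var["stimulus"]) if var["stimulus"] else 0, (n_genes, 2)),
        "status": rng.normal(0, np.sqrt(var["status"]) if var["status"] else 0, (n_genes, 2)),
        "interaction": rng.normal(0, np.sqrt(var["interaction"]) if var["interaction"] else 0, (n_genes, 4)),
    }
    di = factors["donor_i"].to_numpy()
    bi = factors["batch_i"].to_numpy()
    si = factors["stim_i"].to_numpy()
    st = factors["status_i"].to_numpy()
    ii = si * 2 + st
    Y = (
        u["donor"][:, di]
        + u["batch"][:, bi]
        + u["stimulus"][:, si]
        + u["status"][:, st]
        + u["interaction"][:, ii]
        + rng.normal(0, np.sqrt(resid), (n_genes, n))
    ).T
    truth = {"variances": {**var, "residual": resid}, "effects": u}
    factors = factors[["donor", "batch", "stimulus", "status"]]
    return Y, factors, truth


# ---------------------------------------------------------------------------
# Proportion simulation
# ---------------------------------------------------------------------------

def simulate_proportions(cfg: SimulationConfig, mode: str = "gaussian"):
    """Per-sample cell-type proportions with configured effects.

    ``mode="gaussian"`` adds proportion-scale shifts and donor/batch/noise
    deviations directly (then renormalizes rows); ``mode="multinomial"``
    applies logit-scale shifts and draws multinomial counts of size
    ``cells_per_sample``.  Returns ``(ProportionTable, truth)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    donors = cfg.donor_table()
    p = cfg.proportions
    cell_types = cfg.cell_type_names()
    base = cfg.baseline_proportions()
    C = cfg.n_cell_types

    if mode == "gaussian":
        donor_dev = rng.normal(0, p.sd_donor, (cfg.n_donors, C))
        batch_dev = rng.normal(0, p.sd_batch, (cfg.n_batches, C))
    elif mode == "multinomial":
        donor_dev = rng.normal(0, p.sd_donor_logit, (cfg.n_donors, C))
        batch_dev = rng.normal(0, p.sd_batch_logit, (cfg.n_batches, C))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    shift = {
        "stimulus": np.array([p.stimulus_shift.get(ct, 0.0) for ct in cell_types]),
        "status": np.array([p.status_shift.get(ct, 0.0) for ct in cell_types]),
        "interaction": np.array([p.interaction_shift.get(ct, 0.0) for ct in cell_types]),
    }

    rows, meta = [], []
    for di, drow in donors.iterrows():
        bi = int(drow["batch"]) - 1
        is_case = drow["status"] == "JIA"
        for stim in cfg.stimuli:
            is_stim = stim == cfg.stimuli[1]
            eff = (
                is_stim * shift["stimulus"]
                + is_case * shift["status"]
                + (is_stim and is_case) * shift["interaction"]
            )
            if mode == "gaussian":
                noise = rng.normal(0, p.sd_noise, C)
                vec = base + eff + donor_dev[di] + batch_dev[bi] + noise
                vec = np.clip(vec, 1e-9, None)
                vec = vec / vec.sum()
            else:
                logits = np.log(base) + eff + donor_dev[di] + batch_dev[bi]
                probs = np.exp(logits - logits.max())
                probs /= probs.sum()
                n_cells = max(int(rng.poisson(cfg.cells_per_sample)), 1)
                counts = rng.multinomial(n_cells, probs)
                vec = counts / counts.sum()
            rows.append(vec)
            meta.append(
                {
                    "sample": f"{drow['donor']}_{stim}",
                    "donor": drow["donor"],
                    "stimulus": stim,
                    "status": drow["status"],
                    "batch": drow["batch"],
                }
            )
    fractions = pd.DataFrame(rows, columns=cell_types)
    factors = pd.DataFrame(meta)
    truth = {
        "baseline": base,
        "shifts": shift,
        "donor_dev": donor_dev,
        "batch_dev": batch_dev,
        "mode": mode,
    }
    return ProportionTable(fractions=fractions, factors=factors), truth
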