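"""Random pseudocell pooling of single cells and CP100K normalization.

Cells are partitioned at random within each stratum — one (donor, stimulus)
sample crossed with one cluster — into pools of a fixed size ``k``.  A
stratum of ``n`` cells yields exactly ``floor(n / k)`` pseudocells; the
``n mod k`` leftover cells of that iteration are left unassigned.  Pool
counts are the per-gene sums over member cells, then scaled to counts per
100,000 (CP100K).  The whole procedure is repeated for several independent
iterations to give pseudo-replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellAnnotation, GeneExpressionMatrix

__all__ = [
    "PseudocellAssignment",
    "PseudocellMatrix",
    "assign_pseudocells",
    "aggregate_counts",
    "normalize_cp100k",
    "run_scpool",
]

CP100K_SCALE = 1e5


@dataclass
class PseudocellAssignment:
    """Membership record for one pseudocell."""

    pseudocell_id: str
    donor: str
    stimulus: str
    cluster: str
    batch: str
    status: str
    iteration: int
    pool_size: int
    member_cell_ids: list

    def __post_init__(self) -> None:
        if len(self.member_cell_ids) != self.pool_size:
            raise ValueError(
                f"{self.pseudocell_id}: {len(self.member_cell_ids)} members "
                f"for pool size {self.pool_size}"
            )


@dataclass
class PseudocellMatrix:
    """Pseudocells x genes expression with provenance.

    ``cp100k`` rows sum to 100,000; ``raw`` retains the summed counts.
    ``factors`` carries one row per pseudocell (donor, batch, stimulus,
    status, cluster, iteration, pool_size).
    """

    raw: sp.csr_matrix
    cp100k: np.ndarray
    gene_ids: np.ndarray
    factors: pd.DataFrame
    assignments: list

    @property
    def n_pseudocells(self) -> int:
        return self.raw.shape[0]

    def subset_cluster(self, cluster) -> "PseudocellMatrix":
        mask = (self.factors["cluster"] == cluster).to_numpy()
        return PseudocellMatrix(
            raw=self.raw[mask],
            cp100k=self.cp100k[mask],
            gene_ids=self.gene_ids,
            factors=self.factors.loc[mask].reset_index(drop=True),
            assignments=[a for a, m in zip(self.assignments, mask) if m],
        )

    def to_frame(self) -> pd.DataFrame:
        frame = self.factors.copy()
        values = pd.DataFrame(self.cp100k, columns=list(self.gene_ids))
        return pd.concat([frame.reset_index(drop=True), values], axis=1)


def assign_pseudocells(
    annotation: CellAnnotation,
    k: int,
    iterations: int = 3,
    seed: int | np.random.SeedSequence = 0,
) -> list[PseudocellAssignment]:
    """Randomly partition each stratum into pools of exactly ``k`` cells.

    Each iteration draws an independent uniform random partition (shuffle
    then chunk) from the seeded stream; strata with fewer than ``k`` cells
    yield no pseudocells.  Iterations are numbered from 1.
    """
    if k < 1:
        raise ValueError("pool size k must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    table = annotation.table
    assignments: list[PseudocellAssignment] = []
    # sorted strata for a deterministic traversal order
    grouped = table.groupby(["donor", "stimulus", "cluster"], observed=True, sort=True)
    strata = [(key, grp) for key, grp in grouped]
    for iteration in range(1, iterations + 1):
        for (donor, stimulus, cluster), grp in strata:
            cell_ids = grp["cell_id"].to_numpy(dtype=object)
            n_pools = len(cell_ids) // k
            perm = rng.permutation(len(cell_ids))
            if n_pools == 0:
                continue
            batch = str(grp["batch"].iloc[0])
            status = str(grp["status"].iloc[0])
            for j in range(n_pools):
                members = cell_ids[perm[j * k : (j + 1) * k]]
                assignments.append(
                    PseudocellAssignment(
                        pseudocell_id=(
                            f"{donor}_{stimulus}_{cluster}_k{k}_it{iteration}_p{j + 1}"
                        ),
                        donor=str(donor),
                        stimulus=str(stimulus),
                        cluster=str(cluster),
                        batch=batch,
                        status=status,
                        iteration=iteration,
                        pool_size=k,
                        member_cell_ids=list(members),
                    )
                )
    return assignments


def aggregate_counts(
    matrix: GeneExpressionMatrix, assignments: list[PseudocellAssignment]
) -> sp.csr_matrix:
    """Sum member-cell counts per pseudocell (pseudocells x genes, integer)."""
    cell_idx = matrix.cell_index()
    rows, cols = [], []
    for i, a in enumerate(assignments):
        for c in a.member_cell_ids:
            if c not in cell_idx:
                raise KeyError(f"member cell {c!r} not found in matrix")
            rows.append(i)
            cols.append(cell_idx[c])
    pool = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(assignments), matrix.n_cells),
    )
    out = pool @ matrix.counts
    out = sp.csr_matrix(out)
    out.data = np.round(out.data)  # exact integers; guard float accumulation
    return out


def normalize_cp100k(raw) -> np.ndarray:
    """Scale each pseudocell row to counts per 100,000.

    Every row total must be positive; a zero-total pseudocell indicates an
    upstream fault (QC should have removed empty cells) and raises.
    """
    dense = np.asarray(raw.todense() if sp.issparse(raw) else raw, dtype=float)
    totals = dense.sum(axis=1)
    if (totals <= 0).any():
        bad = int(np.argmax(totals <= 0))
        raise ValueError(f"pseudocell row {bad} has zero total counts")
    return dense / totals[:, None] * CP100K_SCALE


def _build_pseudocell_matrix(matrix, assignments) -> PseudocellMatrix:
    raw = aggregate_counts(matrix, assignments)
    cp100k = normalize_cp100k(raw)
    factors = pd.DataFrame(
        {
            "pseudocell_id": [a.pseudocell_id for a in assignments],
            "donor": [a.donor for a in assignments],
            "batch": [a.batch for a in assignments],
            "stimulus": [a.stimulus for a in assignments],
            "status": [a.status for a in assignments],
            "cluster": [a.cluster for a in assignments],
            "iteration": [a.iteration for a in assignments],
            "pool_size": [a.pool_size for a in assignments],
        }
    )
    return PseudocellMatrix(
        raw=raw,
        cp100k=cp100k,
        gene_ids=matrix.gene_ids,
        factors=factors,
        assignments=list(assignments),
    )


def run_scpool(
    matrix: GeneExpressionMatrix,
    annotation: CellAnnotation,
    sizes=(5, 10, 15, 20),
    iterations: int = 3,
    seed: int = 0,
) -> dict:
    """Full pooling run: one :class:`PseudocellMatrix` per (size, iteration).

    QC is assumed to have been applied already.  Randomness flows from the
    single ``seed`` through one child stream per (size, iteration) so that
    adding a pool size never perturbs the draws of another.
    """
    base = np.random.SeedSequence(seed)
    out: dict[tuple[int, int], PseudocellMatrix] = {}
    for si, k in enumerate(sizes):
        children = base.spawn(len(sizes))[si].spawn(iterations)
        for it in range(1, iterations + 1):
            assignments = assign_pseudocells(
                annotation, k=k, iterations=1, seed=children[it - 1]
            )
            # stamp the true iteration number
            for a in assignments:
                a.iteration = it
                a.pseudocell_id = a.pseudocell_id.replace("_it1_", f"_it{it}_")
            if assignments:
                pm = _build_pseudocell_matrix(matrix, assignments)
                pm.factors["iteration"] = it
            else:
                pm = PseudocellMatrix(
                    raw=sp.csr_matrix((0, matrix.n_genes)),
                    cp100k=np.zeros((0, matrix.n_genes)),
                    gene_ids=matrix.gene_ids,
                    factors=pd.DataFrame(
                        columns=[
                            "pseudocell_id", "donor", "batch", "stimulus",
                            "status", "cluster", "iteration", "pool_size",
                        ]
                    ),
                    assignments=[],
                )
            out[(k, it)] = pm
    return out
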