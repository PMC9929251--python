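"""Concordance curves and the AUCC statistic between ranked gene lists.

For two ranked top-K lists the concordance curve is
``C[i] = |top_i(a) & top_i(b)|`` for i = 1..K.  The AUCC is the area under
this curve divided by a maximum-sharing denominator.  Two normalizations are
shipped:

- ``"paper"``: denominator K^2 / 2.  This is the published convention; note
  that two identical lists then score (K+1)/K (1.01 at K = 100), slightly
  above 1.
- ``"exact"``: denominator K (K + 1) / 2, the true maximum of the numerator,
  so identical lists score exactly 1.

The published description states the metric ranges from 0 to 1 while also
dividing by K^2/2; both conventions are therefore kept rather than silently
resolving the inconsistency, with ``"paper"`` the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("scpool")

__all__ = ["RankedGeneList", "concordance_curve", "aucc", "aucc_matrix"]


@dataclass(frozen=True)
class RankedGeneList:
    """An ordered list of unique gene ids with a label."""

    label: str
    genes: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.label}: duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.genes)

    def truncated(self, k: int) -> "RankedGeneList":
        return RankedGeneList(self.label, self.genes[:k])


def _common_length(a: RankedGeneList, b: RankedGeneList) -> int:
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty ranked list")
    if len(a) != len(b):
        logger.warning(
            "ranked lists %s (%d) and %s (%d) differ in length: truncating",
            a.label, len(a), b.label, len(b),
        )
    return min(len(a), len(b))


def concordance_curve(a: RankedGeneList, b: RankedGeneList) -> np.ndarray:
    """Cumulative prefix overlap ``C[i] = |top_i(a) & top_i(b)|``, i = 1..K.

    Computed in O(K) via the rank of each shared gene in both lists: a gene
    enters the intersection at prefix ``max(rank_a, rank_b)``.
    """
    k = _common_length(a, b)
    rank_b = {g: i for i, g in enumerate(b.genes[:k])}
    entry = [
        max(i, rank_b[g]) for i, g in enumerate(a.genes[:k]) if g in rank_b
    ]
    curve = np.zeros(k, dtype=int)
    if entry:
        counts = np.bincount(np.asarray(entry), minlength=k)
        curve = np.cumsum(counts)
    return curve


def aucc(a: RankedGeneList, b: RankedGeneList, normalization: str = "paper") -> float:
    """Area under the concordance curve, normalized.

    ``normalization="paper"`` divides by K^2/2; ``"exact"`` divides by
    K(K+1)/2 so that identical lists score exactly 1.
    """
    curve = concordance_curve(a, b)
    k = len(curve)
    area = float(curve.sum())
    if normalization == "paper":
        return area / (k**2 / 2.0)
    if normalization == "exact":
        return area / (k * (k + 1) / 2.0)
    raise ValueError(f"unknown normalization {normalization!r}")


def aucc_matrix(lists, normalization: str = "paper") -> pd.DataFrame:
    """Symmetric pairwise AUCC matrix over a collection of ranked lists."""
    lists = list(lists)
    if len(lists) < 2:
        raise ValueError("need at least two ranked lists")
    labels = [x.label for x in lists]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate list labels")
    n = len(lists)
    out = np.zeros((n, n))
    for i in range(n):
        out[i, i] = aucc(lists[i], lists[i], normalization)
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = aucc(lists[i], lists[j], normalization)
    return pd.DataFrame(out, index=labels, columns=labels)
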