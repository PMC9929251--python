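import numpy as np
import pandas as pd
import pytest

from scpool import (
    fit_variance_components,
    partition_cell_type,
    rank_genes,
    simulate_pseudocell_expression,
    transform_expression,
)
from scpool.pooling import PseudocellMatrix
from scpool.varpart import (
    ALL_COMPONENTS,
    VarianceComponents,
    filter_expressed_genes,
    pooled_fraction,
    results_to_frame,
    summarize_components,
)

import scipy.sparse as sp


def pm_from_values(values, clusters=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    clusters = clusters or ["T"] * n
    factors = pd.DataFrame(
        {
            "pseudocell_id": [f"p{i}" for i in range(n)],
            "donor": ["J-01"] * n,
            "batch": ["1"] * n,
            "stimulus": ["TNF"] * n,
            "status": ["JIA"] * n,
            "cluster": clusters,
            "iteration": [1] * n,
            "pool_size": [5] * n,
        }
    )
    return PseudocellMatrix(
        raw=sp.csr_matrix(values),
        cp100k=values,
        gene_ids=np.array(gene_ids or [f"g{j}" for j in range(g)], dtype=object),
        factors=factors,
        assignments=[None] * n,
    )


class TestExpressedFilter:
    def test_boundary_inclusive(self):
        pm = pm_from_values([[1.0], [1.0], [1.0]])
        assert list(filter_expressed_genes(pm)) == ["g0"]

    def test_below_threshold_excluded(self):
        pm = pm_from_values([[0.5], [0.5], [0.5]])
        assert len(filter_expressed_genes(pm)) == 0

    def test_mean_not_minimum(self):
        pm = pm_from_values([[0.0, 0.0], [0.0, 0.0], [3.3, 0.9]])
        assert list(filter_expressed_genes(pm)) == ["g0"]  # mean 1.1 vs 0.3


class TestTransform:
    def test_log2p1_anchors(self):
        pm = pm_from_values([[0.0, 1.0, 3.0]])
        out = transform_expression(pm)
        assert out[0, 0] == 0.0
        assert out[0, 1] == 1.0  # log2(2)
        assert out[0, 2] == pytest.approx(2.0)

    def test_raw_identity(self):
        pm = pm_from_values([[0.0, 5.0]])
        assert np.array_equal(transform_expression(pm, "raw"), pm.cp100k)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            transform_expression(pm_from_values([[1.0]]), "sqrt")


def vc(gene, fractions, sigma2=None):
    fr = {e: 0.0 for e in ALL_COMPONENTS}
    fr.update(fractions)
    fr["Residual"] = 1.0 - sum(v for k, v in fr.items() if k != "Residual")
    s2 = {e: fr[e] for e in ALL_COMPONENTS}
    if sigma2:
        s2.update(sigma2)
    return VarianceComponents(gene, s2, fr, True, "REML")


class TestSummaries:
    def test_mean_fraction_arithmetic(self):
        results = [vc("a", {"Donor": 0.4}), vc("b", {"Donor": 0.6})]
        summary = summarize_components(results, "T", 5, 1)
        assert summary.mean_fraction["Donor"] == pytest.approx(0.5)
        assert summary.n_genes == 2

    def test_gt5_threshold_strict(self):
        results = [vc("a", {"Donor": 0.04}), vc("b", {"Donor": 0.06})]
        summary = summarize_components(results, "T", 5, 1)
        assert summary.frac_genes_gt5["Donor"] == pytest.approx(0.5)

    def test_mean_fractions_sum_to_one(self):
        results = [vc("a", {"Donor": 0.3, "Batch": 0.2}), vc("b", {"Stimulus": 0.5})]
        summary = summarize_components(results, "T", 5, 1)
        assert sum(summary.mean_fraction.values()) == pytest.approx(1.0)

    def test_results_frame_columns(self):
        frame = results_to_frame([vc("a", {"Donor": 0.3})])
        assert "fraction_Donor" in frame.columns
        assert "sigma2_Residual" in frame.columns


class TestRankGenes:
    def test_top_one(self):
        results = [vc("gA", {"Donor": 0.3}), vc("gB", {"Donor": 0.7})]
        assert rank_genes(results, "Donor", top_k=1).genes == ("gB",)

    def test_tie_broken_by_raw_sigma2(self):
        a = vc("gA", {"Donor": 0.5}, sigma2={"Donor": 2.0})
        b = vc("gB", {"Donor": 0.5}, sigma2={"Donor": 1.0})
        assert rank_genes([b, a], "Donor", top_k=2).genes == ("gA", "gB")

    def test_k_larger_than_gene_count(self):
        results = [vc("gA", {"Donor": 0.3}), vc("gB", {"Donor": 0.7})]
        assert len(rank_genes(results, "Donor", top_k=100)) == 2

    def test_unknown_effect(self):
        with pytest.raises(ValueError):
            rank_genes([vc("gA", {})], "Treatment")


class TestFitVarianceComponents:
    def test_constant_gene_is_pure_residual(self):
        factors = pd.DataFrame(
            {
                "stimulus": ["TNF", "Null"] * 4,
                "status": ["JIA"] * 8,
                "batch": ["1"] * 8,
                "donor": ["J-01", "J-02"] * 4,
            }
        )
        res = fit_variance_components(np.ones(8), factors, gene_id="flat")
        assert res.fraction["Residual"] == 1.0
        assert not res.converged

    def test_fractions_valid_on_noise(self):
        Y, factors, _ = simulate_pseudocell_expression({}, n_genes=3, seed=0)
        for g in range(3):
            res = fit_variance_components(Y[:, g], factors)
            assert sum(res.fraction.values()) == pytest.approx(1.0, abs=1e-6)
            assert all(0 <= v <= 1 for v in res.fraction.values())

    def test_donor_signal_recovered_balanced_model(self):
        """Mean per-gene donor fraction for a 0.5 generative fraction stays
        within the +-0.1 band expected from an 8-donor panel."""
        Y, factors, _ = simulate_pseudocell_expression(
            {"donor": 0.5}, n_genes=40, pseudocells_per_sample=10, seed=21
        )
        res = [
            fit_variance_components(Y[:, g], factors, effects=("Donor", "Stimulus"))
            for g in range(Y.shape[1])
        ]
        mean_fraction = np.mean([r.fraction["Donor"] for r in res])
        assert abs(mean_fraction - 0.5) < 0.1
        assert abs(pooled_fraction(res, "Donor") - 0.5) < 0.1

    def test_pure_noise_has_low_donor_fraction(self):
        Y, factors, _ = simulate_pseudocell_expression({}, n_genes=30, seed=8)
        res = [fit_variance_components(Y[:, g], factors) for g in range(30)]
        assert np.mean([r.fraction["Donor"] for r in res]) <= 0.1

    def test_added_noise_shrinks_signal_fractions(self):
        """Adding i.i.d. noise to every pseudocell dilutes the donor
        fraction (monotonicity, checked statistically over genes)."""
        rng = np.random.default_rng(12)
        Y, factors, _ = simulate_pseudocell_expression(
            {"donor": 0.5}, n_genes=30, seed=12
        )
        base, noisy = [], []
        for g in range(Y.shape[1]):
            y = Y[:, g]
            base.append(
                fit_variance_components(y, factors, effects=("Donor",)).fraction["Donor"]
            )
            y2 = y + rng.normal(0, 1.0, len(y))
            noisy.append(
                fit_variance_components(y2, factors, effects=("Donor",)).fraction["Donor"]
            )
        assert np.mean(noisy) < np.mean(base)


class TestPartitionCellType:
    def test_absent_cell_type_raises(self):
        pm = pm_from_values([[2.0]])
        with pytest.raises(ValueError, match="NK"):
            partition_cell_type(pm, "NK")

    def test_empty_expressed_set(self):
        pm = pm_from_values(np.full((4, 2), 0.2))
        results, summary = partition_cell_type(pm, "T")
        assert results == []
        assert summary.n_genes == 0
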