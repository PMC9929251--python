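import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scpool import (
    aggregate_counts,
    assign_pseudocells,
    normalize_cp100k,
    run_scpool,
)
from scpool.pooling import CP100K_SCALE

from conftest import make_annotation, make_matrix


def stratum_annotation(n, donor="J-01"):
    return make_annotation(n, clusters=["T"] * n, donors=[donor] * n)


class TestAssign:
    @pytest.mark.parametrize("k,expected", [(5, 12), (10, 6), (15, 4), (20, 3)])
    def test_63_cell_stratum(self, k, expected):
        """A 63-cell stratum supports 12, 6, 4 and 3 pools of 5/10/15/20."""
        ann = stratum_annotation(63)
        assignments = assign_pseudocells(ann, k=k, iterations=1, seed=0)
        assert len(assignments) == expected
        used = [c for a in assignments for c in a.member_cell_ids]
        assert len(used) == len(set(used)) == expected * k

    def test_stratum_smaller_than_k_yields_none(self):
        ann = stratum_annotation(4)
        assert assign_pseudocells(ann, k=5, iterations=1, seed=0) == []

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n=st.integers(1, 80), k=st.integers(1, 25), seed=st.integers(0, 10))
    def test_partition_property(self, n, k, seed):
        ann = stratum_annotation(n)
        assignments = assign_pseudocells(ann, k=k, iterations=1, seed=seed)
        assert len(assignments) == n // k
        members = [c for a in assignments for c in a.member_cell_ids]
        assert len(members) == len(set(members))
        for a in assignments:
            assert len(a.member_cell_ids) == k

    def test_iterations_are_independent_draws(self):
        ann = stratum_annotation(40)
        assignments = assign_pseudocells(ann, k=10, iterations=2, seed=1)
        its = {a.iteration for a in assignments}
        assert its == {1, 2}
        first = [set(a.member_cell_ids) for a in assignments if a.iteration == 1]
        second = [set(a.member_cell_ids) for a in assignments if a.iteration == 2]
        assert first != second  # re-shuffled (overwhelmingly likely)

    def test_exchangeability_of_cell_order(self):
        ann = stratum_annotation(47)
        shuffled = ann.table.sample(frac=1.0, random_state=3)
        from scpool import CellAnnotation
        ann2 = CellAnnotation(shuffled)
        a1 = assign_pseudocells(ann, k=10, iterations=1, seed=5)
        a2 = assign_pseudocells(ann2, k=10, iterations=1, seed=5)
        assert len(a1) == len(a2) == 4

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            assign_pseudocells(stratum_annotation(5), k=0, iterations=1, seed=0)


class TestAggregate:
    def test_summation(self):
        counts = np.full((5, 3), 2)
        m = make_matrix(counts)
        ann = stratum_annotation(5)
        (a,) = assign_pseudocells(ann, k=5, iterations=1, seed=0)
        raw = aggregate_counts(m, [a])
        assert (raw.toarray() == 10).all()

    def test_row_total_is_sum_of_member_totals(self):
        rng = np.random.default_rng(0)
        totals = [100, 150, 250, 300, 200]
        counts = np.array([rng.multinomial(t, [0.25] * 4) for t in totals])
        m = make_matrix(counts)
        (a,) = assign_pseudocells(stratum_annotation(5), k=5, iterations=1, seed=0)
        raw = aggregate_counts(m, [a])
        assert raw.sum() == 1000

    def test_all_zero_members(self):
        m = make_matrix(np.zeros((5, 2), dtype=int))
        (a,) = assign_pseudocells(stratum_annotation(5), k=5, iterations=1, seed=0)
        assert aggregate_counts(m, [a]).nnz == 0

    def test_unknown_cell_raises(self):
        m = make_matrix(np.ones((5, 2), dtype=int))
        (a,) = assign_pseudocells(stratum_annotation(5), k=5, iterations=1, seed=0)
        a.member_cell_ids[0] = "nope"
        with pytest.raises(KeyError, match="nope"):
            aggregate_counts(m, [a])


class TestNormalize:
    def test_forced_by_formula(self):
        out = normalize_cp100k(np.array([[1.0, 1.0, 2.0]]))
        assert np.allclose(out, [[25_000, 25_000, 50_000]])

    def test_identity_at_scale(self):
        row = np.array([[60_000.0, 40_000.0]])
        assert np.allclose(normalize_cp100k(row), row)

    def test_single_expressed_gene(self):
        assert np.allclose(
            normalize_cp100k(np.array([[3.0, 0.0, 0.0]])), [[CP100K_SCALE, 0, 0]]
        )

    def test_rows_sum_to_scale(self):
        rng = np.random.default_rng(1)
        raw = rng.poisson(5, size=(20, 30)) + 1
        out = normalize_cp100k(raw.astype(float))
        assert np.allclose(out.sum(axis=1), CP100K_SCALE, atol=1e-6)

    def test_zero_row_raises(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_cp100k(np.array([[0.0, 0.0]]))


class TestRunScpool:
    def test_cardinality_and_determinism(self, small_dataset):
        _, matrix, annotation, _ = small_dataset
        out1 = run_scpool(matrix, annotation, sizes=[5, 20], iterations=3, seed=9)
        out2 = run_scpool(matrix, annotation, sizes=[5, 20], iterations=3, seed=9)
        assert set(out1) == {(5, 1), (5, 2), (5, 3), (20, 1), (20, 2), (20, 3)}
        for key in out1:
            assert (out1[key].raw != out2[key].raw).nnz == 0
            assert list(out1[key].factors["pseudocell_id"]) == list(
                out2[key].factors["pseudocell_id"]
            )

    def test_conservation(self, small_dataset):
        _, matrix, annotation, _ = small_dataset
        out = run_scpool(matrix, annotation, sizes=[5], iterations=1, seed=9)
        pm = out[(5, 1)]
        cell_totals = dict(zip(matrix.cell_ids, matrix.total_counts_per_cell()))
        raw_totals = np.asarray(pm.raw.sum(axis=1)).ravel()
        for i, a in enumerate(pm.assignments):
            assert raw_totals[i] == sum(cell_totals[c] for c in a.member_cell_ids)
        assert pm.raw.sum() <= matrix.counts.sum()

    def test_cp100k_rows(self, small_dataset):
        _, matrix, annotation, _ = small_dataset
        out = run_scpool(matrix, annotation, sizes=[10], iterations=2, seed=2)
        for pm in out.values():
            if pm.n_pseudocells:
                assert np.allclose(pm.cp100k.sum(axis=1), CP100K_SCALE, atol=1e-6)

    def test_pseudocell_id_scheme(self, small_dataset):
        _, matrix, annotation, _ = small_dataset
        out = run_scpool(matrix, annotation, sizes=[5], iterations=2, seed=2)
        pm = out[(5, 2)]
        a = pm.assignments[0]
        assert a.pseudocell_id == (
            f"{a.donor}_{a.stimulus}_{a.cluster}_k5_it2_p1"
        )
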