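"""MI estimator, DPI pruning and top-k retention against brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexpnet.inference import (
    InferenceConfig,
    MITable,
    auto_bins,
    dpi_prune,
    infer_network,
    mi_matrix,
    mutual_information,
    quantile_bin,
    top_k_edges,
)


def brute_force_mi(x, y, n_bins):
    """Independent plug-in MI: explicit double sum over the joint table
    of quantile-bin assignments."""
    bx, by = quantile_bin(np.asarray(x), n_bins), quantile_bin(np.asarray(y), n_bins)
    n = len(bx)
    total = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            nij = int(np.sum((bx == i) & (by == j)))
            if nij == 0:
                continue
            ni = int(np.sum(bx == i))
            nj = int(np.sum(by == j))
            total += (nij / n) * math.log((nij * n) / (ni * nj))
    return total


class TestMutualInformation:
    def test_perfect_dependence_is_ln2(self):
        x = np.arange(8.0)
        assert mutual_information(x, 2 * x, 2) == pytest.approx(math.log(2), abs=1e-12)

    def test_constant_vector_gives_zero(self):
        x = np.arange(12.0)
        assert mutual_information(x, np.full(12, 3.0), 3) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n_bins", [2, 3])
    def test_matches_brute_force_on_small_fixtures(self, seed, n_bins):
        rng = np.random.default_rng(seed)
        n = rng.integers(4 * n_bins, 13)
        x, y = rng.normal(size=n), rng.normal(size=n)
        assert mutual_information(x, y, n_bins) == pytest.approx(
            brute_force_mi(x, y, n_bins), abs=1e-12
        )

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert mutual_information(x, y, 3) == pytest.approx(
            mutual_information(y, x, 3), abs=1e-12
        )

    @pytest.mark.parametrize(
        "transform", [np.exp, lambda v: v**3, lambda v: 5 * v - 2], ids=["exp", "cube", "affine"]
    )
    def test_invariant_under_strictly_monotone_transforms(self, transform):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=40), rng.normal(size=40)
        base = mutual_information(x, y, 4)
        assert mutual_information(transform(x), y, 4) == pytest.approx(base, abs=1e-12)
        assert mutual_information(x, transform(y), 4) == pytest.approx(base, abs=1e-12)

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="samples"):
            mutual_information(np.arange(7.0), np.arange(7.0), 2)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal length"):
            mutual_information(np.arange(10.0), np.arange(9.0), 2)

    def test_auto_bins_respects_sample_floor(self):
        for n in range(8, 500):
            assert 4 * auto_bins(n) <= n
            assert 2 <= auto_bins(n) <= 20


class TestMIMatrix:
    def test_entries_match_pairwise_calls(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(rng.normal(size=(5, 30)),
                              index=[f"g{i}" for i in range(5)])
        table = mi_matrix(matrix, InferenceConfig(n_bins=3))
        for i, j in itertools.combinations(range(5), 2):
            expected = mutual_information(matrix.iloc[i], matrix.iloc[j], 3)
            assert table.values[i, j] == pytest.approx(expected, abs=1e-10)
            assert table.values[j, i] == pytest.approx(expected, abs=1e-10)
        assert np.isnan(np.diag(table.values)).all()

    def test_two_genes_single_value(self):
        rng = np.random.default_rng(4)
        matrix = pd.DataFrame(rng.normal(size=(2, 24)), index=["a", "b"])
        table = mi_matrix(matrix, InferenceConfig(n_bins=2))
        assert table.values[0, 1] == pytest.approx(
            mutual_information(matrix.iloc[0], matrix.iloc[1], 2), abs=1e-12
        )

    def test_row_permutation_relabels_only(self):
        rng = np.random.default_rng(7)
        matrix = pd.DataFrame(rng.normal(size=(6, 40)),
                              index=[f"g{i}" for i in range(6)])
        perm = [3, 0, 5, 1, 4, 2]
        t1 = mi_matrix(matrix, InferenceConfig(n_bins=3))
        t2 = mi_matrix(matrix.iloc[perm], InferenceConfig(n_bins=3))
        inv = np.argsort(perm)
        np.testing.assert_allclose(
            t2.values[np.ix_(inv, inv)], t1.values, atol=1e-12
        )


def exhaustive_dpi(table: MITable, eps: float) -> MITable:
    """Oracle: check every triple explicitly against the input table."""
    m = table.values
    n = m.shape[0]
    out = m.copy()
    for i, j in itertools.combinations(range(n), 2):
        if np.isnan(m[i, j]):
            continue
        for k in range(n):
            if k in (i, j) or np.isnan(m[i, k]) or np.isnan(m[j, k]):
                continue
            if m[i, j] < min(m[i, k], m[j, k]) * (1 - eps):
                out[i, j] = out[j, i] = np.nan
                break
    return MITable(list(table.genes), out)


class TestDPI:
    def test_weakest_triangle_edge_removed(self):
        genes = ["a", "b", "c"]
        m = np.array([[np.nan, 0.9, 0.3], [0.9, np.nan, 0.8], [0.3, 0.8, np.nan]])
        pruned = dpi_prune(MITable(genes, m))
        assert np.isnan(pruned.values[0, 2]) and np.isnan(pruned.values[2, 0])
        assert pruned.values[0, 1] == 0.9 and pruned.values[1, 2] == 0.8

    def test_no_complete_triangle_unchanged(self):
        genes = ["a", "b", "c", "d"]
        m = np.full((4, 4), np.nan)
        m[0, 1] = m[1, 0] = 0.5
        m[2, 3] = m[3, 2] = 0.2
        pruned = dpi_prune(MITable(genes, m))
        np.testing.assert_array_equal(np.isnan(pruned.values), np.isnan(m))

    def test_equilateral_triangle_survives(self):
        m = np.full((3, 3), 0.7)
        np.fill_diagonal(m, np.nan)
        pruned = dpi_prune(MITable(["a", "b", "c"], m))
        assert not np.isnan(pruned.values[0, 1])
        assert not np.isnan(pruned.values[0, 2])
        assert not np.isnan(pruned.values[1, 2])

    @pytest.mark.parametrize("eps", [0.0, 0.1])
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_triple_oracle(self, seed, eps):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        m = rng.uniform(0, 1, size=(n, n))
        m = (m + m.T) / 2
        m[rng.uniform(size=(n, n)) < 0.2] = np.nan
        m = np.where(np.isnan(m) | np.isnan(m.T), np.nan, m)
        np.fill_diagonal(m, np.nan)
        table = MITable([f"g{i}" for i in range(n)], m)
        got = dpi_prune(table, eps)
        want = exhaustive_dpi(table, eps)
        np.testing.assert_array_equal(np.isnan(got.values), np.isnan(want.values))

    def test_never_adds_edges(self):
        rng = np.random.default_rng(11)
        m = rng.uniform(0, 1, size=(7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, np.nan)
        table = MITable([f"g{i}" for i in range(7)], m)
        pruned = dpi_prune(table)
        assert (np.isnan(pruned.values) | ~np.isnan(table.values)).all()

    def test_gene_order_independence(self):
        rng = np.random.default_rng(13)
        m = rng.uniform(0, 1, size=(6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, np.nan)
        genes = [f"g{i}" for i in range(6)]
        perm = [4, 2, 0, 5, 1, 3]
        direct = dpi_prune(MITable(genes, m))
        permuted = dpi_prune(MITable([genes[p] for p in perm], m[np.ix_(perm, perm)]))
        inv = np.argsort(perm)
        np.testing.assert_array_equal(
            np.isnan(permuted.values[np.ix_(inv, inv)]), np.isnan(direct.values)
        )

    def test_negative_tolerance_raises(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, np.nan)
        with pytest.raises(ValueError, match="tolerance"):
            dpi_prune(MITable(["a", "b", "c"], m), tolerance=-0.1)


def brute_force_top_k(table: MITable, k: int):
    """Oracle: rank all present pairs by (-mi, pair) and take the head."""
    pairs = []
    n = len(table.genes)
    for i, j in itertools.combinations(range(n), 2):
        if not np.isnan(table.values[i, j]):
            a, b = sorted((table.genes[i], table.genes[j]))
            pairs.append(((a, b), table.values[i, j]))
    pairs.sort(key=lambda pw: (-pw[1], pw[0]))
    return pairs[:k]


class TestTopK:
    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("k", [1, 3, 7, 100])
    def test_matches_sort_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        m = rng.choice([0.2, 0.5, 0.8], size=(n, n))  # deliberate ties
        m = np.triu(m, 1) + np.triu(m, 1).T
        np.fill_diagonal(m, np.nan)
        m[m == 0] = np.nan
        table = MITable([f"g{i}" for i in range(n)], m)
        want = brute_force_top_k(table, k)
        got = top_k_edges(table, k)
        assert [(p, w) for p, w in got.edges.items()] == want

    def test_k_ge_pairs_keeps_all(self):
        m = np.array([[np.nan, 0.1, 0.2], [0.1, np.nan, 0.3], [0.2, 0.3, np.nan]])
        net = top_k_edges(MITable(["a", "b", "c"], m), 100)
        assert len(net) == 3

    def test_monotone_in_k(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(size=(8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, np.nan)
        table = MITable([f"g{i}" for i in range(8)], m)
        for k in range(1, 28):
            assert top_k_edges(table, k).pairs <= top_k_edges(table, k + 1).pairs

    def test_invalid_k_raises(self):
        m = np.array([[np.nan, 0.5], [0.5, np.nan]])
        with pytest.raises(ValueError, match="k"):
            top_k_edges(MITable(["a", "b"], m), 0)


class TestInferNetwork:
    def test_composition_without_dpi(self):
        rng = np.random.default_rng(9)
        matrix = pd.DataFrame(rng.normal(size=(6, 32)),
                              index=[f"g{i}" for i in range(6)])
        cfg = InferenceConfig(k=5, n_bins=3, dpi_enabled=False)
        net = infer_network(matrix, cfg)
        table = mi_matrix(matrix, cfg)
        assert net.edges == top_k_edges(table, 5).edges

    def test_composition_with_dpi(self):
        rng = np.random.default_rng(10)
        matrix = pd.DataFrame(rng.normal(size=(6, 32)),
                              index=[f"g{i}" for i in range(6)])
        cfg = InferenceConfig(k=5, n_bins=3, dpi_enabled=True)
        net = infer_network(matrix, cfg)
        expected = top_k_edges(dpi_prune(mi_matrix(matrix, cfg)), 5)
        assert net.edges == expected.edges

    def test_deterministic_across_runs(self, tmp_path):
        rng = np.random.default_rng(12)
        matrix = pd.DataFrame(rng.normal(size=(10, 40)),
                              index=[f"g{i}" for i in range(10)])
        cfg = InferenceConfig(k=20, n_bins=3)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        infer_network(matrix, cfg).write_tsv(p1)
        infer_network(matrix, cfg).write_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()
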