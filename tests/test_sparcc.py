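"""SparCC basis correlations, permutation nulls, edge calling, and
network metrics."""

import numpy as np
import pandas as pd
import pytest

from propstab.sparcc import (
    BasisEstimate,
    _basis_iteration,
    _dirichlet_fractions,
    _variation_matrix,
    build_network,
    connected_components,
    degree_distribution,
    edge_threshold,
    infer_network,
    network_summary,
    pseudo_p_values,
    shuffle_null,
    shuffle_table,
    sparcc_correlations,
)


def lognormal_counts(rng, D=30, n=100, rho=0.0, pair=(0, 1), depth=5000):
    """Compositional counts from a log-normal basis with one optional
    correlated pair."""
    mu = rng.normal(0, 1, D)
    Z = rng.normal(size=(n, D))
    i, j = pair
    Z[:, j] = rho * Z[:, i] + np.sqrt(1 - rho ** 2) * Z[:, j]
    ab = np.exp(mu + Z)
    frac = ab / ab.sum(axis=1, keepdims=True)
    return np.vstack([rng.multinomial(depth, f) for f in frac]).T


class TestBasisSolve:
    def test_closed_form_linear_system(self):
        """With uncorrelated basis T_ij = ω_i + ω_j exactly, so solving
        t = [(D−2)I + J]ω recovers ω and yields ρ = 0 off-diagonal."""
        omega_true = np.array([0.5, 1.0, 1.5, 2.0, 0.8])
        D = len(omega_true)
        T = omega_true[:, None] + omega_true[None, :]
        np.fill_diagonal(T, 0.0)
        M = np.ones((D, D)) + (D - 2) * np.eye(D)
        direct = np.linalg.solve(M, T.sum(axis=1))
        assert np.allclose(direct, omega_true, atol=1e-12)
        omega, rho, excluded = _basis_iteration(T, 10, 0.1)
        assert np.allclose(omega, omega_true, atol=1e-10)
        off = rho[~np.eye(D, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-10)
        assert excluded == []

    def test_independent_basis_near_zero_correlations(self):
        rng = np.random.default_rng(21)
        counts = lognormal_counts(rng, D=30, n=100, rho=0.0)
        est = sparcc_correlations(counts, seed=0)
        off = est.correlation[np.triu_indices(30, 1)]
        assert np.median(np.abs(off)) < 0.1

    def test_planted_pair_recovered(self):
        errs = []
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            counts = lognormal_counts(rng, rho=0.8)
            est = sparcc_correlations(counts, seed=s)
            errs.append(est.correlation[0, 1])
        assert abs(np.median(errs) - 0.8) < 0.15

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            sparcc_correlations(np.ones((3, 10), dtype=int))

    def test_deterministic(self):
        rng = np.random.default_rng(22)
        counts = lognormal_counts(rng, D=10, n=30)
        a = sparcc_correlations(counts, seed=5).correlation
        b = sparcc_correlations(counts, seed=5).correlation
        assert np.array_equal(a, b)

    def test_correlation_matrix_shape_and_bounds(self):
        rng = np.random.default_rng(23)
        counts = lognormal_counts(rng, D=10, n=30)
        est = sparcc_correlations(counts, seed=0)
        r = est.correlation
        assert np.allclose(r, r.T, atol=1e-12)
        assert np.allclose(np.diag(r), 1.0)
        assert (np.abs(r) <= 1.0).all()
        assert (est.basis_variance > 0).all()

    def test_variation_matrix_scale_invariance(self):
        """T depends only on log-ratios: scaling a sample's fractions by a
        constant leaves T unchanged."""
        rng = np.random.default_rng(24)
        f = rng.dirichlet(np.ones(6), size=20).T  # 6 taxa x 20 samples
        T1 = _variation_matrix(f)
        T2 = _variation_matrix(f * rng.uniform(0.5, 2.0, size=(1, 20)))
        assert np.allclose(T1, T2, atol=1e-10)

    def test_dirichlet_fractions_sum_to_one(self):
        rng = np.random.default_rng(25)
        counts = rng.integers(0, 50, size=(8, 10)).astype(float)
        f = _dirichlet_fractions(rng, counts)
        assert np.allclose(f.sum(axis=0), 1.0, atol=1e-12)
        assert (f > 0).all()


class TestShuffleNull:
    def test_shuffle_preserves_multisets(self):
        rng = np.random.default_rng(26)
        counts = rng.integers(0, 20, size=(10, 15))
        shuffled = shuffle_table(counts, rng)
        for i in range(10):
            assert sorted(shuffled[i]) == sorted(counts[i])

    def test_null_pool_centred(self):
        rng = np.random.default_rng(27)
        counts = lognormal_counts(rng, D=20, n=50)
        null = shuffle_null(counts, n_tables=20, seed=0)
        assert abs(null.pooled.mean()) < 0.02

    def test_same_seed_identical_pool(self):
        rng = np.random.default_rng(28)
        counts = lognormal_counts(rng, D=8, n=20)
        a = shuffle_null(counts, n_tables=5, seed=9)
        b = shuffle_null(counts, n_tables=5, seed=9)
        assert np.array_equal(a.rhos, b.rhos)


class TestEdgeThreshold:
    def test_all_zero_pool(self):
        assert edge_threshold(np.zeros(100)) == 0.0

    def test_matches_bruteforce_quantile(self):
        grid = np.concatenate([np.arange(0.1, 1.01, 0.1),
                               -np.arange(0.1, 1.01, 0.1)])
        assert edge_threshold(grid, 0.95) == pytest.approx(
            np.quantile(np.abs(grid), 0.95)
        )

    def test_monotone_in_confidence(self):
        rng = np.random.default_rng(29)
        pool = rng.normal(0, 0.2, 1000)
        ts = [edge_threshold(pool, c) for c in (0.5, 0.8, 0.95, 0.99)]
        assert ts == sorted(ts)


class TestPseudoP:
    def test_zero_observed_is_one(self):
        rng = np.random.default_rng(30)
        nulls = rng.normal(0, 0.1, size=(50, 4, 4))
        obs = np.zeros((4, 4))
        p = pseudo_p_values(obs, nulls)
        off = p[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_extreme_observed_minimum_p(self):
        nulls = np.random.default_rng(31).normal(0, 0.1, size=(99, 4, 4))
        obs = np.full((4, 4), 5.0)
        p = pseudo_p_values(obs, nulls)
        assert np.allclose(p[0, 1], 1 / 100)

    def test_matches_exhaustive_enumeration(self):
        """Tiny table: pseudo-p from the full shuffle ensemble agrees with
        direct counting over the same ensemble."""
        rng = np.random.default_rng(32)
        counts = lognormal_counts(rng, D=5, n=12, depth=500)
        est = sparcc_correlations(counts, n_inner_iterations=3, seed=0)
        null = shuffle_null(counts, n_tables=30, seed=1,
                            n_inner_iterations=3)
        p = pseudo_p_values(est.correlation, null)
        i, j = 0, 1
        expect = (1 + (np.abs(null.rhos[:, i, j])
                       >= abs(est.correlation[i, j])).sum()) / 31
        assert p[i, j] == pytest.approx(expect)


class TestNetwork:
    def _estimate(self, D=5):
        rho = np.eye(D)
        return BasisEstimate([f"t{i}" for i in range(D)],
                             np.zeros((D, D)), np.ones(D), rho)

    def test_empty_network(self):
        est = self._estimate()
        net = build_network(est, np.ones((5, 5)), threshold=0.2)
        assert net.n_edges == 0
        n_comp, sizes = connected_components(net)
        assert n_comp == 5 and sizes == [1] * 5
        dd = degree_distribution(net)
        assert dd.loc[0] == 5

    def test_triangle(self):
        est = self._estimate(5)
        est.correlation[0, 1] = est.correlation[1, 0] = 0.9
        est.correlation[1, 2] = est.correlation[2, 1] = 0.8
        est.correlation[0, 2] = est.correlation[2, 0] = -0.7
        p = np.ones((5, 5))
        for i, j in ((0, 1), (1, 2), (0, 2)):
            p[i, j] = p[j, i] = 0.001
        net = build_network(est, p, threshold=0.5, p_cutoff=0.01)
        assert net.n_edges == 3
        dd = degree_distribution(net)
        assert dd.loc[2] == 3 and dd.loc[0] == 2
        n_comp, sizes = connected_components(net)
        assert n_comp == 3 and sizes == [3, 1, 1]
        assert set(net.edges["sign"]) == {"positive", "negative"}
        summ = network_summary(net)
        assert summ["largest_component_fraction"] == pytest.approx(3 / 5)

    def test_components_match_unionfind_oracle(self):
        rng = np.random.default_rng(33)
        D = 20
        est = self._estimate(D)
        p = np.ones((D, D))
        edges = []
        for i in range(D):
            for j in range(i + 1, D):
                if rng.random() < 0.08:
                    est.correlation[i, j] = est.correlation[j, i] = 0.9
                    p[i, j] = p[j, i] = 0.001
                    edges.append((i, j))
        net = build_network(est, p, threshold=0.5)
        # union-find oracle
        parent = list(range(D))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in edges:
            parent[find(i)] = find(j)
        n_comp_oracle = len({find(i) for i in range(D)})
        sizes_oracle = sorted(
            pd.Series([find(i) for i in range(D)]).value_counts().tolist(),
            reverse=True,
        )
        n_comp, sizes = connected_components(net)
        assert n_comp == n_comp_oracle
        assert sizes == sizes_oracle

    def test_planted_edge_detected_end_to_end(self):
        rng = np.random.default_rng(34)
        counts = lognormal_counts(rng, D=20, n=80, rho=0.9)
        # n_boot must resolve the 0.01 cutoff: min pseudo-p is 1/(n_boot+1)
        net, est = infer_network(counts_table(counts), n_boot=199, seed=0)
        pairs = set(map(tuple, net.edges[["taxon_a", "taxon_b"]].to_numpy()))
        assert ("t000", "t001") in pairs or ("t001", "t000") in pairs


def counts_table(counts):
    from propstab.tables import AbundanceTable
    D, n = counts.shape
    return AbundanceTable([f"t{i:03d}" for i in range(D)],
                          [f"s{j}" for j in range(n)], counts)
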