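"""SparCC correlations, bootstrap pseudo p-values, hubs."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gutdev import AbundanceTable
from gutdev.network import (
    bootstrap_pseudo_pvalues,
    build_network,
    rank_hubs,
    sparcc_correlations,
)
from gutdev.simulate import generate_correlated_counts


@pytest.fixture(scope="module")
def planted():
    f = 15
    sigma = np.eye(f)
    sigma[0, 1] = sigma[1, 0] = 0.8
    table, _ = generate_correlated_counts(200, sigma, depth=5000, seed=8)
    rho, _ = sparcc_correlations(table, seed=8)
    return table, rho


class TestSparcc:
    def test_null_correlations_small(self):
        table, _ = generate_correlated_counts(200, np.eye(15), depth=5000, seed=3)
        rho, _ = sparcc_correlations(table, seed=3)
        off = np.abs(rho.to_numpy()[np.triu_indices(15, 1)])
        assert np.median(off) < 0.1

    def test_planted_pair_recovered(self, planted):
        _, rho = planted
        assert rho.iloc[0, 1] == pytest.approx(0.8, abs=0.15)

    def test_sample_order_invariance(self):
        table, _ = generate_correlated_counts(60, np.eye(6), depth=2000, seed=5)
        rho1, _ = sparcc_correlations(table, seed=9)
        perm = table.values.sample(frac=1.0, random_state=0)
        rho2, _ = sparcc_correlations(AbundanceTable(perm, kind="counts"), seed=9)
        # Dirichlet draws consume per-row randomness, so allow stochastic slack
        np.testing.assert_allclose(rho1.to_numpy(), rho2.to_numpy(), atol=0.1)

    def test_agrees_with_clr_pearson_in_easy_regime(self):
        """High diversity, weak correlation: SparCC ~ CLR Pearson."""
        table, _ = generate_correlated_counts(300, np.eye(25), depth=10000, seed=1)
        rho, _ = sparcc_correlations(table, seed=1)
        frac = (table.matrix() + 0.5)
        frac = frac / frac.sum(axis=1, keepdims=True)
        clr = np.log(frac) - np.log(frac).mean(axis=1, keepdims=True)
        pear = np.corrcoef(clr, rowvar=False)
        diff = np.abs(rho.to_numpy() - pear)[np.triu_indices(25, 1)]
        assert np.quantile(diff, 0.9) < 0.1

    def test_too_few_features_rejected(self):
        t = AbundanceTable(
            pd.DataFrame([[1, 2, 3]] * 5, index=[f"s{i}" for i in range(5)],
                         columns=list("abc")),
            kind="counts",
        )
        with pytest.raises(ValueError, match="at least 4"):
            sparcc_correlations(t)


class TestBootstrap:
    def test_structure_and_planted_extreme(self, planted):
        table, rho = planted
        p = bootstrap_pseudo_pvalues(table, rho, n_boot=99, seed=2)
        arr = p.to_numpy()
        mask = ~np.isnan(arr)
        np.testing.assert_allclose(arr[mask], arr.T[mask])
        assert np.isnan(np.diag(arr)).all()
        assert p.iloc[0, 1] == pytest.approx(1.0 / 100.0)
        assert (arr[mask] >= 1.0 / 100.0).all()

    def test_low_boot_warns(self, planted):
        table, rho = planted
        with pytest.warns(UserWarning, match="unstable"):
            bootstrap_pseudo_pvalues(table, rho, n_boot=10, seed=0)


class TestBuildNetwork:
    def _toy(self):
        ids = list("abcd")
        rho = pd.DataFrame(
            [[1, 0.5, -0.6, 0.1], [0.5, 1, 0.2, -0.3],
             [-0.6, 0.2, 1, 0.4], [0.1, -0.3, 0.4, 1]],
            index=ids, columns=ids, dtype=float,
        )
        p = pd.DataFrame(0.01, index=ids, columns=ids)
        np.fill_diagonal(p.values, np.nan)
        return rho, p

    def test_alpha_one_complete_graph(self):
        rho, p = self._toy()
        net = build_network(rho, p, alpha=1.01)
        assert net.graph.number_of_edges() == 6

    def test_tiny_alpha_empty(self):
        rho, p = self._toy()
        net = build_network(rho, p, alpha=0.001)
        assert net.graph.number_of_edges() == 0

    def test_display_clamp_preserves_stored_rho(self):
        rho, p = self._toy()
        net = build_network(rho, p, alpha=0.05)
        e = net.edges.set_index(["source", "target"])
        assert e.loc[("a", "c"), "rho"] == pytest.approx(-0.6)
        assert e.loc[("a", "c"), "display_rho"] == pytest.approx(-0.4)

    def test_empty_subset_rejected(self):
        rho, p = self._toy()
        with pytest.raises(ValueError, match="empty"):
            build_network(rho, p, node_subset=[])

    def test_two_cluster_sign_recovery(self):
        """Within-cluster edges positive, between-cluster negative.

        The correlated clusters sit inside a mostly-independent
        background, respecting the sparsity assumption the basis-variance
        estimator relies on.
        """
        f = 20
        sigma = np.eye(f)
        c1, c2 = [0, 1, 2], [3, 4, 5]
        for grp in (c1, c2):
            for a in grp:
                for b in grp:
                    if a != b:
                        sigma[a, b] = 0.7
        for a in c1:
            for b in c2:
                sigma[a, b] = sigma[b, a] = -0.6
        table, _ = generate_correlated_counts(300, sigma, depth=5000, seed=4)
        rho, _ = sparcc_correlations(table, seed=4)
        within = [rho.iloc[a, b] for grp in (c1, c2) for a in grp for b in grp if a < b]
        between = [rho.iloc[a, b] for a in c1 for b in c2]
        assert np.mean(np.array(within) > 0) >= 0.8
        assert np.mean(np.array(between) < 0) >= 0.8


class TestHubs:
    def test_star_center_dominates(self):
        ids = ["hub"] + [f"leaf{i}" for i in range(5)]
        rho = pd.DataFrame(np.eye(6), index=ids, columns=ids)
        p = pd.DataFrame(1.0, index=ids, columns=ids)
        for leaf in ids[1:]:
            rho.loc["hub", leaf] = rho.loc[leaf, "hub"] = 0.5
            p.loc["hub", leaf] = p.loc[leaf, "hub"] = 0.001
        net = rank_hubs(build_network(rho, p, alpha=0.05))
        assert net.pagerank.idxmax() == "hub"
        assert net.eigencentrality.idxmax() == "hub"
        assert net.hubs[0] == "hub"

    def test_complete_graph_uniform_pagerank(self):
        ids = list("abcde")
        rho = pd.DataFrame(0.5, index=ids, columns=ids)
        np.fill_diagonal(rho.values, 1.0)
        p = pd.DataFrame(0.01, index=ids, columns=ids)
        net = rank_hubs(build_network(rho, p, alpha=0.05))
        np.testing.assert_allclose(net.pagerank, 0.2, atol=1e-8)
        assert net.pagerank.sum() == pytest.approx(1.0, abs=1e-9)

    def test_pagerank_matches_linear_solve_oracle(self, rng):
        ids = [f"n{i}" for i in range(10)]
        w = rng.random((10, 10)) * (rng.random((10, 10)) < 0.4)
        w = np.triu(w, 1)
        w = w + w.T
        rho = pd.DataFrame(np.clip(w, 0, 1), index=ids, columns=ids)
        np.fill_diagonal(rho.values, 1.0)
        p = pd.DataFrame(np.where(w > 0, 0.01, 0.9), index=ids, columns=ids)
        net = rank_hubs(build_network(rho, p, alpha=0.05), damping=0.85)
        # dense oracle: pr = (1-d)/n 1 + d W_norm^T pr, solved directly
        adj = nx.to_numpy_array(net.graph, nodelist=net.node_ids, weight="weight")
        deg = adj.sum(axis=1)
        n = len(ids)
        trans = np.where(deg[:, None] > 0, adj / np.where(deg[:, None] == 0, 1, deg[:, None]),
                         1.0 / n)
        d = 0.85
        pr = np.linalg.solve(np.eye(n) - d * trans.T, (1 - d) / n * np.ones(n))
        dangling = deg == 0
        # networkx spreads dangling mass uniformly; replicate via iteration oracle
        if dangling.any():
            pr_vec = np.full(n, 1.0 / n)
            for _ in range(500):
                pr_vec = (1 - d) / n + d * (
                    trans.T @ pr_vec + pr_vec[dangling].sum() / n
                )
            pr = pr_vec
        pr = pr / pr.sum()
        np.testing.assert_allclose(net.pagerank.to_numpy(), pr, atol=1e-8)

    def test_no_edges_rejected(self):
        ids = list("ab")
        rho = pd.DataFrame(np.eye(2), index=ids, columns=ids)
        p = pd.DataFrame(0.9, index=ids, columns=ids)
        with pytest.raises(ValueError, match="no edges"):
            rank_hubs(build_network(rho, p, alpha=0.05))
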