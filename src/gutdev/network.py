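"""Compositional co-occurrence networks.

Correlation inference on count compositions follows the SparCC
estimator: pairwise log-ratio variances ``t_ij = var(log x_i / x_j)``
relate to latent basis variances ``w_i`` through

    t_ij = w_i + w_j - 2 rho_ij sqrt(w_i w_j),

and under the sparsity assumption (most correlations near zero) the
basis variances solve a linear system in the row sums of ``t``.
Strongly correlated pairs are iteratively excluded from the system and
the procedure is averaged over Dirichlet resamples of the composition.
Pseudo p-values come from feature-wise bootstrap resampling that breaks
all between-feature association; hubs are ranked by PageRank on the
|rho|-weighted graph, with eigenvector centrality for node scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data import AbundanceTable

__all__ = [
    "CorrelationNetwork",
    "sparcc_correlations",
    "bootstrap_pseudo_pvalues",
    "build_network",
    "rank_hubs",
]


@dataclass
class CorrelationNetwork:
    node_ids: list[str]
    rho: pd.DataFrame
    pseudo_p: pd.DataFrame
    edges: pd.DataFrame                  # source, target, rho, display_rho, p
    graph: nx.Graph
    alpha: float
    eigencentrality: pd.Series | None = None
    pagerank: pd.Series | None = None
    hubs: list[str] = field(default_factory=list)


def _sparcc_once(frac: np.ndarray, n_exclusion: int, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """One SparCC basis-correlation estimate from a fraction matrix."""
    logf = np.log(frac)
    f = logf.shape[1]
    cov = np.cov(logf, rowvar=False)
    var = np.diag(cov)
    # t_ij = var(log xi - log xj)
    t = var[:, None] + var[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)

    # linear system M w = t row sums; exclusions knock out entries
    m = np.ones((f, f)) + np.eye(f) * (f - 2)
    t_work = t.copy()
    excluded: list[tuple[int, int]] = []
    w = None
    for _ in range(n_exclusion + 1):
        rowsum = t_work.sum(axis=1)
        try:
            w = np.linalg.solve(m, rowsum)
        except np.linalg.LinAlgError:
            w = np.linalg.lstsq(m, rowsum, rcond=None)[0]
        w = np.maximum(w, 1e-10)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t) / denom
        np.fill_diagonal(rho, 1.0)
        rho = np.clip(rho, -1.0, 1.0)
        # find the strongest not-yet-excluded off-diagonal pair
        cand = np.abs(rho).copy()
        np.fill_diagonal(cand, 0.0)
        for i, j in excluded:
            cand[i, j] = cand[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= threshold or len(excluded) >= n_exclusion:
            break
        excluded.append((i, j))
        m[i, j] -= 1
        m[j, i] -= 1
        m[i, i] -= 1
        m[j, j] -= 1
        t_work[i, j] = t_work[j, i] = 0.0
    return rho, w


def sparcc_correlations(
    table: AbundanceTable,
    n_inner: int = 20,
    n_exclusion: int = 10,
    exclusion_threshold: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """SparCC correlation matrix and basis variances from a count table.

    Counts are converted to fractions by a Dirichlet draw with unit
    pseudocounts in each of ``n_inner`` inner iterations; the reported
    rho is the element-wise median across iterations.
    """
    if table.shape[1] < 4:
        raise ValueError("SparCC needs at least 4 features")
    X = table.matrix()
    rng = np.random.default_rng(seed)
    rhos = []
    ws = []
    for _ in range(max(1, n_inner)):
        frac = np.vstack([rng.dirichlet(row + 1.0) for row in X])
        rho, w = _sparcc_once(frac, n_exclusion, exclusion_threshold)
        rhos.append(rho)
        ws.append(w)
    rho_med = np.median(np.stack(rhos), axis=0)
    rho_med = np.clip((rho_med + rho_med.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho_med, 1.0)
    ids = table.feature_ids
    return pd.DataFrame(rho_med, index=ids, columns=ids), np.median(np.stack(ws), axis=0)


def bootstrap_pseudo_pvalues(
    table: AbundanceTable,
    rho_obs: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    n_inner: int = 5,
) -> pd.DataFrame:
    """Two-sided pseudo p-values from feature-wise resampled null datasets.

    Each null dataset independently permutes every feature's counts
    across samples (destroying all between-feature association while
    preserving each feature's marginal exactly), re-runs the SparCC
    estimate and counts how often |rho_null| >= |rho_obs| (add-one
    rule).  Sampling with replacement instead of permuting widens the
    null and makes the test conservative.
    """
    if n_boot < 50:
        warnings.warn("fewer than 50 bootstraps gives unstable pseudo p-values")
    X = table.matrix()
    n, f = X.shape
    obs = np.abs(rho_obs.to_numpy())
    rng = np.random.default_rng(seed)
    hits = np.zeros((f, f), dtype=int)
    for _ in range(n_boot):
        shuffled = np.column_stack([X[rng.permutation(n), j] for j in range(f)])
        rhos = []
        for _ in range(max(1, n_inner)):
            frac = np.vstack([rng.dirichlet(row + 1.0) for row in shuffled])
            rhos.append(_sparcc_once(frac, 10, 0.1)[0])
        rho_b = np.median(np.stack(rhos), axis=0)
        rho_b = np.clip((rho_b + rho_b.T) / 2.0, -1.0, 1.0)
        hits += np.abs(rho_b) >= obs
    p = (1 + hits) / (n_boot + 1)
    np.fill_diagonal(p, np.nan)
    p = np.where(np.isnan(p), np.nan, np.minimum(p, p.T))
    return pd.DataFrame(p, index=rho_obs.index, columns=rho_obs.columns)


def build_network(
    rho: pd.DataFrame,
    pseudo_p: pd.DataFrame,
    alpha: float = 0.05,
    node_subset: list[str] | None = None,
    display_clip: float = 0.4,
) -> CorrelationNetwork:
    """Graph of significant correlations among a node subset.

    Edge display weights are clamped to ``[-display_clip, display_clip]``
    for rendering parity with the conventional -0.4..0.4 scale; stored
    rho values are untouched.
    """
    nodes = list(node_subset) if node_subset is not None else list(rho.index)
    if not nodes:
        raise ValueError("empty node subset")
    missing = [x for x in nodes if x not in rho.index]
    if missing:
        raise ValueError(f"nodes not in correlation matrix: {missing}")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    rows = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            p = pseudo_p.loc[u, v]
            if np.isfinite(p) and p < alpha:
                r = float(rho.loc[u, v])
                disp = float(np.clip(r, -display_clip, display_clip))
                g.add_edge(u, v, rho=r, display_rho=disp, p=float(p), weight=abs(r))
                rows.append(
                    {"source": u, "target": v, "rho": r, "display_rho": disp, "p": float(p)}
                )
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "display_rho", "p"])
    return CorrelationNetwork(
        node_ids=nodes,
        rho=rho.loc[nodes, nodes],
        pseudo_p=pseudo_p.loc[nodes, nodes],
        edges=edges,
        graph=g,
        alpha=alpha,
    )


def rank_hubs(
    net: CorrelationNetwork, damping: float = 0.85, top_n: int = 5
) -> CorrelationNetwork:
    """PageRank hubs and eigenvector centralities on |rho| edge weights.

    Isolated nodes are handled by PageRank teleportation; hubs are the
    ``top_n`` nodes by PageRank with lexicographic tie-breaking.
    """
    if net.graph.number_of_edges() < 1:
        raise ValueError("network has no edges")
    pr = nx.pagerank(net.graph, alpha=damping, weight="weight", tol=1e-10, max_iter=500)
    try:
        ec = nx.eigenvector_centrality_numpy(net.graph, weight="weight")
    except (nx.NetworkXError, np.linalg.LinAlgError):  # disconnected corner cases
        ec = {v: 0.0 for v in net.graph}
        giant = max(nx.connected_components(net.graph), key=len)
        sub = net.graph.subgraph(giant)
        ec.update(nx.eigenvector_centrality_numpy(sub, weight="weight"))
    net.pagerank = pd.Series(pr, name="pagerank").loc[net.node_ids]
    net.eigencentrality = pd.Series(ec, name="eigencentrality").loc[net.node_ids]
    ranked = sorted(net.node_ids, key=lambda v: (-pr[v], v))
    net.hubs = ranked[:top_n]
    return net
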