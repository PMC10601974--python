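"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's code paths and the scipy/statsmodels
routines the implementation delegates to: BH from its step-up definition,
Fisher's exact test by exhaustive hypergeometric enumeration, and the greedy
module search re-implemented directly on networkx subgraphs with modularity
recomputed from scratch at every step.
"""
from __future__ import annotations

from math import comb

import networkx as nx
import numpy as np


def bh_adjust_brute(pvals) -> np.ndarray:
    """Benjamini-Hochberg by the literal step-up definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        value = p[i] * m / (rank_from_top + 1)
        running_min = min(running_min, value)
        adj[i] = min(running_min, 1.0)
    return adj


def fisher_two_sided_brute(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by enumerating the hypergeometric support.

    Margins fixed at (a+b, c+d, a+c); the p-value sums the probabilities of
    all tables as or less probable than the observed one.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(k: int) -> float:
        return comb(r1, k) * comb(r2, c1 - k) / denom

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


def greedy_reference(
    wgraph: nx.Graph,
    seed,
    min_module_size: int = 5,
    max_module_size: int = 100,
    gain_tolerance: float = 1.05,
):
    """Reference greedy module growth on networkx, everything from scratch.

    At each step: among neighbors of the member set, add the node whose
    inclusion maximizes the induced-subgraph mean edge weight (tie broken
    lexicographically); accept while below the minimum size or while the
    mean weight of the newly included edges times the tolerance is at least
    the current modularity. Returns (member set, final M, peak M).
    """

    def modularity(nodes) -> float:
        sub = wgraph.subgraph(nodes)
        weights = [d["weight"] for _, _, d in sub.edges(data=True)]
        return float(np.mean(weights)) if weights else 0.0

    members = {seed}
    m_cur = 0.0
    m_peak = 0.0
    while len(members) < max_module_size:
        candidates = sorted(
            {n for m in members for n in wgraph.neighbors(m)} - members
        )
        if not candidates:
            break
        scored = sorted(
            ((modularity(members | {n}), n) for n in candidates),
            key=lambda t: (-t[0], t[1]),
        )
        m_new, best = scored[0]
        new_edges = [
            wgraph[best][m]["weight"] for m in members if wgraph.has_edge(best, m)
        ]
        marginal = float(np.mean(new_edges))
        if len(members) >= min_module_size and (
            marginal * gain_tolerance < m_cur
        ):
            break
        members.add(best)
        m_cur = m_new
        if len(members) >= min_module_size:
            m_peak = max(m_peak, m_cur)
    if len(members) < min_module_size:
        m_peak = m_cur
    return members, m_cur, m_peak


def size_factors_brute(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors computed element by element."""
    n_genes, n_samples = counts.shape
    usable = [
        g for g in range(n_genes) if all(counts[g, j] > 0 for j in range(n_samples))
    ]
    factors = []
    for j in range(n_samples):
        ratios = []
        for g in usable:
            geomean = np.prod([float(counts[g, k]) for k in range(n_samples)]) ** (
                1.0 / n_samples
            )
            ratios.append(counts[g, j] / geomean)
        factors.append(float(np.median(ratios)))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def hypergeom_tail_brute(overlap: int, n_bg: int, n_set: int, n_query: int):
    """P(X >= overlap) for X hypergeometric(n_bg, n_set, n_query)."""
    denom = comb(n_bg, n_query)
    total = 0.0
    for k in range(overlap, min(n_set, n_query) + 1):
        total += comb(n_set, k) * comb(n_bg - n_set, n_query - k) / denom
    return min(total, 1.0)


def random_connected_graph(
    rng: np.random.Generator, max_nodes: int = 8
) -> nx.Graph:
    """A small random connected graph with uniform node/edge weights."""
    n = int(rng.integers(2, max_nodes + 1))
    while True:
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    for node in g.nodes:
        g.nodes[node]["weight"] = float(rng.uniform())
    for u, v in g.edges:
        g[u][v]["weight"] = (
            g.nodes[u]["weight"] + g.nodes[v]["weight"]
        ) / 2.0
    return g
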