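"""Functional epigenetic module (FEM) detection on a PPI scaffold.

The integration overlays two per-gene statistics on a protein-protein
interaction graph: a region-level methylation statistic (Stouffer
combination of signed per-CpG probit scores over the gene body or promoter)
and an expression statistic (the Wald z of the differential-expression fit).
Each is rank-normalized to [0, 1] by magnitude across graph genes and the
node weight is their mean, making the integration scale-free across assays.
Edge weights are the average of the endpoint node weights.

Modules are grown greedily from high-weight seed genes: starting at the
seed, the neighbor that maximizes the module's mean induced edge weight
("modularity" M) is added while the module is below the minimum size, or
while the mean weight of the edges that addition brings in stays within
the gain tolerance gamma of the current M (i.e. marginal * gamma >= M).
Significance is a Monte-Carlo permutation test: non-seed node weights are
shuffled over the graph (topology preserved, signal-topology coupling
destroyed, seed-selection bias conditioned away) and the same seeded search
is re-run; both the observed and each permuted search are scored by their
trajectory-peak modularity and the p-value is
``(1 + #{peak* >= peak_obs}) / (1 + B)``.

Overlapping detections from different seeds are merged by single-linkage
Jaccard grouping, as a hub found from several seed genes is one module.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneRegion
from .expression import bh_adjust, call_degs

Z_CAP = 8.0  # cap per-CpG probit scores; Phi^-1 overflows near p=0


@dataclass(frozen=True)
class NodeStat:
    """Per-gene integrated statistic mapped onto the PPI scaffold."""

    gene_id: str
    z_meth: float
    s_expr: float
    w_meth: float
    w_expr: float
    weight: float
    meth_state: str = "none"  # hyper | hypo | none
    expr_state: str = "none"  # up | down | none


@dataclass(frozen=True)
class FEMParams:
    """Tunables of the module search and its permutation test."""

    n_seeds: int = 100
    max_module_size: int = 100
    min_module_size: int = 5
    gain_tolerance: float = 1.05
    n_permutations: int = 1000
    p_max: float = 0.05
    dedup_jaccard: float = 0.9
    level: str = "promoter"  # gene_body | promoter
    score_multiplier: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_tolerance < 1.0:
            raise ValueError("gain_tolerance must be >= 1")
        if self.n_permutations < 19:
            raise ValueError("need >= 19 permutations")
        if not (0 < self.dedup_jaccard <= 1):
            raise ValueError("dedup_jaccard must be in (0, 1]")
        if self.level not in ("gene_body", "promoter"):
            raise ValueError(f"invalid level {self.level!r}")


@dataclass(frozen=True)
class Module:
    """A detected module: seed(s), member set, modularity, significance."""

    seeds: frozenset
    members: frozenset
    modularity: float
    p_perm: float | None
    node_stats: Mapping[str, NodeStat]
    edges: tuple
    degenerate: bool = False
    peak_modularity: float = 0.0

    @property
    def seed_gene(self) -> str:
        return sorted(self.seeds)[0]

    def jaccard(self, other: "Module | frozenset | set") -> float:
        members = other.members if isinstance(other, Module) else set(other)
        union = self.members | members
        if not union:
            return 1.0
        return len(self.members & members) / len(union)


# ---------------------------------------------------------------------------
# node statistics
# ---------------------------------------------------------------------------

def region_meth_statistic(
    cpg_results: pd.DataFrame,
    regions: Iterable[GeneRegion],
    level: str = "promoter",
) -> dict[str, float]:
    """Per-gene Stouffer z over the CpGs in the gene's region at ``level``.

    Each CpG contributes ``sign(meth_diff) * Phi^-1(1 - p/2)`` (capped at
    |z| = 8); the gene statistic is ``sum(z_i) / sqrt(n)``. Genes with no
    covered CpG get 0.
    """
    with np.errstate(divide="ignore"):
        probit = stats.norm.isf(cpg_results["p"].to_numpy() / 2.0)
    z_i = np.sign(cpg_results["meth_diff"].to_numpy()) * np.minimum(
        probit, Z_CAP
    )
    by_chrom = {}
    for chrom, idx in cpg_results.groupby("chrom").groups.items():
        by_chrom[chrom] = (
            cpg_results.loc[idx, "pos"].to_numpy() - 1,
            z_i[cpg_results.index.get_indexer(idx)],
        )
    out: dict[str, float] = {}
    for region in regions:
        if region.kind != level:
            continue
        out.setdefault(region.gene_id, 0.0)
        if region.chrom not in by_chrom:
            continue
        pos0, z = by_chrom[region.chrom]
        mask = (pos0 >= region.start) & (pos0 < region.end)
        n = int(mask.sum())
        if n:
            out[region.gene_id] = float(z[mask].sum() / np.sqrt(n))
    return out


def _rank_unit(values: np.ndarray) -> np.ndarray:
    # average ranks of magnitudes, scaled so the largest maps to 1.0
    return stats.rankdata(np.abs(values), method="average") / len(values)


def integrate_node_stats(
    z_meth: Mapping[str, float],
    de_table: pd.DataFrame,
    graph: nx.Graph,
    dmg_table: pd.DataFrame | None = None,
    deg_sets: tuple[set, set] | None = None,
    level: str = "promoter",
) -> tuple[list[NodeStat], int]:
    """Rank-normalize both omics statistics over graph genes.

    Returns the NodeStat list (one per graph gene) and the number of
    statistic-bearing genes that were absent from the graph (excluded).
    """
    genes = sorted(graph.nodes)
    gene_set = set(genes)
    de_by_gene = de_table.set_index("gene_id")
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = de_by_gene["lfc"] / de_by_gene["se"]
    wald = wald.replace([np.inf, -np.inf], 0.0).fillna(0.0)

    n_excluded = len(
        (set(z_meth) | set(de_by_gene.index)) - gene_set
    )
    zm = np.array([float(z_meth.get(g, 0.0)) for g in genes])
    se_ = np.array([float(wald.get(g, 0.0)) for g in genes])
    w_meth = _rank_unit(zm)
    w_expr = _rank_unit(se_)
    weight = (w_meth + w_expr) / 2.0

    meth_state = {g: "none" for g in genes}
    if dmg_table is not None:
        at_level = dmg_table[dmg_table["region_kind"] == level]
        for _, row in at_level.iterrows():
            if row["gene_id"] in meth_state:
                meth_state[row["gene_id"]] = row["direction"]
    expr_state = {g: "none" for g in genes}
    if deg_sets is not None:
        up, down = deg_sets
        for g in up & gene_set:
            expr_state[g] = "up"
        for g in down & gene_set:
            expr_state[g] = "down"

    node_stats = [
        NodeStat(
            gene_id=g,
            z_meth=float(zm[i]),
            s_expr=float(se_[i]),
            w_meth=float(w_meth[i]),
            w_expr=float(w_expr[i]),
            weight=float(weight[i]),
            meth_state=meth_state[g],
            expr_state=expr_state[g],
        )
        for i, g in enumerate(genes)
    ]
    return node_stats, n_excluded


def build_weighted_graph(
    graph: nx.Graph,
    node_stats: Sequence[NodeStat],
    score_multiplier: bool = False,
) -> nx.Graph:
    """Weight every PPI edge with the average of its endpoint node weights."""
    by_gene = {s.gene_id: s for s in node_stats}
    missing = [g for g in graph.nodes if g not in by_gene]
    if missing:
        raise ValueError(f"no node statistic for gene(s): {sorted(missing)[:5]}")
    wgraph = nx.Graph()
    for g in graph.nodes:
        wgraph.add_node(g, weight=by_gene[g].weight)
    for u, v, data in graph.edges(data=True):
        w = (by_gene[u].weight + by_gene[v].weight) / 2.0
        if score_multiplier:
            w *= data.get("score", 1000.0) / 1000.0
        wgraph.add_edge(u, v, weight=w, score=data.get("score", np.nan))
    return wgraph


def select_seeds(node_stats: Sequence[NodeStat], n_seeds: int) -> list[str]:
    """Top-weight genes, ties broken lexicographically by gene id."""
    ranked = sorted(node_stats, key=lambda s: (-s.weight, s.gene_id))
    return [s.gene_id for s in ranked[:n_seeds]]


# ---------------------------------------------------------------------------
# greedy search
# ---------------------------------------------------------------------------

class _SearchGraph:
    """Index-based view of a weighted graph for fast repeated searches."""

    def __init__(self, wgraph: nx.Graph, score_multiplier: bool = False):
        self.genes = sorted(wgraph.nodes)
        self.index = {g: i for i, g in enumerate(self.genes)}
        self.node_weight = np.array(
            [wgraph.nodes[g]["weight"] for g in self.genes], dtype=float
        )
        edges = []
        mult = []
        self.adj: list[list[tuple[int, int]]] = [[] for _ in self.genes]
        for eid, (u, v, data) in enumerate(sorted(wgraph.edges(data=True))):
            iu, iv = self.index[u], self.index[v]
            edges.append((iu, iv))
            if score_multiplier:
                mult.append(data.get("score", 1000.0) / 1000.0)
            else:
                mult.append(1.0)
            self.adj[iu].append((iv, eid))
            self.adj[iv].append((iu, eid))
        self.edge_index = np.array(edges, dtype=np.int64).reshape(-1, 2)
        self.edge_mult = np.array(mult, dtype=float)
        self.edge_weight = self._edge_weights(self.node_weight)

    def _edge_weights(self, node_weight: np.ndarray) -> np.ndarray:
        if len(self.edge_index) == 0:
            return np.empty(0)
        avg = (
            node_weight[self.edge_index[:, 0]]
            + node_weight[self.edge_index[:, 1]]
        ) / 2.0
        return avg * self.edge_mult


def _greedy(
    sg: _SearchGraph, edge_weight: np.ndarray, seed_idx: int, params: FEMParams
) -> tuple[set[int], float, list[int], float]:
    """Greedy hill-climb.

    Returns (member indices, final M, member edge ids, peak M), where peak M
    is the largest modularity seen along the growth trajectory at sizes >=
    min_module_size — the statistic the permutation test compares, so that
    observed and permuted searches are scored by the same functional
    regardless of where each one stops.
    """
    members = {seed_idx}
    member_edges: list[int] = []
    edge_sum, edge_cnt = 0.0, 0
    m_cur = 0.0
    m_peak = 0.0
    # candidate bookkeeping: for each outside neighbor, the edges into members
    cand: dict[int, list[int]] = {}
    for nb, eid in sg.adj[seed_idx]:
        cand.setdefault(nb, []).append(eid)
    while len(members) < params.max_module_size and cand:
        best = None  # (M_new, gene_id) minimized on (-M, gene)
        for node, eids in cand.items():
            add = float(edge_weight[eids].sum()) if len(eids) > 1 else float(
                edge_weight[eids[0]]
            )
            m_new = (edge_sum + add) / (edge_cnt + len(eids))
            key = (-m_new, sg.genes[node])
            if best is None or key < best[0]:
                best = (key, node, add, len(eids))
        (neg_m, _), node, add_sum, add_cnt = best
        # Acceptance gates on the incoming edges' own mean, not the diluted
        # overall mean: in a large module a single weak edge barely moves
        # the mean, and gating on it lets the search absorb the whole graph.
        marginal = add_sum / add_cnt
        if len(members) >= params.min_module_size and (
            marginal * params.gain_tolerance < m_cur
        ):
            break
        members.add(node)
        member_edges.extend(cand.pop(node))
        edge_sum += add_sum
        edge_cnt += add_cnt
        m_cur = edge_sum / edge_cnt
        if len(members) >= params.min_module_size:
            m_peak = max(m_peak, m_cur)
        for nb, eid in sg.adj[node]:
            if nb not in members:
                cand.setdefault(nb, []).append(eid)
    if len(members) < params.min_module_size:
        m_peak = m_cur
    return members, m_cur, member_edges, m_peak


def greedy_module_search(
    wgraph: nx.Graph, seed: str, params: FEMParams | None = None
) -> Module:
    """Grow one module from ``seed`` on a weighted graph (deterministic)."""
    params = params or FEMParams()
    sg = _SearchGraph(wgraph, score_multiplier=False)
    return _module_from_search(sg, sg.edge_weight, seed, params)


def _module_from_search(
    sg: _SearchGraph, edge_weight: np.ndarray, seed: str, params: FEMParams
) -> Module:
    seed_idx = sg.index[seed]
    if not sg.adj[seed_idx]:
        return Module(
            seeds=frozenset([seed]),
            members=frozenset([seed]),
            modularity=0.0,
            p_perm=None,
            node_stats={},
            edges=(),
            degenerate=True,
        )
    members, m_cur, member_edges, m_peak = _greedy(
        sg, edge_weight, seed_idx, params
    )
    edges = tuple(
        (sg.genes[sg.edge_index[eid, 0]], sg.genes[sg.edge_index[eid, 1]],
         float(edge_weight[eid]))
        for eid in sorted(member_edges)
    )
    return Module(
        seeds=frozenset([seed]),
        members=frozenset(sg.genes[i] for i in members),
        modularity=float(m_cur),
        p_perm=None,
        node_stats={},
        edges=edges,
        peak_modularity=float(m_peak),
    )


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode("utf8"))


def module_pvalue(
    wgraph: nx.Graph,
    seed: str,
    observed_m: float,
    params: FEMParams | None = None,
) -> float:
    """Monte-Carlo p-value by shuffling node weights over the graph.

    ``observed_m`` is the observed trajectory-peak modularity (for a module
    from :func:`greedy_module_search`, its ``peak_modularity``). Each
    permutation reruns the same natural-stopping search and records its own
    trajectory peak, so observed and permuted runs are scored by an
    identical functional and the p-value is exact under a global null. The
    permutation stream is derived from ``params.rng_seed`` and the seed
    gene's name, so the value does not depend on the order modules are
    processed in.
    """
    params = params or FEMParams()
    sg = _SearchGraph(wgraph, score_multiplier=params.score_multiplier)
    return _module_pvalue_indexed(sg, seed, observed_m, params)


def _module_pvalue_indexed(
    sg: _SearchGraph,
    seed: str,
    observed_m: float,
    params: FEMParams,
) -> float:
    rng = np.random.default_rng(
        [params.rng_seed % (2**31), _stable_hash(seed)]
    )
    seed_idx = sg.index[seed]
    # Conditional permutation: the seed gene was selected for its high
    # weight, so its weight stays fixed and only the other nodes' weights
    # are shuffled. Shuffling the seed too makes the test anti-conservative
    # under a global null (the observed search always starts from a
    # top-weight node, the permuted ones rarely do).
    other_idx = np.array(
        [i for i in range(len(sg.node_weight)) if i != seed_idx]
    )
    other_weights = sg.node_weight[other_idx]
    n_ge = 0
    for _ in range(params.n_permutations):
        perm_weight = sg.node_weight.copy()
        perm_weight[other_idx] = rng.permutation(other_weights)
        edge_weight = sg._edge_weights(perm_weight)
        if not sg.adj[seed_idx]:
            m_star = 0.0
        else:
            _, _, _, m_star = _greedy(sg, edge_weight, seed_idx, params)
        if m_star >= observed_m:
            n_ge += 1
    return (1 + n_ge) / (1 + params.n_permutations)


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def deduplicate_modules(
    modules: Sequence[Module], dedup_jaccard: float = 0.9
) -> list[Module]:
    """Merge near-identical detections (single-linkage Jaccard grouping).

    Each merged group reports the union of its seeds, the member set of the
    highest-modularity member, and the minimum permutation p-value.
    """
    n = len(modules)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if modules[i].jaccard(modules[j]) >= dedup_jaccard:
                parent[find(i)] = find(j)
    groups: dict[int, list[Module]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(modules[i])
    merged = []
    for group in groups.values():
        best = max(group, key=lambda m: (m.modularity, m.seed_gene))
        seeds = frozenset().union(*(m.seeds for m in group))
        pvals = [m.p_perm for m in group if m.p_perm is not None]
        merged.append(
            replace(
                best,
                seeds=seeds,
                p_perm=min(pvals) if pvals else best.p_perm,
            )
        )
    merged.sort(key=lambda m: (-m.modularity, m.seed_gene))
    return merged


def concordant_genes(
    deg_sets: tuple[set, set],
    dmg_table: pd.DataFrame,
    convention: str = "anticorrelated",
) -> set[str]:
    """Genes with coupled methylation and expression calls.

    ``anticorrelated``: hypermethylated & downregulated, or hypomethylated &
    upregulated. ``any``: any DMG that is any DEG.
    """
    up, down = deg_sets
    hyper = set(dmg_table.loc[dmg_table["direction"] == "hyper", "gene_id"])
    hypo = set(dmg_table.loc[dmg_table["direction"] == "hypo", "gene_id"])
    if convention == "anticorrelated":
        return (hyper & down) | (hypo & up)
    if convention == "any":
        return (hyper | hypo) & (up | down)
    raise ValueError(f"unknown concordance convention {convention!r}")


def hypergeometric_ora(
    query_genes: Iterable[str],
    background_genes: Iterable[str],
    gene_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation across gene sets."""
    background = set(background_genes)
    if not background:
        raise ValueError("empty background")
    query = set(query_genes)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    rows = []
    for name, members in gene_sets.items():
        in_bg = set(members) & background
        overlap = in_bg & query
        p = float(
            stats.hypergeom.sf(
                len(overlap) - 1, len(background), len(in_bg), len(query)
            )
        )
        rows.append(
            {
                "gene_set": name,
                "set_size": len(in_bg),
                "overlap": len(overlap),
                "p": min(p, 1.0),
                "genes": ",".join(sorted(overlap)),
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene_set", "set_size", "overlap", "p", "genes"]
    )
    if not table.empty:
        table["padj"] = bh_adjust(table["p"].to_numpy())
    else:
        table["padj"] = []
    return table


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class FunctionalEpigeneticModules:
    """Seeded FEM detection over a PPI graph from DE and DMP tables.

    Parameters
    ----------
    graph:
        Gene-level PPI scaffold (undirected, scored edges).
    de_table:
        Per-gene DE results (native or imported TSV schema).
    dmp_table:
        Per-CpG differential methylation results with status column.
    regions:
        Gene bodies and promoters used to aggregate CpGs to genes.
    params:
        Search and permutation tunables.
    """

    def __init__(
        self,
        graph: nx.Graph,
        de_table: pd.DataFrame,
        dmp_table: pd.DataFrame,
        regions: Sequence[GeneRegion],
        params: FEMParams | None = None,
        deg_padj_max: float = 0.05,
        deg_lfc_min: float = 1.0,
        dmg_min_dmps: int = 5,
    ) -> None:
        self.graph = graph
        self.de_table = de_table
        self.dmp_table = dmp_table
        self.regions = list(regions)
        self.params = params or FEMParams()
        self.deg_padj_max = deg_padj_max
        self.deg_lfc_min = deg_lfc_min
        self.dmg_min_dmps = dmg_min_dmps

    def fit(self) -> "FEMResults":
        from .methylation import call_dmgs, count_dmps_by_region

        params = self.params
        z_meth = region_meth_statistic(
            self.dmp_table, self.regions, level=params.level
        )
        deg_sets = call_degs(
            self.de_table, self.deg_padj_max, self.deg_lfc_min
        )
        dmg_table = call_dmgs(
            count_dmps_by_region(self.dmp_table, self.regions),
            min_dmps=self.dmg_min_dmps,
        )
        node_stats, n_excluded = integrate_node_stats(
            z_meth, self.de_table, self.graph,
            dmg_table=dmg_table, deg_sets=deg_sets, level=params.level,
        )
        wgraph = build_weighted_graph(
            self.graph, node_stats, score_multiplier=params.score_multiplier
        )
        by_gene = {s.gene_id: s for s in node_stats}
        seeds = select_seeds(node_stats, params.n_seeds)
        sg = _SearchGraph(wgraph, score_multiplier=params.score_multiplier)
        raw_modules: list[Module] = []
        for seed in seeds:
            module = _module_from_search(sg, sg.edge_weight, seed, params)
            if module.degenerate:
                raw_modules.append(module)
                continue
            p_perm = _module_pvalue_indexed(
                sg, seed, module.peak_modularity, params
            )
            module = replace(
                module,
                p_perm=p_perm,
                node_stats={g: by_gene[g] for g in module.members},
            )
            raw_modules.append(module)
        searchable = [m for m in raw_modules if not m.degenerate]
        merged = deduplicate_modules(searchable, params.dedup_jaccard)
        return FEMResults(
            self, node_stats, wgraph, raw_modules, merged, deg_sets,
            dmg_table, n_excluded,
        )


class FEMResults:
    """Detected modules plus the integrated node statistics behind them."""

    def __init__(
        self,
        model: FunctionalEpigeneticModules,
        node_stats: list[NodeStat],
        weighted_graph: nx.Graph,
        raw_modules: list[Module],
        modules: list[Module],
        deg_sets: tuple[set, set],
        dmg_table: pd.DataFrame,
        n_excluded: int,
    ) -> None:
        self.model = model
        self.node_stats = node_stats
        self.weighted_graph = weighted_graph
        self.raw_modules = raw_modules
        self.modules = modules
        self.deg_sets = deg_sets
        self.dmg_table = dmg_table
        self.n_excluded = n_excluded

    @property
    def significant_modules(self) -> list[Module]:
        p_max = self.model.params.p_max
        return [
            m for m in self.modules
            if m.p_perm is not None and m.p_perm <= p_max
        ]

    def concordant_genes(self, convention: str = "anticorrelated") -> set[str]:
        return concordant_genes(self.deg_sets, self.dmg_table, convention)

    def module_report(self) -> pd.DataFrame:
        rows = []
        for m in self.modules:
            rows.append(
                {
                    "seeds": ",".join(sorted(m.seeds)),
                    "size": len(m.members),
                    "modularity": m.modularity,
                    "p_perm": m.p_perm,
                    "members": ",".join(sorted(m.members)),
                }
            )
        return pd.DataFrame(
            rows, columns=["seeds", "size", "modularity", "p_perm", "members"]
        )

    def summary(self) -> str:
        params = self.model.params
        sig = self.significant_modules
        lines = [
            "Functional epigenetic module detection",
            "=" * 40,
            f"graph: {self.weighted_graph.number_of_nodes()} genes, "
            f"{self.weighted_graph.number_of_edges()} edges",
            f"level: {params.level}; seeds searched: "
            f"{min(params.n_seeds, len(self.node_stats))}",
            f"permutations per seed: {params.n_permutations}",
            f"modules after deduplication: {len(self.modules)}",
            f"significant modules (p <= {params.p_max}): {len(sig)}",
        ]
        for m in sig:
            lines.append(
                f"  seed(s) {','.join(sorted(m.seeds))}: "
                f"{len(m.members)} genes, M = {m.modularity:.3f}, "
                f"p = {m.p_perm:.4g}"
            )
        return "\n".join(lines)
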