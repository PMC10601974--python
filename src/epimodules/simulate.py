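"""Synthetic multi-omic study generator with planted ground truth.

Generates everything the pipeline consumes — gene annotation with promoter
CpGs, a connected PPI scaffold, negative-binomial RNA-seq counts and
beta-binomial RRBS coverage — around a set of planted connected modules
whose genes carry a log2 fold-change and a promoter methylation shift.
Non-module genes are null (lfc 0, methylation difference 0), so downstream
callers can be checked for both calibration and recovery.

Defaults emulate the target study's design: a two-group comparison with six
RNA-seq replicates per group, one pooled RRBS library per condition at mean
coverage 30x, planted effects |lfc| = 2 and |delta beta| = 0.4 concentrated
in promoters, and anticorrelated coupling (hypermethylated promoter implies
downregulated gene).

Every stage draws from a stream derived from ``rng_seed`` plus a fixed
stage tag, so identical configs give byte-identical outputs regardless of
call order.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .datatypes import ExpressionMatrix, GeneRegion, MethylationSite
from .io import _promoter

_STAGE = {"annotation": 1, "ppi": 2, "truth": 3, "rnaseq": 4, "rrbs": 5}

GENE_BODY_LENGTH = 2000
GENE_STRIDE = 10_000
CHROM = "chrS"


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 200
    n_samples_per_group: int = 6
    graph_model: str = "barabasi_albert"  # | watts_strogatz | stochastic_block
    ba_attachment: int = 2
    ws_neighbors: int = 4
    ws_rewire: float = 0.1
    sbm_blocks: int = 4
    sbm_p_in: float = 0.15
    sbm_p_out: float = 0.01
    n_modules: int = 2
    module_size_range: tuple[int, int] = (15, 15)
    lfc_effect: float = 2.0
    meth_diff_effect: float = 0.4
    nb_dispersion: float = 0.05
    mean_coverage: float = 30.0
    coverage_dispersion: float = 0.1
    bb_rho: float = 0.05
    cpgs_per_promoter: int = 8
    promoter_upstream: int = 1500
    promoter_downstream: int = 500
    anticorrelated: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.cpgs_per_promoter < 1:
            raise ValueError(
                "cpgs_per_promoter must be >= 1; the methylation branch "
                "is untestable without promoter CpGs"
            )
        if not (0 < self.meth_diff_effect < 1):
            raise ValueError("meth_diff_effect must lie in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.module_size_range[0] > self.module_size_range[1]:
            raise ValueError("invalid module_size_range")
        if self.module_size_range[1] > self.n_genes:
            raise ValueError("module sizes cannot exceed n_genes")
        if self.bb_rho < 0 or self.bb_rho >= 1:
            raise ValueError("bb_rho must lie in [0, 1)")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            [self.rng_seed % (2**31), _STAGE[stage]]
        )


def gene_name(i: int) -> str:
    return f"g{i:04d}"


@dataclass
class SyntheticAnnotation:
    """Gene bodies + promoters on one synthetic chromosome, with CpG sites."""

    regions: list[GeneRegion]
    cpg_positions: dict[str, list[int]]  # gene -> 1-based promoter CpG sites

    def promoters(self) -> list[GeneRegion]:
        return [r for r in self.regions if r.kind == "promoter"]


@dataclass
class SyntheticTruth:
    """Planted modules and per-gene true effects (0 for null genes)."""

    planted_modules: list[set[str]]
    true_lfc: dict[str, float]
    true_meth_diff: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "true_lfc": self.true_lfc,
            "true_meth_diff": self.true_meth_diff,
        }
        with Path(path).open("w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with Path(path).open() as fh:
            payload = json.load(fh)
        return cls(
            planted_modules=[set(m) for m in payload["planted_modules"]],
            true_lfc=payload["true_lfc"],
            true_meth_diff=payload["true_meth_diff"],
        )


def generate_annotation(config: SimulationConfig) -> SyntheticAnnotation:
    """Non-overlapping gene bodies with promoter CpG positions.

    Genes sit on one synthetic chromosome at a fixed stride wide enough
    that no promoter reaches a neighboring gene; strands are random.
    """
    rng = config.rng("annotation")
    regions: list[GeneRegion] = []
    cpgs: dict[str, list[int]] = {}
    for i in range(config.n_genes):
        gene = gene_name(i)
        start = 5000 + i * GENE_STRIDE
        end = start + GENE_BODY_LENGTH
        strand = "+" if rng.random() < 0.5 else "-"
        body = GeneRegion(gene, CHROM, start, end, strand, "gene_body")
        prom = _promoter(
            start, end, strand, config.promoter_upstream,
            config.promoter_downstream, gene, CHROM,
        )
        regions.append(body)
        regions.append(prom)
        # CpGs occupy two positions (C on each strand), so sample even
        # offsets to keep neighboring sites from overlapping
        n_slots = (prom.end - prom.start) // 2
        offsets = rng.choice(
            n_slots, size=min(config.cpgs_per_promoter, n_slots), replace=False
        )
        cpgs[gene] = sorted(int(prom.start + 2 * o) + 1 for o in offsets)
    return SyntheticAnnotation(regions=regions, cpg_positions=cpgs)


def generate_ppi(config: SimulationConfig) -> nx.Graph:
    """A connected scored PPI graph over all genes."""
    if config.n_genes < 3:
        raise ValueError("need >= 3 genes for a PPI graph")
    rng = config.rng("ppi")
    nx_seed = int(rng.integers(0, 2**31 - 1))
    n = config.n_genes
    if config.graph_model == "barabasi_albert":
        g = nx.barabasi_albert_graph(n, config.ba_attachment, seed=nx_seed)
    elif config.graph_model == "watts_strogatz":
        g = nx.connected_watts_strogatz_graph(
            n, config.ws_neighbors, config.ws_rewire, seed=nx_seed
        )
    elif config.graph_model == "stochastic_block":
        base = n // config.sbm_blocks
        sizes = [base] * (config.sbm_blocks - 1)
        sizes.append(n - base * (config.sbm_blocks - 1))
        p = [
            [
                config.sbm_p_in if i == j else config.sbm_p_out
                for j in range(config.sbm_blocks)
            ]
            for i in range(config.sbm_blocks)
        ]
        g = nx.stochastic_block_model(sizes, p, seed=nx_seed)
        g = nx.Graph(g)  # drop block metadata / potential multi-edges
        # stitch components deterministically so the scaffold is connected
        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort(key=lambda c: c[0])
        for a, b in zip(comps, comps[1:]):
            g.add_edge(a[0], b[0])
    else:
        raise ValueError(f"unknown graph model {config.graph_model!r}")
    mapping = {i: gene_name(i) for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    for u, v in sorted(g.edges):
        g[u][v]["score"] = int(rng.integers(400, 1001))
    return g


def plant_truth(graph: nx.Graph, config: SimulationConfig) -> SyntheticTruth:
    """Grow disjoint connected modules by random BFS and assign effects.

    Each module gene gets |true_meth_diff| = meth_diff_effect with a random
    sign; with ``anticorrelated`` its lfc sign is the opposite of the
    methylation sign (hypermethylated promoter -> downregulated gene),
    otherwise signs are independent.
    """
    if not nx.is_connected(graph):
        raise ValueError("PPI graph must be connected")
    rng = config.rng("truth")
    genes = sorted(graph.nodes)
    modules: list[set[str]] = []
    # whole-plan restarts: an unlucky first module can fragment what is
    # left of the graph (hub neighborhoods are blocked), so regrow all
    for _ in range(20):
        used: set[str] = set()
        modules = []
        for _ in range(config.n_modules):
            size = int(rng.integers(
                config.module_size_range[0], config.module_size_range[1] + 1
            ))
            module = _grow_module(graph, genes, used, size, rng)
            if module is None:
                break
            modules.append(module)
            used |= module
        if len(modules) == config.n_modules:
            break
    else:
        raise ValueError(
            "could not grow disjoint connected modules; "
            "use fewer or smaller modules"
        )
    true_lfc = {g: 0.0 for g in genes}
    true_meth_diff = {g: 0.0 for g in genes}
    for module in modules:
        for g in sorted(module):
            meth_sign = 1.0 if rng.random() < 0.5 else -1.0
            if config.anticorrelated:
                lfc_sign = -meth_sign
            else:
                lfc_sign = 1.0 if rng.random() < 0.5 else -1.0
            true_meth_diff[g] = meth_sign * config.meth_diff_effect
            true_lfc[g] = lfc_sign * config.lfc_effect
    return SyntheticTruth(modules, true_lfc, true_meth_diff)


def _grow_module(graph, genes, used, size, rng, max_tries: int = 50):
    # Keep a 1-hop buffer around previously planted modules: without it,
    # high-weight direct edges between two planted modules make them a
    # single connected hotspot and the two truths are not identifiable.
    blocked = set(used)
    for g in used:
        blocked.update(graph.neighbors(g))
    free = [g for g in genes if g not in blocked]
    for _ in range(max_tries):
        if not free:
            return None
        start = free[int(rng.integers(len(free)))]
        members = {start}
        frontier = [start]
        while frontier and len(members) < size:
            node = frontier.pop(0)
            nbrs = [
                n for n in sorted(graph.neighbors(node))
                if n not in members and n not in blocked
            ]
            rng.shuffle(nbrs)
            for n in nbrs:
                if len(members) >= size:
                    break
                members.add(n)
                frontier.append(n)
        if len(members) == size:
            return members
    return None


def simulate_rnaseq_counts(
    truth: SyntheticTruth, config: SimulationConfig
) -> ExpressionMatrix:
    """NB counts: mean mu_g * 2^(lfc * I[case]), dispersion alpha.

    Baselines mu_g are log-uniform in [50, 5000]. Sampling is
    gamma-Poisson so alpha -> 0 approaches the Poisson limit smoothly.
    """
    rng = config.rng("rnaseq")
    genes = sorted(truth.true_lfc)
    n = config.n_samples_per_group
    samples = [f"case_{i + 1}" for i in range(n)] + [
        f"ctrl_{i + 1}" for i in range(n)
    ]
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}
    mu0 = np.exp(rng.uniform(np.log(50.0), np.log(5000.0), size=len(genes)))
    lfc = np.array([truth.true_lfc[g] for g in genes])
    mu = np.empty((len(genes), 2 * n))
    mu[:, :n] = (mu0 * 2.0**lfc)[:, None]
    mu[:, n:] = mu0[:, None]
    alpha = config.nb_dispersion
    counts = _nb_draw(rng, mu, alpha)
    return ExpressionMatrix(genes, samples, counts, groups)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float):
    if alpha < 1e-12:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(lam)


def simulate_rrbs_counts(
    truth: SyntheticTruth,
    annotation: SyntheticAnnotation,
    config: SimulationConfig,
) -> tuple[list[MethylationSite], list[MethylationSite]]:
    """Beta-binomial promoter CpG counts for the pooled case/control design.

    Sites are strand-resolved, as in a real coverage file: each CpG yields a
    ``+`` record at its position and a ``-`` record one base downstream,
    with independent coverage draws but a shared methylation level
    (symmetric CpG methylation), so downstream strand-collapsing roughly
    doubles effective coverage. Per strand and condition, coverage ~
    NB(mean_coverage, coverage_dispersion); methylated reads ~
    BetaBinomial(coverage, p, rho) where control p is the promoter baseline
    p0 ~ U[0.2, 0.8] (truncated so p0 + diff stays in [0, 1]) and case
    p = p0 + true_meth_diff. Sites with zero sampled coverage in a
    condition are omitted from that condition.
    """
    rng = config.rng("rrbs")
    case_sites: list[MethylationSite] = []
    ctrl_sites: list[MethylationSite] = []
    for gene in sorted(annotation.cpg_positions):
        diff = float(truth.true_meth_diff.get(gene, 0.0))
        lo = max(0.2, -diff)
        hi = min(0.8, 1.0 - diff)
        p0 = float(rng.uniform(lo, hi))
        for pos in annotation.cpg_positions[gene]:
            for p, sink in (
                (np.clip(p0 + diff, 1e-9, 1 - 1e-9), case_sites),
                (np.clip(p0, 1e-9, 1 - 1e-9), ctrl_sites),
            ):
                for strand, strand_pos in (("+", pos), ("-", pos + 1)):
                    cov = int(
                        _nb_draw(
                            rng,
                            np.array([config.mean_coverage]),
                            config.coverage_dispersion,
                        )[0]
                    )
                    if cov == 0:
                        continue
                    if config.bb_rho <= 0:
                        n_meth = int(rng.binomial(cov, p))
                    else:
                        a = p * (1 - config.bb_rho) / config.bb_rho
                        b = (1 - p) * (1 - config.bb_rho) / config.bb_rho
                        n_meth = int(rng.binomial(cov, rng.beta(a, b)))
                    sink.append(
                        MethylationSite(
                            CHROM, strand_pos, strand, n_meth, cov - n_meth
                        )
                    )
    return case_sites, ctrl_sites


def simulate_study(config: SimulationConfig):
    """Run every generator stage; returns (annotation, graph, truth,
    expression matrix, case sites, control sites)."""
    annotation = generate_annotation(config)
    graph = generate_ppi(config)
    truth = plant_truth(graph, config)
    matrix = simulate_rnaseq_counts(truth, config)
    case_sites, ctrl_sites = simulate_rrbs_counts(truth, annotation, config)
    return annotation, graph, truth, matrix, case_sites, ctrl_sites


def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Materialize a full synthetic dataset in the pipeline's file formats."""
    from . import io as omio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, graph, truth, matrix, case_sites, ctrl_sites = simulate_study(
        config
    )
    paths = {
        "regions": outdir / "annotation.bed",
        "counts": outdir / "counts.tsv",
        "ppi": outdir / "ppi.tsv",
        "case_coverage": outdir / "case.cov",
        "ctrl_coverage": outdir / "ctrl.cov",
        "truth": outdir / "truth.json",
        "groups": outdir / "groups.json",
    }
    bodies = [r for r in annotation.regions if r.kind == "gene_body"]
    omio.write_regions_bed(bodies, paths["regions"])
    omio.write_counts_table(matrix, paths["counts"])
    omio.write_ppi_edges(graph, paths["ppi"])
    omio.write_methylation_coverage(case_sites, paths["case_coverage"])
    omio.write_methylation_coverage(ctrl_sites, paths["ctrl_coverage"])
    truth.to_json(paths["truth"])
    with paths["groups"].open("w") as fh:
        json.dump(matrix.groups, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
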