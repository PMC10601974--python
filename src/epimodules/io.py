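"""Readers and writers for the external formats the pipeline touches.

Dialects
--------
* Methylation coverage: Bismark-like 5-column TSV
  ``chrom  pos(1-based)  strand  n_meth  n_unmeth``.
* Counts: TSV, first column ``gene_id``, remaining columns one per sample.
* Regions: GFF3 (1-based closed, converted) or BED6 (0-based half-open,
  taken as-is).
* PPI: StringDB-style whitespace-separated ``protein1 protein2
  combined_score`` with optional header line.
* Gene sets: GMT.
* Module graphs: GraphML (one file per module) or JSON (node-link, one file).

All readers validate rather than repair; parse errors carry line numbers.
"""
from __future__ import annotations

import json
import tempfile
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneRegion,
    MethylationSite,
    validate_id_map,
)


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# methylation coverage
# ---------------------------------------------------------------------------

def read_methylation_coverage(
    path: str | Path, collapse_strands: bool = True
) -> list[MethylationSite]:
    """Read a Bismark-like per-CpG coverage table for one condition.

    With ``collapse_strands`` a +/- pair at positions (p, p+1) on the same
    chromosome is merged into a single record at the + position with summed
    counts (symmetric-CpG collapsing).
    """
    path = Path(path)
    sites: list[MethylationSite] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 5 fields, got {len(fields)}"
                )
            chrom, pos_s, strand, m_s, u_s = fields[:5]
            try:
                pos, n_meth, n_unmeth = int(pos_s), int(m_s), int(u_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if n_meth < 0 or n_unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative count")
            try:
                sites.append(
                    MethylationSite(chrom, pos, strand, n_meth, n_unmeth)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    sites.sort(key=lambda s: (s.chrom, s.pos, s.strand))
    if collapse_strands:
        sites = collapse_symmetric_cpgs(sites)
    return sites


def collapse_symmetric_cpgs(
    sites: Sequence[MethylationSite],
) -> list[MethylationSite]:
    """Merge +/- pairs at (pos, pos+1) into one + record with summed counts."""
    out: list[MethylationSite] = []
    i = 0
    sites = sorted(sites, key=lambda s: (s.chrom, s.pos, s.strand))
    while i < len(sites):
        s = sites[i]
        nxt = sites[i + 1] if i + 1 < len(sites) else None
        if (
            nxt is not None
            and s.strand == "+"
            and nxt.strand == "-"
            and s.chrom == nxt.chrom
            and nxt.pos == s.pos + 1
        ):
            out.append(
                MethylationSite(
                    s.chrom,
                    s.pos,
                    "+",
                    s.n_meth + nxt.n_meth,
                    s.n_unmeth + nxt.n_unmeth,
                )
            )
            i += 2
        else:
            out.append(s)
            i += 1
    return out


def write_methylation_coverage(
    sites: Iterable[MethylationSite], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos, s.strand)):
            fh.write(f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.n_meth}\t{s.n_unmeth}\n")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_counts_table(
    path: str | Path, group_spec: Mapping[str, str]
) -> ExpressionMatrix:
    """Read a gene x sample TSV of raw counts with a sample->group mapping."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate gene ids: {dupes}")
    for col in df.columns:
        vals = df[col]
        if not np.all(np.equal(np.mod(vals, 1), 0)):
            raise ValueError(f"{path}: non-integer count in sample {col}")
    unknown = [s for s in group_spec if s not in df.columns]
    if unknown:
        raise ValueError(f"group_spec names unknown samples: {unknown}")
    samples = [s for s in df.columns if s in group_spec]
    return ExpressionMatrix(
        gene_ids=list(df.index.astype(str)),
        sample_ids=samples,
        counts=df[samples].to_numpy().astype(np.int64),
        groups={s: group_spec[s] for s in samples},
    )


def write_counts_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def _promoter(
    tss_start: int, tss_end: int, strand: str, upstream: int, downstream: int,
    gene_id: str, chrom: str,
) -> GeneRegion:
    # Promoter is [TSS - upstream, TSS + downstream) in transcription
    # direction, clamped at the chromosome start.
    if strand == "+":
        start, end = tss_start - upstream, tss_start + downstream
    elif strand == "-":
        start, end = tss_end - downstream, tss_end + upstream
    else:
        raise ValueError(
            f"gene {gene_id} has no strand; promoters need a strand"
        )
    start = max(0, start)
    return GeneRegion(gene_id, chrom, start, end, strand, "promoter")


def read_regions(
    path: str | Path,
    format: str,
    promoter_upstream: int = 1500,
    promoter_downstream: int = 500,
) -> list[GeneRegion]:
    """Read gene annotation and derive gene-body + promoter regions.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open;
    BED6 is taken as-is. Promoters are strand-aware windows around the TSS,
    clamped at position 0.
    """
    path = Path(path)
    if format == "gff3":
        raw = _read_gff3_genes(path)
    elif format == "bed":
        raw = _read_bed_genes(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    regions: list[GeneRegion] = []
    for gene_id, chrom, start, end, strand in raw:
        regions.append(
            GeneRegion(gene_id, chrom, start, end, strand, "gene_body")
        )
        regions.append(
            _promoter(
                start, end, strand, promoter_upstream, promoter_downstream,
                gene_id, chrom,
            )
        )
    return regions


def _read_gff3_genes(path: Path) -> list[tuple[str, str, int, int, str]]:
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(path), tmp.name, force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        out = []
        for feat in db.features_of_type("gene"):
            for key in ("gene_id", "ID", "Name"):
                if key in feat.attributes:
                    gene_id = feat.attributes[key][0]
                    break
            else:
                raise ValueError(
                    f"{path}: gene feature at {feat.seqid}:{feat.start} "
                    "lacks a gene identifier attribute"
                )
            # GFF3 1-based closed -> 0-based half-open
            out.append(
                (gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand)
            )
    return out


def _read_bed_genes(path: Path) -> list[tuple[str, str, int, int, str]]:
    out = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{lineno}: BED needs >= 4 columns for gene ids"
                )
            chrom, start_s, end_s, gene_id = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            out.append((gene_id, chrom, start, end, strand))
    return out


def write_regions_bed(regions: Iterable[GeneRegion], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}"
                f"\t{r.kind}\n"
            )


# ---------------------------------------------------------------------------
# PPI
# ---------------------------------------------------------------------------

def read_ppi_edges(
    path: str | Path,
    id_map: Mapping[str, str] | None = None,
    min_score: float = 400,
) -> nx.Graph:
    """Read a StringDB-style edge list into an undirected gene-level graph.

    Edges below ``min_score`` are dropped; protein ids are translated through
    ``id_map`` (edges with an unmappable endpoint are dropped and counted in
    ``graph.graph['n_unmapped_edges']``); reversed duplicates keep the max
    score; self-loops after mapping are dropped.
    """
    path = Path(path)
    id_map = validate_id_map(id_map) if id_map else None
    graph = nx.Graph()
    n_unmapped = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 fields, got {len(fields)}"
                )
            p1, p2, score_s = fields[:3]
            if lineno == 1 and score_s.lower() in ("combined_score", "score"):
                continue  # header
            try:
                score = float(score_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if score < min_score:
                continue
            if id_map is not None:
                if p1 not in id_map or p2 not in id_map:
                    n_unmapped += 1
                    continue
                g1, g2 = id_map[p1], id_map[p2]
            else:
                g1, g2 = p1, p2
            if g1 == g2:
                continue
            if graph.has_edge(g1, g2):
                graph[g1][g2]["score"] = max(graph[g1][g2]["score"], score)
            else:
                graph.add_edge(g1, g2, score=score)
    if graph.number_of_edges() == 0:
        raise ValueError(
            f"{path}: no edges left after filtering at min_score={min_score}; "
            "lower the threshold or check the identifier map"
        )
    graph.graph["n_unmapped_edges"] = n_unmapped
    return graph


def write_ppi_edges(graph: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['score']:g}\n")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT rows need name, description, genes"
                )
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# result tables (also import formats for externally computed results)
# ---------------------------------------------------------------------------

DE_COLUMNS = ["gene_id", "lfc", "se", "p", "padj", "mean_expr"]
DMP_COLUMNS = [
    "chrom", "pos", "beta_case", "beta_ctrl", "meth_diff", "p", "q", "status",
]


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df[DE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: DE table missing columns {sorted(missing)}")
    return df


def write_dmp_table(df: pd.DataFrame, path: str | Path) -> None:
    df[DMP_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_dmp_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DMP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: DMP table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# module graphs
# ---------------------------------------------------------------------------

def _module_to_nx(module) -> nx.Graph:
    g = nx.Graph()
    g.graph["seed"] = ",".join(sorted(module.seeds))
    g.graph["modularity"] = float(module.modularity)
    g.graph["p_perm"] = float(module.p_perm)
    for gene in sorted(module.members):
        stat = module.node_stats[gene]
        g.add_node(
            gene,
            methylation_state=stat.meth_state,
            expression_state=stat.expr_state,
            node_weight=float(stat.weight),
        )
    for u, v, w in module.edges:
        g.add_edge(u, v, edge_weight=float(w))
    return g


def write_module_graph(
    modules: Sequence, path: str | Path, format: str = "graphml"
) -> list[Path]:
    """Export modules for Cytoscape-style viewing.

    GraphML: one file per module, named ``<stem>_<seed>.graphml``.
    JSON: a single node-link file holding every module. Returns the paths
    written.
    """
    if not modules:
        raise ValueError("module set is empty")
    path = Path(path)
    if format == "graphml":
        paths = []
        for module in modules:
            g = _module_to_nx(module)
            seed = sorted(module.seeds)[0]
            out = path.with_name(f"{path.stem}_{seed}{path.suffix or '.graphml'}")
            nx.write_graphml(g, out)
            paths.append(out)
        return paths
    if format == "json":
        payload = {
            "modules": [
                nx.node_link_data(_module_to_nx(m), edges="links")
                for m in modules
            ]
        }
        with path.open("w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        return [path]
    raise ValueError(f"unknown module graph format {format!r}")


def read_module_graphs(path: str | Path, format: str = "json") -> list[nx.Graph]:
    path = Path(path)
    if format == "json":
        with path.open() as fh:
            payload = json.load(fh)
        return [
            nx.node_link_graph(d, edges="links") for d in payload["modules"]
        ]
    if format == "graphml":
        return [nx.read_graphml(path)]
    raise ValueError(f"unknown module graph format {format!r}")
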