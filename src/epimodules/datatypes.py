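"""Core in-memory containers shared across the pipeline.

Coordinate convention: all internal intervals are 0-based half-open
``[start, end)``. CpG positions are carried 1-based (as in coverage files);
a CpG at 1-based position ``p`` falls in region ``[start, end)`` iff
``start <= p - 1 < end``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class MethylationSite:
    """A single CpG's bisulfite coverage in one condition.

    ``pos`` is the 1-based genomic position of the cytosine. ``beta`` is the
    methylated fraction n_meth / (n_meth + n_unmeth), defined only when
    coverage is positive.
    """

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError(
                f"negative count at {self.chrom}:{self.pos} "
                f"({self.n_meth}, {self.n_unmeth})"
            )

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def beta(self) -> float:
        if self.coverage == 0:
            raise ValueError(
                f"beta undefined at zero coverage ({self.chrom}:{self.pos})"
            )
        return self.n_meth / self.coverage


@dataclass(frozen=True)
class GeneRegion:
    """A gene-anchored interval: the gene body or a strand-aware promoter."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    kind: str  # "gene_body" | "promoter"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.gene_id}"
            )
        if self.kind not in ("gene_body", "promoter"):
            raise ValueError(f"invalid region kind {self.kind!r}")

    def contains_cpg(self, pos_1based: int) -> bool:
        return self.start <= pos_1based - 1 < self.end


class ExpressionMatrix:
    """Gene x sample raw count matrix with a two-group design.

    Counts are non-negative integers; every sample carries a group label in
    {"case", "control"}.
    """

    def __init__(
        self,
        gene_ids: Iterable[str],
        sample_ids: Iterable[str],
        counts: np.ndarray,
        groups: Mapping[str, str],
    ) -> None:
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        counts = np.asarray(counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted(
                {g for g in self.gene_ids if self.gene_ids.count(g) > 1}
            )
            raise ValueError(f"duplicate gene ids: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.sample_ids if s not in groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        bad = {s: g for s, g in groups.items() if g not in ("case", "control")}
        if bad:
            raise ValueError(f"invalid group labels: {bad}")
        unknown = [s for s in groups if s not in self.sample_ids]
        if unknown:
            raise ValueError(f"group_spec names unknown samples: {unknown}")
        self.counts = counts.astype(np.int64)
        self.groups = {s: groups[s] for s in self.sample_ids}

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == "case"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == "control"]

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([self.groups[s] == group for s in self.sample_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.sample_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and self.groups == other.groups
        )


def validate_id_map(id_map: Mapping[str, str]) -> dict[str, str]:
    """Protein -> gene identifier map (many-to-one allowed)."""
    for k, v in id_map.items():
        if not k or not v:
            raise ValueError("id map entries must be non-empty")
    return dict(id_map)


def validate_ppi(graph: nx.Graph) -> nx.Graph:
    """Check the PPI scaffold invariants: undirected, simple, scored edges."""
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("PPI graph must be a simple undirected graph")
    for u, v, data in graph.edges(data=True):
        if u == v:
            raise ValueError(f"self-loop at {u}")
        score = data.get("score")
        if score is None or not (0 <= score <= 1000):
            raise ValueError(f"edge ({u}, {v}) score out of [0, 1000]: {score}")
    return graph
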