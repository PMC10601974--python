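"""Differential methylation between pooled case and control RRBS libraries.

Each condition is a single pooled library (many retinas, one library), so no
replicate variance is estimable and per-CpG differential methylation is
tested with a two-sided Fisher exact test on the 2x2 methylated/unmethylated
count table. Sites are filtered for minimum coverage and against a
top-percentile coverage cap (PCR-duplicate guard) per condition; a CpG must
pass in both conditions to be testable.

A differentially methylated position (DMP) requires BH q <= 0.01 and
|beta_case - beta_ctrl| >= 0.25 by default. A differentially methylated gene
(DMG) is a gene whose annotated region (gene body or promoter) holds at
least five DMPs; its direction is the majority DMP direction, ties broken
toward the larger summed |meth_diff|.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneRegion, MethylationSite
from .expression import bh_adjust


def compute_beta(site: MethylationSite) -> float:
    """Methylated fraction n_meth / coverage; errors at zero coverage."""
    return site.beta


def filter_by_coverage(
    sites: Sequence[MethylationSite],
    min_cov: int = 10,
    max_percentile: float = 99.9,
) -> list[MethylationSite]:
    """Keep sites with coverage >= min_cov and <= the max_percentile quantile.

    The quantile is computed over this condition's site list.
    """
    if not sites:
        return []
    cov = np.array([s.coverage for s in sites], dtype=float)
    cap = np.percentile(cov, max_percentile)
    return [s for s in sites if min_cov <= s.coverage <= cap]


def test_dmp(case: MethylationSite, ctrl: MethylationSite) -> float:
    """Two-sided Fisher exact p for one CpG's pooled 2x2 count table."""
    table = [[case.n_meth, case.n_unmeth], [ctrl.n_meth, ctrl.n_unmeth]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def test_dmp_logistic(case_sites, ctrl_sites):
    """Replicate-aware logistic-regression DMP test (replicated designs).

    Not implemented: the pooled single-library design this pipeline targets
    has no estimable replicate variance. Placeholder for datasets with
    per-replicate coverage files.
    """
    raise NotImplementedError(
        "logistic-regression DMP testing requires replicated libraries; "
        "the pooled design uses the Fisher exact path"
    )


def call_dmps(
    results: pd.DataFrame, q_max: float = 0.01, min_diff: float = 0.25
) -> pd.DataFrame:
    """Assign hyper/hypo/ns status from BH q-values and effect sizes.

    ``results`` needs columns chrom, pos, beta_case, beta_ctrl, meth_diff, p;
    q is (re)computed across all tested CpGs genome-wide.
    """
    out = results.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    sig = out["q"] <= q_max
    out["status"] = "ns"
    out.loc[sig & (out["meth_diff"] >= min_diff), "status"] = "hyper"
    out.loc[sig & (out["meth_diff"] <= -min_diff), "status"] = "hypo"
    return out


def count_dmps_by_region(
    dmps: pd.DataFrame, regions: Iterable[GeneRegion]
) -> pd.DataFrame:
    """Count DMPs per (gene, region kind), with hyper/hypo breakdown.

    A DMP at 1-based position p is assigned to region [start, end) iff
    start <= p - 1 < end; a DMP in several genes' regions counts in each.
    Returns columns gene_id, region_kind, n_dmps, n_hyper, n_hypo,
    sum_abs_diff_hyper, sum_abs_diff_hypo.
    """
    called = dmps[dmps["status"].isin(("hyper", "hypo"))]
    by_chrom: dict[str, pd.DataFrame] = {
        chrom: grp for chrom, grp in called.groupby("chrom")
    }
    rows = []
    for region in regions:
        grp = by_chrom.get(region.chrom)
        if grp is None:
            continue
        pos0 = grp["pos"].to_numpy() - 1
        inside = grp[(pos0 >= region.start) & (pos0 < region.end)]
        if inside.empty:
            continue
        hyper = inside[inside["status"] == "hyper"]
        hypo = inside[inside["status"] == "hypo"]
        rows.append(
            {
                "gene_id": region.gene_id,
                "region_kind": region.kind,
                "n_dmps": len(inside),
                "n_hyper": len(hyper),
                "n_hypo": len(hypo),
                "sum_abs_diff_hyper": float(hyper["meth_diff"].abs().sum()),
                "sum_abs_diff_hypo": float(hypo["meth_diff"].abs().sum()),
            }
        )
    columns = [
        "gene_id", "region_kind", "n_dmps", "n_hyper", "n_hypo",
        "sum_abs_diff_hyper", "sum_abs_diff_hypo",
    ]
    return pd.DataFrame(rows, columns=columns)


def call_dmgs(counts: pd.DataFrame, min_dmps: int = 5) -> pd.DataFrame:
    """Emit genes with >= min_dmps DMPs in a region, with majority direction.

    Direction ties break toward the larger summed |meth_diff|, so every
    emitted gene-region receives exactly one direction.
    """
    kept = counts[counts["n_dmps"] >= min_dmps].copy()
    directions = []
    for _, row in kept.iterrows():
        if row["n_hyper"] > row["n_hypo"]:
            directions.append("hyper")
        elif row["n_hypo"] > row["n_hyper"]:
            directions.append("hypo")
        elif row["sum_abs_diff_hyper"] >= row["sum_abs_diff_hypo"]:
            directions.append("hyper")
        else:
            directions.append("hypo")
    kept["direction"] = directions
    cols = ["gene_id", "region_kind", "n_dmps", "n_hyper", "n_hypo", "direction"]
    return kept[cols].reset_index(drop=True)


class DifferentialMethylation:
    """Per-CpG Fisher exact differential methylation model.

    Parameters
    ----------
    case_sites, ctrl_sites:
        Per-condition pooled coverage (strand-collapsed or not).
    min_cov, max_percentile:
        Coverage filter applied per condition before testing.
    """

    def __init__(
        self,
        case_sites: Sequence[MethylationSite],
        ctrl_sites: Sequence[MethylationSite],
        min_cov: int = 10,
        max_percentile: float = 99.9,
    ) -> None:
        self.case_sites = list(case_sites)
        self.ctrl_sites = list(ctrl_sites)
        self.min_cov = min_cov
        self.max_percentile = max_percentile

    def fit(self, q_max: float = 0.01, min_diff: float = 0.25) -> "DMPResults":
        case_f = filter_by_coverage(
            self.case_sites, self.min_cov, self.max_percentile
        )
        ctrl_f = filter_by_coverage(
            self.ctrl_sites, self.min_cov, self.max_percentile
        )
        case_by_pos = {(s.chrom, s.pos): s for s in case_f}
        ctrl_by_pos = {(s.chrom, s.pos): s for s in ctrl_f}
        shared = sorted(set(case_by_pos) & set(ctrl_by_pos))
        rows = []
        for key in shared:
            ca, ct = case_by_pos[key], ctrl_by_pos[key]
            rows.append(
                {
                    "chrom": key[0],
                    "pos": key[1],
                    "beta_case": ca.beta,
                    "beta_ctrl": ct.beta,
                    "meth_diff": ca.beta - ct.beta,
                    "p": test_dmp(ca, ct),
                }
            )
        columns = ["chrom", "pos", "beta_case", "beta_ctrl", "meth_diff", "p"]
        table = pd.DataFrame(rows, columns=columns)
        table = call_dmps(table, q_max=q_max, min_diff=min_diff)
        return DMPResults(self, table, q_max=q_max, min_diff=min_diff)


class DMPResults:
    """Fitted per-CpG results plus region aggregation to DMGs."""

    def __init__(
        self,
        model: DifferentialMethylation,
        table: pd.DataFrame,
        q_max: float,
        min_diff: float,
    ) -> None:
        self.model = model
        self.table = table
        self.q_max = q_max
        self.min_diff = min_diff

    @property
    def dmps(self) -> pd.DataFrame:
        return self.table[self.table["status"] != "ns"]

    def dmg_table(
        self, regions: Iterable[GeneRegion], min_dmps: int = 5
    ) -> pd.DataFrame:
        counts = count_dmps_by_region(self.table, regions)
        return call_dmgs(counts, min_dmps=min_dmps)

    def summary(self) -> str:
        n_hyper = int((self.table["status"] == "hyper").sum())
        n_hypo = int((self.table["status"] == "hypo").sum())
        lines = [
            "Fisher exact differential methylation (pooled design)",
            "=" * 54,
            f"CpGs testable in both conditions: {len(self.table)}",
            f"DMP thresholds: q <= {self.q_max}, |meth_diff| >= {self.min_diff}",
            f"hypermethylated DMPs: {n_hyper}",
            f"hypomethylated DMPs:  {n_hypo}",
        ]
        return "\n".join(lines)
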