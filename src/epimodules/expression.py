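"""Differential expression from raw RNA-seq counts.

The model is a deliberately simple negative-binomial Wald test on
median-of-ratios-normalized counts: per gene, the case/control log2
fold-change is ``log2((mean_case + c0) / (mean_ctrl + c0))`` with a small
pseudo-mean ``c0`` for stability at low counts, the NB dispersion is
estimated gene-wise by the method of moments, and a delta-method standard
error yields a two-sided normal p-value. This is not a DESeq2
re-implementation (no dispersion or fold-change shrinkage, no independent
filtering); it targets the same null and the same effect scale, and the
surrounding pipeline can equally consume an externally computed DE table.

Differentially expressed genes (DEGs) are called at adjusted p <= 0.05 and
|LFC| >= 1 by default, boundaries inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

LN2 = np.log(2.0)


def size_factors_median_ratio(matrix: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios sample size factors, rescaled to geometric mean 1.

    For each gene with nonzero counts in every sample, compute the ratio of
    each sample's count to the gene's geometric mean; the sample's factor is
    the median of those ratios.
    """
    counts = matrix.counts.astype(float)
    all_nonzero = np.all(counts > 0, axis=1)
    if not np.any(all_nonzero):
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "cannot compute median-of-ratios size factors"
        )
    sub = counts[all_nonzero]
    log_geomean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geomean)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qPCR fold-change by the 2^-ddCT method.

    CT values are normalized within condition to the reference transcript,
    and the case delta-CT is referenced to the control delta-CT.
    """
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("CT values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


@dataclass(frozen=True)
class DEGThresholds:
    padj_max: float = 0.05
    lfc_min: float = 1.0


def call_degs(
    results: pd.DataFrame,
    padj_max: float = 0.05,
    lfc_min: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Split genes into up-/down-regulated DEG sets (inclusive boundaries)."""
    if results.empty:
        raise ValueError("empty DE results")
    sig = results["padj"] <= padj_max
    up = set(results.loc[sig & (results["lfc"] >= lfc_min), "gene_id"])
    down = set(results.loc[sig & (results["lfc"] <= -lfc_min), "gene_id"])
    return up, down


class NegativeBinomialDE:
    """Two-group NB Wald test for differential expression.

    Parameters
    ----------
    matrix:
        Raw counts with case/control group labels.
    pseudo_mean:
        Stabilizer ``c0`` added to both group means inside the log-ratio.
    dispersion_floor:
        Lower bound for the method-of-moments dispersion estimate.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        pseudo_mean: float = 0.5,
        dispersion_floor: float = 1e-8,
    ) -> None:
        if len(matrix.case_samples) < 2 or len(matrix.control_samples) < 2:
            raise ValueError("need >= 2 samples per group")
        self.matrix = matrix
        self.pseudo_mean = pseudo_mean
        self.dispersion_floor = dispersion_floor

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, groups: dict[str, str], **kwargs
    ) -> "NegativeBinomialDE":
        matrix = ExpressionMatrix(
            gene_ids=list(counts.index.astype(str)),
            sample_ids=list(counts.columns),
            counts=counts.to_numpy(),
            groups=groups,
        )
        return cls(matrix, **kwargs)

    def fit(self) -> "DEResults":
        m = self.matrix
        counts = m.counts.astype(float)
        case = m.group_mask("case")
        ctrl = m.group_mask("control")
        if np.all(counts[:, case] == 0) or np.all(counts[:, ctrl] == 0):
            raise ValueError("one group has all-zero counts for every gene")
        factors = size_factors_median_ratio(m).to_numpy()
        y = counts / factors  # normalized counts
        n1, n0 = case.sum(), ctrl.sum()
        mean_case = y[:, case].mean(axis=1)
        mean_ctrl = y[:, ctrl].mean(axis=1)
        c0 = self.pseudo_mean
        lfc = np.log2((mean_case + c0) / (mean_ctrl + c0))

        # Method-of-moments NB dispersion from the pooled within-group
        # variance of normalized counts: Var(y) = mu + alpha * mu^2.
        var_case = y[:, case].var(axis=1, ddof=1)
        var_ctrl = y[:, ctrl].var(axis=1, ddof=1)
        pooled_var = ((n1 - 1) * var_case + (n0 - 1) * var_ctrl) / (n1 + n0 - 2)
        grand_mean = (n1 * mean_case + n0 * mean_ctrl) / (n1 + n0)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (pooled_var - grand_mean) / np.square(grand_mean)
        alpha = np.where(np.isfinite(alpha), alpha, self.dispersion_floor)
        alpha = np.maximum(alpha, self.dispersion_floor)

        # Delta method: Var(lfc) = [Var(mean_case)/(mean_case+c0)^2
        #                           + Var(mean_ctrl)/(mean_ctrl+c0)^2] / ln2^2
        var_m1 = (mean_case + alpha * mean_case**2) / n1
        var_m0 = (mean_ctrl + alpha * mean_ctrl**2) / n0
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(
                var_m1 / (mean_case + c0) ** 2 + var_m0 / (mean_ctrl + c0) ** 2
            ) / LN2
        all_zero = (mean_case == 0) & (mean_ctrl == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, lfc / se, 0.0)
        # Student-t reference with pooled df: the dispersion (hence the SE)
        # is estimated from few replicates, and a normal reference is
        # visibly anti-conservative at n = 6 + 6.
        df = len(m.case_samples) + len(m.control_samples) - 2
        p = 2.0 * stats.t.sf(np.abs(z), df=df)
        p = np.where(all_zero | (se == 0), 1.0, p)
        lfc = np.where(all_zero, 0.0, lfc)
        p = np.clip(p, 0.0, 1.0)
        padj = bh_adjust(p)

        table = pd.DataFrame(
            {
                "gene_id": m.gene_ids,
                "lfc": lfc,
                "se": se,
                "p": p,
                "padj": padj,
                "mean_expr": (mean_case + mean_ctrl) / 2.0,
                "dispersion": alpha,
            }
        )
        return DEResults(self, table, pd.Series(factors, index=m.sample_ids))


class DEResults:
    """Fitted differential-expression results.

    ``table`` holds one row per gene: lfc, se, p, padj, mean_expr,
    dispersion. ``deg_sets()`` applies the DEG thresholds.
    """

    def __init__(
        self, model: NegativeBinomialDE, table: pd.DataFrame,
        size_factors: pd.Series,
    ) -> None:
        self.model = model
        self.table = table
        self.size_factors = size_factors

    def deg_sets(
        self, padj_max: float = 0.05, lfc_min: float = 1.0
    ) -> tuple[set[str], set[str]]:
        return call_degs(self.table, padj_max=padj_max, lfc_min=lfc_min)

    def summary(self, padj_max: float = 0.05, lfc_min: float = 1.0) -> str:
        up, down = self.deg_sets(padj_max, lfc_min)
        lines = [
            "Negative-binomial Wald differential expression",
            "=" * 46,
            f"genes tested:        {len(self.table)}",
            f"case samples:        {len(self.model.matrix.case_samples)}",
            f"control samples:     {len(self.model.matrix.control_samples)}",
            f"DEG thresholds:      padj <= {padj_max}, |lfc| >= {lfc_min}",
            f"upregulated DEGs:    {len(up)}",
            f"downregulated DEGs:  {len(down)}",
        ]
        return "\n".join(lines)
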