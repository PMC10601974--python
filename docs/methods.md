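# Methods

`epimodules` integrates reduced-representation bisulphite sequencing (RRBS)
differential methylation and RNA-seq differential expression on a
protein–protein-interaction (PPI) scaffold, and searches that weighted
interactome for *functional epigenetic modules* (FEMs): connected
subnetworks whose genes show coordinated methylation and expression change.
This note documents the statistical models, the tunable parameters, the
synthetic-data generator, and the numerical/design choices.

## Differential expression

The model (`NegativeBinomialDE`) is a deliberately simple two-group
negative-binomial Wald test:

1. **Normalization.** Median-of-ratios size factors: for every gene with
   nonzero counts in all samples, divide each sample's count by the gene's
   geometric mean; a sample's factor is the median of those ratios,
   rescaled to geometric mean 1.
2. **Effect.** `lfc = log2((mean_case + c0) / (mean_ctrl + c0))` on
   normalized counts, with pseudo-mean `c0 = 0.5` (default) for stability
   at low counts. Genes with zero counts everywhere report `lfc = 0`,
   `p = 1`.
3. **Dispersion.** Gene-wise method of moments from the pooled
   within-group variance: `alpha = (s² − μ̂) / μ̂²`, floored at `1e-8`.
4. **Inference.** Delta-method standard error
   `Var(lfc) = [Var(m̄₁)/(m̄₁+c0)² + Var(m̄₀)/(m̄₀+c0)²] / ln2²` with
   `Var(m̄) = (μ + αμ²)/n`, Wald statistic `z = lfc/se`, and a two-sided
   **Student-t** reference with `n₁+n₂−2` degrees of freedom. The t
   reference matters: with six replicates per group a normal reference is
   visibly anti-conservative (≈7.5% of null genes at nominal 5%); with the
   t reference the null 5% tail sits at ≈4.8% and the raw p-values pass a
   Kolmogorov–Smirnov uniformity check.
5. **Multiplicity.** Benjamini–Hochberg across all genes
   (`statsmodels.multipletests`). Differentially expressed genes (DEGs)
   require `padj ≤ 0.05` **and** `|lfc| ≥ 1`, both boundaries inclusive.

This is *not* a DESeq2 re-implementation: there is no dispersion shrinkage,
no fold-change shrinkage, and no independent filtering, so its output will
differ from DESeq2's on the same data. The DE table TSV doubles as an
import format, so a DESeq2 table computed elsewhere can be spliced into
the pipeline unchanged (`inputs: de_table:` in the config).

A small qPCR utility implements the relative fold change
`2^−ΔΔCT = 2^−[(CTtarget−CTref)case − (CTtarget−CTref)control]`.

## Differential methylation

The study design this targets pools many retinas into **one** library per
condition, so no replicate variance exists and per-CpG testing uses the
two-sided Fisher exact test on the 2×2 methylated/unmethylated table
(`scipy.stats.fisher_exact`; an exhaustive hypergeometric enumeration
serves as the test-suite oracle). A replicate-aware logistic-regression
path is a documented stub.

Before testing, each condition is filtered to coverage `≥ 10` and below
its own 99.9th-percentile coverage (a PCR-duplicate guard); a CpG must
pass in both conditions. Symmetric-CpG strand collapsing (a `+/−` pair at
positions `p, p+1` merged to `p` with summed counts) is on by default and
roughly doubles effective coverage.

A **DMP** (differentially methylated position) requires genome-wide BH
`q ≤ 0.01` and `|β_case − β_ctrl| ≥ 0.25` (methylKit-convention defaults,
both configurable). A **DMG** (differentially methylated gene) is a gene
whose gene body or promoter holds `≥ 5` DMPs; its direction is the
majority DMP direction, ties broken toward the larger summed `|Δβ|` so
every DMG gets exactly one direction. Per-CpG power is the limiting
factor here — at 60× collapsed coverage the sampling sd of the observed
`Δβ` is ≈0.09–0.13, so the 0.25 effect gate removes a nontrivial share of
genuinely shifted CpGs; the gene-level ≥5-DMP rule is what restores
sensitivity at the unit biology actually cares about.

Promoters are strand-aware TSS windows, default `[TSS−1500, TSS+500)`,
clamped at the chromosome start; gene bodies come from GFF3 (1-based
closed, converted) or BED (0-based half-open, as-is). All internal
coordinates are 0-based half-open; a 1-based CpG at `p` is in `[s, e)` iff
`s ≤ p−1 < e`, and a CpG inside several genes' regions counts in each.

## FEM integration

**Node statistic.** Per gene, two signed scores: the methylation score is
a Stouffer combination over the CpGs of the chosen region level (gene
body or promoter), `z = Σ sign(Δβᵢ)·Φ⁻¹(1−pᵢ/2) / √n` with each term
capped at |8|; the expression score is the DE Wald statistic. Each score's
magnitude is rank-normalized to (0, 1] across graph genes (average ranks
for ties, the largest maps to 1), and the node weight is the mean of the
two rank scores. Rank normalization makes the integration scale-free
across the two assays — and it also fixes the null weight pool to a
uniform grid, which is what makes the permutation test below exact.
StringDB confidence is used only as an edge filter (default ≥ 400);
an optional confidence multiplier on edge weights is off by default.

**Edge weight.** The average of the endpoint node weights.

**Search.** Seeds are the top-`n_seeds` genes by weight (ties
lexicographic). From each seed a deterministic greedy hill-climb grows the
module: at every step the neighbor maximizing the new mean induced edge
weight *M* ("modularity") is the candidate; it is accepted while the
module is below `min_module_size`, or while the mean weight of the edges
it brings in satisfies `marginal × γ ≥ M_current`. The gate is on the
*marginal* edges, not on the diluted overall mean — in a module with many
edges one weak edge barely moves the overall mean, and gating on it lets
the search absorb the entire graph. The tolerance γ (default **1.05**)
allows controlled expansion past local dips: 1.0 freezes the search at
the minimum size, while ≳1.08 lets it leak across weak bridges between
distinct hotspots (both regimes measured on synthetic studies). Ties are
lexicographic everywhere, so results are independent of node insertion
order.

**Significance.** Monte-Carlo permutation with two properties chosen for
exactness:

* the seed's weight is held fixed and only the other nodes' weights are
  shuffled — the seed was *selected* for high weight, and shuffling it too
  makes the test strongly anti-conservative (empirical CDF 0.20 at nominal
  0.05 under a global null);
* both the observed and every permuted search are scored by their
  **trajectory-peak modularity** (the maximum M reached at sizes
  ≥ `min_module_size` under the natural stopping rule), so the two sides
  are evaluated by the same functional regardless of where each stops.

With both in place observed and permuted scores are exchangeable under a
global null and `p = (1 + #{peak* ≥ peak_obs}) / (1 + B)` is exact
(measured ECDF(0.05) = 0.051 over 1000 null trials); the `+1` makes
`1/(B+1)` the smallest attainable value. Permutation streams derive from
the global seed plus a hash of the seed gene's name, so p-values do not
depend on processing order.

**Post-processing.** Near-identical detections from different seeds are
one biological module: single-linkage grouping at Jaccard ≥ 0.9 (inclusive)
merges them, reporting the union of seeds, the member set of the
highest-M member, and the minimum p. Modules with `p ≤ 0.05` are reported
as significant, exported to GraphML/JSON with per-node methylation state
(hyper/hypo/none), expression state (up/down/none) and weight.
*Concordant genes* are DMGs that are also DEGs; the default
`anticorrelated` convention takes (hyper ∧ down) ∪ (hypo ∧ up), and `any`
takes the plain intersection, since the direction convention is a
reporting choice. Module gene sets can be tested against GMT collections
with a one-sided hypergeometric over-representation test, BH-adjusted
across sets.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes and
provides the recovery oracle for every stage. Defaults are the package's
reference study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `n_genes` | 200 | genes on one synthetic chromosome (10 kb stride, 2 kb bodies, random strand) |
| `n_samples_per_group` | 6 | RNA-seq replicates per condition |
| `graph_model` | Barabási–Albert, m=2 | scale-free PPI scaffold; Watts–Strogatz and stochastic-block alternatives |
| `n_modules`, `module_size_range` | 2, (15, 15) | planted connected modules, grown by random BFS |
| `lfc_effect` | 2.0 | planted \|log2 fold-change\| for module genes |
| `meth_diff_effect` | 0.4 | planted promoter β shift for module genes |
| `nb_dispersion` | 0.05 | NB dispersion of counts (typical bulk RNA-seq replicate level) |
| `mean_coverage` | 30 | per-strand mean RRBS coverage (NB, dispersion 0.1) |
| `bb_rho` | 0.05 | beta-binomial overdispersion of methylation counts |
| `cpgs_per_promoter` | 8 | CpGs per promoter (RRBS enriches promoter CpGs) |
| `anticorrelated` | true | hypermethylated promoter ⇒ downregulated gene |

RNA-seq counts are gamma-Poisson with baseline means log-uniform in
[50, 5000]; RRBS sites are strand-resolved `+/−` records per CpG with a
shared methylation level and independent coverage (so downstream
collapsing behaves as on real coverage files); promoter baselines are
uniform in [0.2, 0.8], truncated so the shifted level stays in [0, 1].
Planted modules are connected, pairwise disjoint, and grown with a one-hop
buffer between them — on a scale-free graph two random 15-gene modules
otherwise share direct edges and form a single hotspot, which would make
per-module recovery ill-posed for any detector. Non-module genes are
exactly null. Everything derives from `rng_seed` plus fixed stage tags:
identical configs give byte-identical files.

What the generator does **not** emulate: read-level errors and bisulfite
conversion failure, mappability and CpG-density structure, GC and length
biases in counts, correlated expression between neighboring genes,
batch effects, and PPI false edges/missing edges beyond the random graph
model. Passing the recovery benchmarks therefore demonstrates the
*algorithms* behave as designed under their assumed sampling models, not
that real retinal RRBS/RNA-seq data meet those assumptions.

## Benchmark problem sizes

The test suite runs every stage at reduced scale so the whole suite stays
interactive: null calibrations use 2 000 genes × 10 seeds (DE), ~5 000
collapsed CpGs × 10 seeds (DMP), and 200 30-node graphs (FEM); the
planted-module recovery benchmark runs 20 replicate studies at the default
conditions with the analysis set to `n_seeds = 30`, `B = 199` permutations
and `min_module_size = 10` — the module scale that benchmark targets —
while the package defaults stay at `n_seeds = 100`, `B = 1000`,
`min_module_size = 5` for real analyses. `scripts/acceptance.py` uses the
same benchmark-scale configuration.

## Known limitations

* The Fisher pooled test treats reads as independent; overdispersion
  between biological replicates is absorbed only via the effect-size gate,
  so pooled designs trade replicate inference for coverage.
* The DE engine is intentionally simpler than DESeq2; import externally
  computed tables when exact parity matters.
* Greedy search finds one local optimum per seed; deduplication across
  many seeds mitigates but does not guarantee global optimality.
* Permutation exactness is per seed gene; reporting the minimum p across
  the seeds merged into one module is a mild selection that the
  module-level p does not correct for.
* The node weight treats both omics equally; there is no weighting by
  assay reliability or CpG count beyond the Stouffer √n.
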