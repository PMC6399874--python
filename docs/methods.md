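# Methods

This note records the models, formulas, defaults and design choices behind
contrastkit, in the order data flows through the package.

## Input model and validation

The root inputs are a gene × sample matrix of non-negative integer counts
(genes in rows — the DE-engine convention; no orientation heuristics), a
sample metadata table whose IDs must cover the count columns exactly, and
per-contrast DE tables with columns mappable to
`{gene, mean_expr, log2fc, pvalue, padj}`. Header synonyms of the common
engines (`baseMean`/`logCPM`, `log2FoldChange`/`logFC`, `PValue`/`P.Value`,
`FDR`/`adj.P.Val`, …) are recognised, and the dialect is extensible. A
missing `padj` is representable (engines emit NA for genes removed by
independent filtering); a missing `pvalue` marks a corrupt row and is
rejected. All tables are UTF-8 TSV/CSV with `.` decimals and `NA`/empty as
missing; the delimiter follows the extension unless overridden.

## TMM normalization

The scale factors follow the canonical trimmed-mean-of-M-values recipe.
With library sizes $N_k$ (column sums), the reference $r$ is the sample
whose 75th-percentile CPM is closest to the mean 75th-percentile CPM (ties:
earliest column — determinism). For sample $k$, over genes with positive
counts in both $k$ and $r$:

$$M_g = \log_2\frac{y_{gk}/N_k}{y_{gr}/N_r},\qquad
  A_g = \tfrac12\log_2\!\left(\frac{y_{gk}}{N_k}\cdot\frac{y_{gr}}{N_r}\right),\qquad
  w_g = \frac{N_k-y_{gk}}{N_k y_{gk}} + \frac{N_r-y_{gr}}{N_r y_{gr}}$$

The top and bottom 30% of genes by $M$ and 5% by $A$ are trimmed
(intersection kept; both fractions are parameters, defaults chosen as the
recipe's conventional values), and
$f_k = 2^{\sum w_g M_g / \sum w_g}$, rescaled so the factors have geometric
mean 1. Columns that are scalar multiples of one another therefore get
factors of exactly 1. Note that scaling a single column is *exactly*
absorbed in the $M$/$A$ statistics, the trim and the reference choice, but
shifts the inverse-variance weights slightly; factors are invariant to
column scaling only up to that weight effect (≲0.2% on matrices of
realistic size).

Transforms: `cpm` $= 10^6 y/(N f)$; `log2cpm` $= \log_2(\mathrm{cpm} + c)$
with pseudocount $c=1$; `reglog` $= \log_2\!\big(10^6 (y+c)/(N f)\big)$
with $c=4$. `reglog` adds the pseudocount on the raw-count scale before
scaling — a shrunken log that damps low-count variance and serves the
visual purpose of a regularized-log/variance-stabilizing transform without
a GLM fit (full rlog-style shrinkage is out of scope).

## Significance calls and the reference NB test

A gene is significant when `padj < p_cut` (strict — the common reading of
"padj < 0.05") **and** `|log2fc| >= lfc_cut` (non-strict). Missing padj is
never significant. Defaults `p_cut=0.05`, `lfc_cut=0`, always exposed.

The built-in two-group test puts counts on a common scale
$q = y/(Nf)\cdot G$ ($G$ = geometric mean of effective libraries $Nf$), so
moments keep their count-scale meaning. Per gene: group means $m_a, m_b$
on the CPM scale; $\widehat{\beta} = \log_2\frac{m_a+0.5}{m_b+0.5}$;
method-of-moments dispersion $\hat\alpha = (s^2-\bar q)/\bar q^2$ per
group, pooled by degrees of freedom and floored at $10^{-8}$; delta-method
standard error of $\widehat\beta$ using
$\operatorname{Var}(\bar q) = (\mu + \alpha\mu^2)/n$; two-sided normal
(Wald) p-value; BH adjustment. Swapping groups exactly negates
$\widehat\beta$ and preserves p. The test is intentionally minimal — no
dispersion shrinkage, no independent filtering, no multi-factor designs —
because its role is fixture generation and pipeline testing; external
engines remain the intended source of contrast tables. At $n=5$ per group
the moment estimator makes the test mildly anti-conservative in the far
tail (null KS ≈ 0.03–0.05 at 2000 genes), which is acceptable for that
role.

## Aggregation semantics

`aggregate` takes the union or intersection of the per-contrast significant
sets at the stated cuts, then re-extracts `lfc` and `padj` from **every**
contrast for every retained gene; the boolean `sig` matrix preserves which
cells actually passed. This re-extraction is what makes cross-contrast heat
maps and profile plots well-defined for genes significant in only some
contrasts. Genes absent from a contrast's table are retained with missing
cells under union, and excluded under intersection (intersection demands
evidence everywhere). Rows are ordered lexicographically by gene ID,
columns by input order; an empty intersection is a valid empty master with
a warning. `filter_master` applies cuts cell-wise with `any`/`all` scope
(missing cells never pass), is idempotent, and appends its parameters to a
provenance trail exported alongside the three matrices.

Sorting statistics (`max`, `min`, `mean`, `variance`, `sd`) summarise each
gene's lfc row; `variance`/`sd` use the $n-1$ denominator, a
single-contrast spread is defined as 0, and ties break lexicographically by
gene ID so orderings are reproducible.

Agreement densities are Gaussian KDEs (per-contrast Silverman bandwidths)
of padj or lfc over the master genes, evaluated on one shared grid padded
by four of the largest bandwidth — enough that each curve integrates to 1
within $10^{-3}$ (the package-wide normalization tolerance; three
bandwidths, the single-curve default, can truncate up to ~0.3% of
edge-kernel mass).

## Distances, clustering, MDS, overlays

Euclidean distances accept any real matrix. The Poisson dissimilarity is a
deviance divergence: with size factors $s_i = N_i/\text{geomean}(N)$ and
$x' = x/s$, for samples $i,j$ and $\mu_g = (x'_{gi}+x'_{gj})/2$,

$$d(i,j) = \sqrt{\sum_g x'_{gi}\ln\frac{x'_{gi}}{\mu_g} +
                       x'_{gj}\ln\frac{x'_{gj}}{\mu_g}}$$

with $0\ln 0 = 0$ — symmetric, non-negative, and zero iff the
depth-adjusted profiles coincide, so pure sequencing-depth differences
vanish. It requires raw counts (a log-scale matrix would make the
likelihood reading meaningless).

Agglomeration is implemented in-package so tie-breaking is part of the
contract: among equally close pairs, the one whose sorted smallest member
IDs compare lowest merges first. The result uses the standard SciPy linkage
encoding, so cutting, leaf ordering and cophenetic distances reuse
`scipy.cluster.hierarchy`; trees export to Newick with branch lengths equal
to height differences. Default linkage is complete — compact clusters and
monotone merge heights for the distance heat map.

Classical (Torgerson) MDS double-centers $-\tfrac12 J D^2 J$ and scales the
top-k eigenvectors by root eigenvalues; negative eigenvalues (non-Euclidean
input) become unused zero axes, and each axis's sign is fixed so its
largest-magnitude coordinate is positive. Distances computed from planar
points are recovered to numerical precision. Group overlays are either
normal-theory confidence ellipses — sample covariance scaled by
$\chi^2_2(\text{level})$, default level 0.95 (scale 5.991), chosen over
data-peeling because it is closed-form and testable — or convex hulls
(counter-clockwise vertices). Groups with under three points, or degenerate
geometry, are skipped and reported rather than failing the whole overlay.

Profile clustering z-scores each gene's lfc row (zero-variance rows become
all-zero profiles; rows with missing cells are excluded and reported)
before complete-linkage Euclidean clustering cut into k groups — the
feature targets shape similarity, not magnitude.

## Statistical primitives

Wilcoxon rank-sum: the statistic is the rank sum W of group one. When
$n_1+n_2 \le 12$ and the pooled data is tie-free, the p-value is exact by
enumerating all $\binom{n_1+n_2}{n_1}$ rank splits (at most 924 — instant
and exactly testable); the two-sided exact p doubles the smaller tail, capped
at 1. Otherwise a normal approximation with tie-corrected variance and a
0.5 continuity correction is used; ties always take this path (exact tie
permutation enumeration is deliberately omitted). The method actually used
is recorded in the result.

Benjamini–Hochberg: step-up over non-missing entries only (missing stay
missing and do not count toward m), monotone via the cumulative minimum
from the largest rank, capped at 1.

KDE: Gaussian kernel, Silverman bandwidth
$0.9\min(\mathrm{sd}, \mathrm{IQR}/1.34)\,n^{-1/5}$ (a zero candidate is
skipped; if both are zero there is no automatic bandwidth and an explicit
one is required), default grid = data ± 3 bandwidths at 512 points.

## Plot registry and project workspace

Sixteen plot types are registered; the census counts pre- and
post-normalization boxplots separately and splits the aggregation agreement
density by the statistic shown (p-value vs fold change). Each type is a
pure data computation returning a `PlotData` (tables + parameters +
provenance) that serializes to TSV sidecars and reloads exactly
(`float_precision="round_trip"` on re-read), plus a renderer that is a pure
function of (PlotData, theme, size). Boxplot whiskers are Tukey's
1.5·IQR. Volcano y-values clamp `padj = 0` to the smallest positive padj in
the table, avoiding infinities deterministically. Heat maps cluster rows
(complete linkage, Euclidean on lfc) but keep user-supplied column order —
contrasts are usually ordinal (time), so column clustering is opt-in. Six
built-in themes supply palette and layout parameters.

Figure sizes follow one rule: row-indexed plots grow 0.15 in per displayed
row beyond 20 (clamped at 4× base height) and 0.3 in per column beyond 12
(clamped at 4× base width); everything else keeps the base size.

The project scaffold uses fixed directory names (`results/de_lists`,
`results/master`, `figures/{pdf,png,data}`, `logs`, `config`) so any
project is navigable without documentation. Re-initialization with `merge`
is idempotent and lossless; `refuse` protects non-empty directories.
Exports never overwrite (versioned `_v2`, `_v3`, … suffixes), names are
sanitized to filesystem-safe form, and every file written under `results/`
or `figures/` gets exactly one timestamped log line, so the scaffold can be
audited against the log. The config snapshot is flat key-value text —
diff-able and durable.

## Synthetic data

The generator emulates a miniature multi-time-point infection study: times
(6h, 1d, 2d) × treatments (ebov, restv, lps, mock), 5 replicates per cell,
2000 genes by default. Baseline means are log-normal (log2 mean 6, sd 1.5 —
typical bulk RNA-seq magnitudes), per-sample depth factors are log-uniform
in [0.7, 1.4] (so TMM is exercised non-trivially), and counts are negative
binomial with var $= \mu + \alpha\mu^2$, $\alpha = 0.05$ by default.
Planted effects multiply the mean by $2^{e}$ ($|e| = 2$, alternating sign)
for 200 genes per treated condition, with ebov and restv sharing 100 genes
so union and intersection merges differ informatively. Identical seeds give
bit-identical output; truth tables list the planted genes per
treated-vs-mock contrast.

What the generator does **not** emulate: batch effects and other
confounders, gene–gene correlation, outlier samples, GC/length biases, and
read-level artefacts. Passing tests therefore demonstrate correctness of
the algorithms under the stated model, not robustness to every property of
real data — the aggregation, geometry and registry layers are
model-agnostic, but the reference test's calibration claims are specific to
independent NB counts.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately small instances — 2000
genes × 10–20 samples for pipeline and calibration checks, ≤10 points for
geometry oracles, 300 genes for the rendering sweep — sizes at which every
oracle can be brute-forced and the whole suite stays fast. Key tolerances:
TMM vs oracle $10^{-10}$; exact Wilcoxon vs enumeration, equality; MDS
recovery $<10^{-8}$ Procrustes residual; KDE normalization $10^{-3}$;
distance-matrix invariants exact (asserted, not approximate). Degenerate
inputs are defined rather than left to chance: all-equal items embed at the
origin with a warning, zero-variance profiles z-score to zero, empty
intersections are valid empty masters, and every tie-break (reference
sample, merge order, sort order) is deterministic.

## Known limitations

- The reference NB test is not publication-grade inference (see above).
- No alternative normalizations (RLE/median-of-ratios, quantile,
  upper-quartile) and no rlog/VST beyond the shrunken log.
- Merge algebra is union/intersection only; k-of-n is a natural later
  extension.
- No t-SNE/UMAP, no dendrogram bootstrap support, no interactive output.
- "Group-wise dendrograms" are implemented as leaf-colored-by-factor with
  optional per-group subsetting, covering both plausible readings.
- The divergence plot shows the signed mean lfc of the significant up- and
  down-sets per contrast; a per-group deviation-from-grand-mean reading is
  a noted alternative.
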