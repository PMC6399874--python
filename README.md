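# contrastkit

Aggregation, exploration and visualization of multi-contrast RNA-seq
differential expression results.

## The problem

Complex transcriptomic experiments — several time points crossed with
several treatments — produce one differential-expression (DE) contrast per
comparison, each with its own set of significant genes. The statistical
engines that produce those per-contrast tables (DESeq2, edgeR, limma and
kin) stop there: comparing gene sets *across* contrasts, deciding whether
merging them is sensible, and visualizing the merged result is left to
ad-hoc scripting. contrastkit is a toolkit for that second half of the
analysis, for bioinformaticians and bench scientists who already have
per-contrast DE tables (or raw counts) and want reproducible cross-contrast
answers.

## What it does

- **Aggregation.** Given contrasts $c = 1..K$ with per-gene adjusted
  p-values $q_{gc}$ and log2 fold changes $\beta_{gc}$, a gene is
  *significant in c* when $q_{gc} < \alpha$ and $|\beta_{gc}| \ge \lambda$.
  The **master result set** is the union (or intersection) of the
  per-contrast significant sets, with $\beta_{gc}$ and $q_{gc}$ re-extracted
  from *every* contrast for every retained gene — so cross-contrast heat
  maps, profile plots and co-expression clustering always have a complete
  gene × contrast matrix. Agreement density plots (kernel densities of
  $q$ or $\beta$ per contrast over the master genes) show whether the merge
  was sensible.
- **Preprocessing.** TMM (trimmed mean of M-values) scale factors:
  for sample $k$ against reference $r$,
  $M_g = \log_2\frac{y_{gk}/N_k}{y_{gr}/N_r}$, trimmed 30% by $M$ and 5% by
  $A$, averaged with inverse-asymptotic-variance weights; CPM, log2-CPM and
  a shrunken-log transform; replicate merging; gene ID → name mapping.
- **A reference NB test.** A deliberately simple two-group
  negative-binomial Wald test (method-of-moments dispersion,
  var $= \mu + \alpha\mu^2$) so the whole pipeline runs and is testable
  without an external engine. External DE tables in any common header
  dialect remain the intended input.
- **Geometry.** Euclidean and Poisson-deviance sample distances,
  deterministic agglomerative clustering (complete/average/single),
  classical MDS with per-group 95% confidence ellipses
  ($\chi^2_{2}$-scaled covariance) or convex hulls, and z-scored
  fold-change profile clustering.
- **Statistics.** Wilcoxon rank-sum with an exact enumeration path
  ($n_1+n_2 \le 12$, tie-free), Benjamini–Hochberg adjustment, Gaussian KDE
  with Silverman bandwidth.
- **16 plot types, data first.** Every figure is computed as a `PlotData` —
  the exact numeric tables behind the plot, serializable to TSV — and
  rendered separately (pdf/png, 6 themes), so on-screen results are always
  re-loadable.
- **Project workspace.** `init_project` creates a fixed scaffold
  (`results/`, `figures/pdf`, `figures/png`, `figures/data`, `logs`,
  `config`); auto-export toggles write every figure plus its data sidecar
  with one audit-log line per file, and exports never overwrite.

## Worked example

```python
import contrastkit as ck

design = ck.SimDesign(times=("1d",), replicates=5, n_genes=2000, seed=1)
sim = ck.simulate_counts(design)                      # counts + metadata + truth
nf = ck.tmm_factors(sim.counts)
contrasts = [
    ck.nb_reference_test(sim.counts, sim.metadata, "treatment", t, "mock", nf)
    for t in ("ebov", "restv")
]
union = ck.aggregate(contrasts, mode="union", p_cut=0.05, lfc_cut=1.0)
inter = ck.aggregate(contrasts, mode="intersection", p_cut=0.05, lfc_cut=1.0)
print(f"union master: {union.n_genes} genes x {len(union.contrast_names)} contrasts")
print(f"intersection master: {inter.n_genes} genes")
print("overlap counts:", union.overlap_counts().value_counts().sort_index().to_dict())
order = ck.sort_genes(inter, stat="variance", descending=True)
print(inter.lfc.loc[order[:3]].round(2))
```

prints

```
union master: 299 genes x 2 contrasts
intersection master: 99 genes
overlap counts: {1: 200, 2: 99}
       treatment:ebov_vs_mock  treatment:restv_vs_mock
gene
g0098                    3.03                     1.15
g0199                   -1.42                    -2.21
g0185                   -2.35                    -1.55
```

299 genes are significant in at least one of the two virus-vs-mock
contrasts, 99 in both (the simulation plants 200 affected genes per
contrast with 100 shared, so the union ≈ 300 and the intersection ≈ 100
planted genes recovered). The overlap table counts genes by how many
contrasts call them significant, and the fold-change matrix shows the three
genes whose responses diverge most between the two viruses.

Any of the 16 plot types works on these objects, inside a project
workspace:

```python
pl = ck.init_project("ebola_study")
pd_ = ck.compute_plot_data("gene_heatmap", master=union,
                           params={"top_n": 30, "stat": "variance"})
ck.save_plot(pl, pd_, theme="colorblind", name="top30")   # pdf + png + TSVs
```

The same pipeline is available from the shell:
`contrastkit init|simulate|normalize|test|aggregate|plot|export`.

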