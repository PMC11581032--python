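# ddstress

Analysis toolkit for **compartment-specific unfolded-protein stress**
experiments built on destabilizing domains (DDs): engineered protein domains
that fold only while bound to a stabilizing ligand, so that ligand withdrawal
acutely exposes cells to a single species of unfolded protein in a chosen
compartment (nucleus-localized *NucDD* vs cytosol-localized *CytoDD*).

The package implements the complete computational arm of such a study, for
bench scientists and computational biologists who want a reproducible,
scriptable version of each readout:

- **Degradation kinetics** — mean fluorescence of the DD-sfGFP fusion over a
  withdrawal time course, fit to first-order decay
  `F(t) = b + (F₀ − b)·e^(−kt)` with half-life `t½ = ln 2 / k`.
- **Proteasome activity** — degron-reporter readout `A(t) = F(0)/F(t)`
  (the inverse of reporter fluorescence relative to the unstressed state),
  with cis/trans compartment comparisons.
- **Time-course differential expression** — median-of-ratios normalization
  and a negative-binomial Wald test (`z = log₂FC / SE`, Var = μ + αμ²) of
  every post-withdrawal timepoint against the 0-min sample of the same cell
  line; DEGs at |FC| > 1.4 and BH-adjusted p < 0.01; per-timepoint
  *common* (both cell lines) vs *distinct* (one cell line) classification.
- **Trajectory clustering** — dynamic-time-warping distances on per-gene
  fold-change trajectories, an exact k-medoids (k = 2) partition into
  common/distinct sets, and Ward sub-clustering into expression-pattern
  clusters C1–C3 / D1–D3.
- **Pathway enrichment** — hypergeometric overrepresentation of clusters
  (ranked by fold enrichment `(k/n)/(K/N)`) and preranked GSEA on the Wald
  statistic, with NES summaries (median across timepoints; sum over the
  late 60/120/240-min timepoints).
- **Cell-cycle gating** — automated assignment of DNA/EdU flow events to
  G1 / early S / late S / G2-M from data-derived mixture-model gates.
- **Synthetic data** — generators for every input with planted ground truth
  (negative-binomial counts with planted gene modules, log-normal flow
  events, multinomial cell-cycle populations), so that every stage can be
  scored against known truth.

## Worked example

```python
from ddstress import simulate, dge, trajectories, flow

# 1. simulate the study design: 5000 genes, 2 cell lines x 6 timepoints x 5 replicates
cfg = simulate.SimConfig(seed=1)
counts, meta, truth = simulate.generate_timecourse_counts(cfg)

# 2. differential expression vs the 0-min reference of each cell line
results = dge.run_contrasts(counts, meta)
called = dge.call_degs(results)            # |FC| > 1.4, BH padj < 0.01
deg_genes = sorted(called.index[called["deg"]].unique())
print(f"{len(deg_genes)} DEGs out of {len(results.index.unique())} detected genes")

# 3. two-step trajectory clustering: common/distinct partition + Ward sub-clusters
traj = trajectories.build_trajectories(results, deg_genes, ("NucDD", "CytoDD"))
dist = trajectories.pairwise_dtw(traj, "cross_condition")
part = trajectories.orient_partition(trajectories.pam(dist, k=2), traj)
sets = trajectories.gene_sets(part, traj)
print(f"common set: {len(sets['common'])} genes, distinct set: {len(sets['distinct'])} genes")

# 4. degradation kinetics of the nuclear DD reporter
events = simulate.generate_decay_events(t_half=77, f0=1000, cv=0.3, seed=1)
fit = flow.fit_first_order_decay(flow.summarize_flow(events, "DD-sfGFP", "GFP"))
print(f"fitted half-life: {fit.t_half:.1f} min")
```

prints

```
297 DEGs out of 4995 detected genes
common set: 176 genes, distinct set: 121 genes
fitted half-life: 77.5 min
```

The 297 DEGs are the genes clearing both the fold-change and FDR thresholds
in at least one contrast; the k = 2 partition separates the genes responding
concordantly in both cell lines (common set — here dominated by the planted
`common_up`/`common_down` modules) from the nucleus-specific responders
(distinct set — the planted `distinct_nuc_up` module); and the decay fit
recovers the planted 77-min half-life from 20,000 noisy events per
timepoint.

A command-line interface mirrors the library
(`ddstress simulate|kinetics|dge|cluster|enrich|cellcycle|run-all`); the
`run-all` command executes every stage from a single YAML config and writes
a reproducibility manifest with input checksums and per-stage timings.

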