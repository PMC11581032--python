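# Methods

This note records the models, conventions and design choices behind each
stage of the pipeline, in the order the pipeline runs them. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic data and what it emulates

The generators reproduce the *design* of a compartment-specific
unfolded-protein stress experiment: two engineered cell lines (nuclear- and
cytosol-localized destabilizing domain, "NucDD" / "CytoDD"), a ligand-
withdrawal time course at 0/15/30/60/120/240 min, and five biological
replicates per condition-timepoint.

**Counts.** Gene g in sample s (condition c, time t) is negative-binomial
with mean `mu_g * 2^FC_gc(t) * s_s` and dispersion alpha (Var = mu +
alpha*mu^2). Defaults: 5000 genes; baseline means log-normal with ln-scale
location 4.0 and scale 1.5 (median ≈ 55 counts, a realistic bulk library
after filtering); global dispersion 0.05 (typical for biological replicates
of a cell line; per-gene overrides allowed); per-sample depth factors
uniform in [0.7, 1.3]. Planted modules: `common_up` (150 genes, both
conditions, log2FC trajectory 0/0/0/0.2/0.5/1.0), `common_down` (100 genes,
the mirror image), and `distinct_nuc_up` (120 genes, NucDD-only
0/0/0/0.3/1.0/1.5, CytoDD flat). The distinct module is deliberately the
strongest and strictly late-onset, emulating a nucleus-specific stress
program (a p53-like late induction); the common modules emulate the shared
late stress response. Trajectories are piecewise-linear in log2 space and
anchored at 0 at t = 0.

**Flow events.** Event intensities are log-normal around the target mean
with a specified coefficient of variation (flow intensities are positive
and right-skewed; truncation is unnecessary by construction). Decay events
follow `F(t) = b + (F0 - b) e^(-t ln2 / t_half)`; reporter events have mean
`F0 / A(t)` for a planted relative-activity profile with A(0) = 1.

**Cell-cycle events.** Four phases sampled multinomially. G1 and G2/M sit
at log-normal DNA peaks (defaults 100 and 200 a.u., cv 0.05) with
EdU-negative intensities; S-phase events are EdU-positive with DNA uniform
over the lower (early S) or upper (late S) half of the 2N-4N interval,
times log-normal noise.

**What the generator does not emulate:** batch effects, mean-dependent
dispersion trends, gene-gene correlation, doublets and debris in flow data,
spectral spillover, and library-preparation artifacts. Passing tests
therefore demonstrate correctness of the algorithms under the stated
stochastic model, not robustness to every failure mode of real data.

**Seeding.** One global integer seed expands into per-generator substreams
via fixed offsets (`SeedSequence([seed, offset])`), so adding a generator
never perturbs another's stream, and every output is bit-reproducible given
(config, seed).

## Degradation kinetics and proteasome activity

Mean fluorescence per timepoint is the arithmetic mean of event intensities
(matching the "mean fluorescence intensity" convention of cytometer
software); a minimum group size (default 1000 events) guards against
unstable means. The decay fit is nonlinear least squares
(`scipy.optimize.curve_fit`) of `F(t) = b + (F0 - b) e^(-kt)` with
parameters bounded positive, initialized from a log-linear regression of
`F - floor` on t; parameter tolerance 1e-8. An additive floor is fit by
default because decaying reporters typically level off at a dark-cell
baseline — omitting the floor biases k downward when one exists; a
no-baseline variant is available. A non-decreasing series has no positive
decay rate and is reported as `converged=False` rather than an error.

Proteasome activity is defined as `A(t) = F(0)/F(t)`; A(0) is set to 1
exactly (it is a definition, not an estimate). The readout is antitone in
F by construction: reporter accumulation (rising F) reads out as falling
activity. Compartment comparisons report each (DD construct, reporter)
pair's minimum activity and its timepoint with a cis/trans flag derived
from the construct names.

## Differential expression

The statistical object is the Wald statistic z = log2FC / SE on
negative-binomial group means. The implementation is intentionally a
*simplified* NB Wald test, not a re-implementation of a full DE framework:

1. **Size factors** — median-of-ratios: per sample, the median over genes
   (expressed in all samples) of count / geometric-mean.
2. **Universe filter** — genes with nonzero total count in every
   (condition, timepoint) group; configurable.
3. **Dispersion** — per-gene moment estimator on the normalized scale,
   pooled across the two groups of a contrast, clipped to [0, 10], then
   shrunk toward a fitted `alpha(mu) = a0 + a1/mu` trend with a prior
   weight of 20 pseudo-degrees of freedom against the 8 residual df of a
   5v5 contrast. The strong shrinkage is what keeps the normal-tail p-value
   calibrated at n = 5: the per-gene moment estimate is far too noisy to
   plug into a Wald denominator directly.
4. **Effect and SE** — log2 ratio of group means with a pseudo-mean of 0.5
   added to each mean (stabilizes low-count genes); delta-method SE with
   `Var(mean) = (mu * mean(1/s) + alpha mu^2)/n`.
5. **Inference** — two-sided normal p; BH step-up within each contrast
   over tested genes only (all-zero genes get NaN and do not count toward
   m). DEG: `2^|log2FC| > 1.4` and padj < 0.01 on the unshrunk estimate;
   these thresholds are the study's fixed analysis constants.

Per timepoint, a gene is *common* if it passes in both cell lines,
*distinct* if in exactly one. Sample PCA uses log2(normalized + 1), keeps
the top 10% most variable genes, and projects samples onto the principal
components of the gene-centered matrix.

## Trajectory clustering

Each DEG contributes a NucDD and a CytoDD log2FC series with 0 prepended at
t = 0. Z-normalization is per gene over the concatenated 12 values
(population SD; constant rows map to all zeros), preserving the
Nuc-vs-Cyto magnitude contrast within a gene.

**DTW convention.** Steps {(1,0),(0,1),(1,1)} with unit weights, Euclidean
local cost, no window, no path-length normalization. With 6-point series,
windows and normalization add nothing; the convention is pinned by
exhaustive-enumeration tests.

**Two representations.** For *pattern* similarity (Ward sub-clustering),
genes are 2-channel series (Z-scored NucDD and CytoDD trajectories) and
D(i,j) is the multivariate DTW distance; warping is shared across channels,
so time stretches cannot cross the condition boundary. For the *k = 2
common/distinct partition*, the default is a concordance representation:
each gene's score delta = univariate DTW between its own NucDD and CytoDD
Z-series, with D(i,j) = |delta_i - delta_j|. The reason is structural: the
common set is defined by "responds the same way in both lines", not by any
particular shape. After row Z-normalization an up-regulated and a
down-regulated common gene are mirror images with a *large* mutual pattern
distance, so a k = 2 pattern clustering necessarily splits up from down
instead of common from distinct whenever the common set mixes directions.
The concordance score measures exactly the defining property, and the same
delta then orients the two clusters (lower median delta = common set). The
pattern representation remains available as a switch.

**k-medoids.** When the medoid-subset space is small (C(n,k) ≤ 200,000 —
which covers k = 2 partitions up to ~630 genes, i.e. every partition this
pipeline produces), the optimal medoid set is found by direct enumeration.
Beyond that, classic PAM (greedy BUILD, then best-improvement SWAP to
convergence, ties toward the lowest index) is used. SWAP is a local search
and can converge short of the global optimum — reference PAM
implementations share this behavior — hence the exact path whenever
affordable. Everything is deterministic; no randomness is consumed.

**Ward sub-clustering.** Ward.D2 linkage (scipy's Lance-Williams
implementation) on the pattern distances within each set, cut into three
clusters by default. Ward on DTW distances is formally a heuristic (DTW is
not Euclidean); it is applied as common practice and validated against
planted patterns. Within a set, clusters are named C1../D1.. in descending
order of mean late (final two timepoints) Z-scored fold change —
condition-averaged for the common set, NucDD-only for the distinct set —
so C1/D1 is always the strongest late up-regulation pattern regardless of
input order.

## Enrichment

**ORA** uses the upper-tail hypergeometric p `P(X >= k)` with the detected-
gene universe as background, set sizes filtered to [5, 500] after
intersection with the background, BH across retained sets, and rows ranked
by fold enrichment `(k/n)/(K/N)`.

**Preranked GSEA** ranks genes by descending Wald z (ties by gene ID).
Running sum: hits add `|z|^w` normalized by the set total (w = 1 default),
misses subtract `1/(N-K)`; ES is the signed maximum deviation, with exact
± ties resolved positive (a 1e-12 tolerance absorbs float noise). The null
is gene-sampling — n_perm (default 1000) random same-size draws from the
ranked list; with five replicates per group a phenotype-permutation null is
not meaningful, and gene sampling matches preranked semantics. NES divides
ES by the mean |ES| of same-sign permutations; p is the same-sign empirical
tail with (k+1)/(n+1) smoothing; BH across sets within a timepoint.
Significance for *display* is raw p < 0.05; padj is always reported
alongside. Summaries per set: the median NES over all supplied timepoints
(non-significant timepoints contribute their NES and are merely flagged)
and the sum of NES over the late 60/120/240-min subset; both rankings are
emitted. Permutation ES values are computed from sorted hit positions
(the running sum only changes slope at hits), which is value-identical to
the explicit running sum and keeps 1000 permutations per set affordable.

## Cell-cycle gating

Gates are derived from the data. The EdU positivity threshold comes first:
a two-component Gaussian mixture on log EdU, cut where the two components'
posteriors are equal (solved by bracketing between the component means).
The DNA mixture is then fit on the *EdU-negative* events only — S-phase
cells fill the 2N-4N interval and would otherwise drag both peak estimates
inward — with means initialized at (m, 2m), m a low-quartile location,
encoding DNA doubling. If the fitted peaks are not consistent with doubling
(ratio < 1.5, e.g. an all-G1 sample), the data are treated as
single-peaked: the 4N gate is synthesized at twice the robust 2N location
with a warning. Assignment: EdU-positive events are S phase, split
early/late at the arithmetic 2N-4N midpoint (exactly-at-midpoint counts as
late S); EdU-negative events must fall within peak ± 2.5 component widths
to be G1 or G2/M (nearer peak wins if the windows overlap), otherwise they
are `unassigned` — a reported category, included in the fraction
denominator. EdU is handled on the log scale (flow convention); DNA on the
linear scale (content is additive). All labels are scale-equivariant:
multiplying every intensity by c > 0 and refitting reproduces them.

## Pipeline, determinism and problem sizes

`run_all` validates every configured path before any compute, then runs
dge → clustering → enrichment → kinetics → gating, writing TSV/CSV/Newick/
JSON outputs and a manifest (config snapshot, seed, input SHA-256 checksums,
output list, per-stage wall time). A single seed drives the GSEA
permutations and any generator substreams; all other stages are
deterministic, so a rerun with fixed inputs and seed is bit-identical.

The test suite and acceptance script exercise the full standard design
(5000 genes × 60 samples), 20,000 events per flow timepoint, 50,000
cell-cycle events, 1000 GSEA permutations, and exhaustive oracles at small
sizes (series length ≤ 5 for DTW path enumeration, n ≤ 8 for k-medoids,
N ≤ 12 for the hypergeometric tail, lists ≤ 20 for the running sum) —
sizes at which enumeration is exact yet the whole suite runs in well under
a minute per module.

## Known limitations

- The NB Wald test trades DESeq2-style empirical-Bayes machinery for a
  transparent moment/trend estimator; calibration is demonstrated on the
  synthetic model (null KS, empirical FDR), not on real data with outliers,
  for which Cook's-distance-style filtering would be needed.
- Ward on DTW distances and the concordance-based k = 2 partition are
  pragmatic conventions; other defensible conventions (per-condition row
  normalization, pattern-based partitions at higher k) would partition
  borderline genes differently.
- The gating model assumes two EdU populations and two DNA peaks; it does
  not model doublets, apoptotic debris, or continuous S-phase DNA structure
  (no Dean-Jett-Fox fitting).
- FCS parsing is out of scope; flow inputs are event-level CSV exports.
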