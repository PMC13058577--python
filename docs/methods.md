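# Methods

This note documents the models and procedures implemented in `revokit`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic data generator does and does not emulate.

## Pool-seq allele frequencies and the filter chain

Pool sequencing estimates a population's reference-allele frequency as
ref reads / biallelic coverage. Two coverage regimes make that estimate
untrustworthy: very low coverage (sampling noise dominates; the floor is 3
reads by default) and coverage above the haploid pool size (more reads than
chromosomes in the pool indicates mapping or duplication artefacts). Such
cells are masked rather than dropped, because a locus that fails in one
population may be perfectly usable elsewhere.

The filter chain then runs in a fixed order: (1) drop loci with no
observation at all; (2) drop populations with ≥ 70 % missing cells (the
threshold is inclusive — "equal to or more than"); (3) drop loci still
missing in more than one population; (4) impute the remaining missing cells
with the per-locus median of the observed frequencies (median of an even
count is the mean of the two central values); (5) drop loci that became
monomorphic. Each stage's removals are reported, and the chain is
idempotent by construction. Imputation by the median keeps imputed values
inside the observed range and is robust to the skewed frequency
distributions typical of pooled data.

Sync-dialect parsing takes the stated reference base's count as the
reference count; the alternate allele is the most frequent non-reference
base summed over pools (ties broken A<C<G<T), and coverage is ref+alt — N
and indel columns are ignored. A minor-allele read-support floor
(`min_rc`) is available but off by default, since it belongs to upstream
variant curation rather than frequency estimation.

## Predictor reduction

Bioclim variables are heavily collinear, which destabilizes any regression
on them. The reduction workflow has four tools:

* **Correlation grouping.** Pairwise R² (squared Pearson correlation) is
  turned into the dissimilarity 1 − R²; complete-linkage trees cut at a
  set of heights give candidate partitions of the predictors.
* **Collinearity index.** With all predictors standardized (each carrying
  sum of squares N − 1), a grouping is scored by
  Σ SS(PC1) / (SS(total) − Σ SS(PC1)), where SS(PC1) of a group is
  (N − 1) × the largest eigenvalue of its correlation matrix. Groups of a
  single variable are excluded from the numerator (they form no synthetic
  component; a flag includes them for sensitivity checks). For a
  two-member group with correlation r next to one singleton the index is
  (1 + |r|)/(2 − |r|) in closed form — 0.5 for independent pairs, 2.0 for
  perfect ones — which the tests verify. Among candidate cuts the toolkit
  reports the index for each and defaults to the argmax over partitions
  with at least one multi-variable group; the choice is the user's.
* **Synthetic predictors.** Each multi-variable group is replaced by its
  PC1 scores (unit-norm loading vector; the alphabetically first member's
  loading is fixed non-negative, since PCA signs are arbitrary);
  singletons pass through standardized. Explained-variance fractions per
  group are reported so users can verify the synthetic set represents the
  original data (~90 % is typical for tight groups).
* **VIF pruning.** VIF_j = 1/(1 − R²_j) from regressing predictor j on all
  others; the largest VIF above 5 is removed (ties: alphabetically last
  goes) and VIFs recomputed until all survive. Perfect collinearity
  reports +inf and is removed first. A simpler greedy |r| > 0.8 pairwise
  filter is also provided for fitting the turnover model on raw
  (non-synthetic) variables, dropping from the worst pair the member with
  the larger mean absolute correlation.

**PCNM spatial covariates.** Geographic structure enters as principal
coordinates of a truncated neighbour matrix: Euclidean distances, truncated
at t = the longest minimum-spanning-tree edge; distances beyond t replaced
by 4t; Gower double-centering of −D²/2; eigen-decomposition. Axes with
eigenvalue > 1e−8 × the largest are kept, scaled by √eigenvalue, and the
first ⌈m/2⌉ of the m positive axes are used as model covariates — enough to
capture broad spatial structure without over-parameterizing a model fitted
on a few dozen populations. These are classical construction choices; the
truncation constant 4t and the tolerance are configurable only in code, as
they rarely matter.

## The turnover model

Each locus is regressed on the predictors with a bagged ensemble of
regression trees: bootstrap rows per tree, a random subset of
mtry = max(1, ⌊P/3⌋) candidate predictors per node (the regression-forest
convention), best split by squared-error reduction, leaves of at least 2
samples (populations are few, so deeper trees would memorize single rows),
200 trees per locus. Out-of-bag R² = 1 − MSE_oob/var(y) measures how much
of a locus's frequency variation the environment explains; loci with
R² ≤ 0 carry no signal and are excluded from aggregation.

Every split contributes its impurity decrease (normalized by the bootstrap
sample size and averaged over trees) to the bin containing its split
location — 200 equal-width bins per predictor across the training range.
Binned masses are weighted by the locus's R², summed over contributing
loci, and divided by their number; the running sum along each predictor is
that predictor's cumulative-importance function, a right-continuous
non-decreasing step function that is 0 at the training minimum and reaches
the predictor's overall importance at the maximum. The tree ensemble is
implemented as a flat numba kernel; one call grows a locus's whole
ensemble and routes out-of-bag rows down the partition simultaneously, so
hundreds of loci × hundreds of trees fit in seconds on one CPU. Per-locus
random streams are keyed on the locus id, making the fit invariant to
locus order and scheduling.

Model surface: `TurnoverForest` (specification + data) and
`TurnoverResults` (curves, importances, R² table, `summary()`, JSON
serialization). Transformation clamps values outside the training range to
the boundary curve values and flags them as extrapolation — offsets into
no-analogue climates are poorly constrained and the flag travels with the
results.

Candidate loci are those with out-of-bag R² ≥ 0.1 by default, the
conventional cut for calling a locus environment-associated in turnover
models.

## Genetic offset

Offset is the Euclidean distance between current and future positions in
cumulative-importance space, summed over climate predictors. Spatial (PCNM)
covariates are time-invariant: they are held at current values and
contribute zero. The phrase "distance between current and required future
allele frequencies" is operationalized in the transformed-climate space —
the computable realization of that idea, and the standard one for
turnover-based offsets.

Multi-period offsets are each computed against the same current baseline:
offset is accumulated mismatch relative to the composition assumed optimal
today, not a slice-to-slice step. This is also what makes the discrete
REvoRate well-defined (see below).

Scenario comparison uses the tie-corrected Friedman statistic
(k − 1) Σ (R_j − n(k+1)/2)² / (A1 − C1) with within-unit average ranks, and
Conover's post-hoc pairwise t-statistics |R_i − R_j| / √(2(nA1 − ΣR_j²)/((n−1)(k−1)))
on (n−1)(k−1) degrees of freedom, Benjamini–Hochberg adjusted across
pairs. The fully tied degenerate case returns statistic 0 and p = 1 with
the post-hoc skipped.

## REvoRate

The discrete Required Evolutionary Rate of transition k is
r_k = (G_k − G_{k−1}) / (t_k − t_{k−1}), with G_0 = 0 at the baseline
midpoint. Defaults: baseline midpoint 1985 (center of a 1970–2000 climate
normal) and period midpoints 2030.5, 2050.5, 2070.5, 2090.5 for the four
bidecadal projection periods; all configurable. Two identities follow and
are enforced by tests: Σ r_k Δt_k telescopes exactly to the final offset,
and the first transition's rate is proportional to its offset (period-one
linearity), so offset and rate can only diverge from the second period on.
Rates are signed — a negative increment means the optimum moved back toward
the current composition — with an absolute-value option; this is the
*minimum* (baseline) rate, since any path other than tracking the optimum
must be faster.

The instantaneous form dG/dt = Σ_p (∂G/∂E_p)(dE_p/dt) is evaluated with
symmetric central differences (O(h²); a Richardson check in the tests
verifies the order). It is offered for smooth, e.g. annually resolved,
trajectories; with bidecadal period data the discrete form is the honest
choice.

**Regimes.** Offset and |rate| are each called high when strictly above a
threshold (defaults: the dataset medians, since high/low is a relative,
qualitative contrast): high/high = adaptive stress, high/low = chronic lag,
low/high = transient stress, low/low = near equilibrium.

## Landscape maps, clusters, enrichment

The transformed grid is centered and PCA-decomposed; components 1–3
(zero-padded if fewer) are min–max scaled per channel to [0, 255] — per
channel rather than globally, so each component uses the full colour range.
Sign convention: the largest-|loading| predictor of each component gets a
non-negative loading. K-means (k-means++ initialization, 10 restarts) runs
over the requested k range and the mean silhouette width selects k. The
default criterion maximizes the silhouette — the standard reading; a
`lowest` flag implements the literal minimum for comparison.

Enrichment maps candidate SNPs to CDS by 1-based inclusive interval
containment (strand-agnostic; a CDS hit by several SNPs counts once) and
tests each GO term with the exact two-sided (minimum-likelihood) binomial
test against the genome-wide annotation frequency. The counting unit is
term-annotation occurrences — a CDS with k terms contributes k annotations
— matching how genome-wide term counts are tabulated; p-values are BH
adjusted within each ontology. No ancestor propagation over the GO graph is
attempted.

## The synthetic data generator

The generator emulates the study design the toolkit targets: a smooth
climate landscape (blurred Gaussian random fields; length-scale 4 cells by
default), 18–50 populations sampled without replacement from grid cells,
pools of 25 diploid trees at Poisson-distributed ~25× coverage with
binomial read sampling, and four bidecadal projection periods with additive
per-period trends plus optional noise. A fraction (10 % by default) of loci
are adaptive: their expected frequency follows a logistic cline
p(e) = 1/(1 + exp(−s(e − c))) on a single driving predictor, with centers
inside the observed gradient (20th–80th percentile) and slopes drawn from
[4, 8] on unit-range gradients — strong clines, the regime in which
turnover models are expected to work. Neutral loci draw population
frequencies around a uniform(0.05, 0.95) ancestral value with
truncated-normal drift noise (s.d. 0.05 by default).

What it does **not** emulate: linkage between loci, spatially explicit gene
flow, demographic history (bottlenecks, founder effects), shared population
structure confounding the environment, reference bias, or multi-predictor
(epistatic/pleiotropic) clines. Passing tests therefore demonstrate that
the machinery recovers a known architecture under clean conditions — they
do not certify detection power or calibration on real pool-seq data, where
structure–environment confounding is the dominant difficulty.

Problem sizes used in the test suite and the acceptance script — 40
populations, 200–500 loci, 200 trees per locus, 20-seed sweeps — were
chosen as the smallest sizes at which the recovery properties are stable
across seeds.

## Numerical and design notes

* Cumulative curves place each bin's mass at the bin center; evaluation is
  right-continuous (`searchsorted` side="right"), values clamp to 0 below
  the training range and to the total above it. Analytic curve objects
  (e.g. the identity map used in geometry tests) use linear interpolation
  instead.
* PCA/eigen signs are fixed by explicit conventions everywhere
  (alphabetically first loading, largest-|loading| predictor) so reruns
  are bit-identical.
* VIF and Pearson pruning break ties alphabetically (removing the
  alphabetically last tied name) for determinism.
* All stochastic operations take an explicit seed and derive per-locus or
  per-stage streams from it; the pipeline manifest records every seed.
* Degenerate inputs fail fast with the offending name in the message:
  duplicate predictor names, zero-variance predictors, duplicate
  coordinates (which break the MST truncation semantics), ref counts above
  coverage, non-partitions, misaligned unit ids.
* Pool-size-based population exclusion is exposed as a flag
  (`--min-pool-size`) rather than a rule, since a defensible general
  cutoff does not exist; the same goes for the choice of grouping cut
  height, where the index for every candidate cut is reported.

## Known limitations

* The turnover ensemble does not implement density-standardized split
  importances or conditional variants; importances of strongly correlated
  predictors are shared between them (hence the |r| > 0.8 pre-filter).
* Offsets in extrapolated climate are lower bounds: curves are flat beyond
  the training range, so genuinely novel climates saturate. The
  extrapolation flags should always be inspected before interpreting such
  cells.
* REvoRate is a demand-side quantity — the rate required, not the rate
  achievable; nothing here models selection intensity, heritability or
  effective population size.
* Gridded climate I/O is CSV (wide and long formats); georeferencing is
  carried as an affine transform on the grid object rather than embedded
  raster metadata.
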