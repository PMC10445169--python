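# Methods

## The pathway activity score (PAS)

`pasmatch` scores a single sample's expression profile against a collection of
gene sets (pathways) using only the within-sample expression *ranks*. For a
profile `x` over `N` genes, genes are sorted in decreasing expression and gene
`g` receives rank `i_g` (1 = highest). A pathway `P` scores

```
PAS(x, P, K) = Σ_{g ∈ P} max(K − i_g, 0) / (|P| · K)
```

Only members ranked within the top `K` genes contribute, with weight
decreasing linearly in rank. Scores lie in `[0, 1)`; a pathway of size
`m ≤ K` whose members occupy ranks `1..m` attains the maximum
`(K − (m+1)/2) / K`. Because the score is purely rank-based, it is invariant
to any strictly increasing per-sample transform of the expression values
(log, scaling, quantile shifts), which is what makes scores comparable
between tissue profiles and cell-line profiles quantified by different
pipelines or in different units.

Numerical conventions, chosen for determinism and documented because the
score is only defined up to them:

* **Ranks are 1-based**: the top gene contributes `K − 1`, not `K`.
* **Ties** are broken by descending value then ascending gene identifier, so
  a fixed matrix always yields the same rank permutation on any platform.
  Either tie convention perturbs a score by at most `1/K` per gene.
* **Normalization** divides by `|P| · K` where `|P|` is the *full* pathway
  size: a pathway member absent from the expression matrix stays in the
  denominator and contributes 0. This keeps scores comparable across matrices
  with different gene coverage, at the cost of deflating scores for pathways
  poorly covered by the platform. This is a convention, not a theorem; the
  alternative (shrinking `|P|` to the measured members) rescales each pathway
  row by a constant and therefore leaves the downstream sample-correlation
  analysis unchanged.
* `K` defaults to 3000 and is configurable; it should be small relative to
  `N` (a few thousand genes of a ~20k-gene transcriptome) so that truncation
  actually discards the noisy low-expression tail.

Gene identifiers are HUGO symbols matched by exact, case-sensitive string
equality. Housekeeping and immune/stromal marker genes can be removed before
scoring via a user-supplied exclusion list (one symbol per line, `#`
comments); the exclusion list's SHA-256 is recorded in the PAS matrix header
for provenance.

## Pathway selection

Class-predictive pathways are selected by L1-penalized **multinomial**
(softmax) logistic regression on the pathway × sample PAS matrix. PAS
features are standardized to zero mean and unit variance first, because the
lasso penalty is scale-sensitive and PAS ranges vary with pathway size. A
pathway is selected when any per-class coefficient exceeds `1e-8` in
magnitude. The solver is SAGA with warm starts along the penalty path; the
fit is deterministic given the data and seed.

The penalty (lasso weight λ; sklearn's `C = 1/λ`) may be given explicitly,
chosen automatically, or bisected to hit a target panel size:

* **`penalty="auto"`** runs stratified 5-fold cross-validation over a
  30-point log-spaced grid (`1e-2` to `1e2`) and applies the `lambda.1se`
  convention: the sparsest model whose mean CV loss is within one standard
  error of the minimum. CV loss is log-loss with predicted probabilities
  **capped at 0.99**. The cap matters: when classes are linearly separable —
  the regime this tool targets, since strong planted or biological signal
  separates classes perfectly — uncapped log-loss rewards ever-larger
  coefficient magnitudes, decreases monotonically along the whole path, and
  drags the chosen penalty to the weakest grid point, selecting scores of
  spurious pathways. Capping bounds each observation's contribution, so the
  loss curve flattens once a model classifies the held-out folds confidently,
  and the 1-SE rule then picks the sparsest such model. This trades a small
  amount of calibration sensitivity for selection stability.
* **`select_to_count`** bisects λ (geometrically, 50 iterations) for the
  largest selection size not exceeding a requested count, reporting a
  `target_reached` flag because the discrete lasso path can jump over a
  requested size.

Known limitation: the lasso keeps one representative of a group of strongly
correlated predictive pathways and may drop the rest; a recovered panel
should be read as "a predictive basis", not an exhaustive list of associated
pathways.

## Sample similarity and clustering

Similarity between two samples is the Pearson correlation (PCC) of their PAS
vectors over the selected pathway panel (at least 3 pathways). Samples with a
constant PAS vector have no defined correlation and are dropped with a
warning. Samples are clustered agglomeratively on distance `1 − PCC` —
sign-preserving, matching the blue/yellow convention of correlation heatmaps
— with average linkage by default (complete and single are available; the
choice is not critical for well-separated classes). Outputs are the reordered
correlation matrix (TSV), the leaf order, and the merge tree in Newick form
for external plotting; the package deliberately has no plotting dependency.

## miRNA profiling

Mature-miRNA composition within a sample group is reported as the percentage
of all sequenced miRNA molecules attributed to each species. The default
pools raw counts across the group's samples before dividing ("share of all
reads"); a `mean_fraction` mode that averages per-sample fractions is exposed
because the two differ whenever library sizes are unequal, and published
abundance figures rarely state which was used. A miRNA counts as "expressed"
with at least 1 read in at least 1 sample by default (`min_count`
configurable).

Differential-expression tables (feature, log2 fold change, BH-adjusted p) are
ingested, not recomputed — count-model DE belongs to DESeq2-class tools.
Volcano classification uses `p_adj < 0.05` and `|log2FC| > 1` (both strict);
top-N tables order by ascending adjusted p with ties broken by |log2FC|
descending then feature id.

## Target consensus and over-representation

Predicted targets of a miRNA from several databases are each intersected with
the significantly downregulated gene set; the consensus is the genes all
sources agree on, the union the genes any source proposes. Over-representation
of a category in a gene list uses the upper-tail hypergeometric test
`P(X ≥ k)` with enrichment ratio `(k/n)/(K/N)`, Benjamini–Hochberg corrected
across categories. The universe defaults to the genes in the DE table.
Database snapshots are deliberately not shipped — prediction sources drift
between versions — so target lists are plain two-column TSV inputs.

## Supporting statistics

* **Fisher's exact test** (two-sided, minimum-likelihood rule: sum of table
  probabilities ≤ the observed table's) via `scipy.stats.fisher_exact`.
* **Power analyses** use exact noncentral distributions, not normal
  approximations, so they agree with dedicated power software even at `df=2`:
  the two-sample t-test power uses noncentral t with `df = 2n − 2` and
  noncentrality `d·√(n/2)`; one-way ANOVA power uses noncentral F with
  `df = (k−1, N−k)` and `λ = f²·N`. (scipy's noncentral F is degenerate at
  `λ = 0`; the central F is substituted there.) Both are verified against
  brute-force Monte-Carlo simulation of the corresponding tests.
* **2^−ΔΔCt** relative quantification for qPCR.
* **IC50**: four-parameter log-logistic fit
  `bottom + (top − bottom)/(1 + (dose/IC50)^hill)` by bounded least squares,
  initialized from the data extremes and the log-midpoint of the dose range.
  A flat response or viability increasing with dose yields a warning and NaN
  IC50 rather than a meaningless estimate. Estimation quality depends on the
  assay design: when the dose range does not reach the lower plateau, IC50
  and the bottom parameter are confounded and the estimate can err by far
  more than the residual noise suggests.

## Synthetic data: what it emulates, and what it does not

The generators produce inputs with the statistical structure the analysis
assumes, so every stage is testable without external downloads.

* **Expression**: gene baselines are log-normal (gene-specific log-means
  drawn once per simulation, sd 1.5), giving the heavy-tailed rank structure
  that makes top-K truncation meaningful. Each class has a set of planted
  active pathways whose member genes receive an additive shift (default 2.0)
  on the natural-log scale *before* per-measurement noise (sd 0.2), so the
  planted signal is rank-stable at large effect. Defaults: 3 classes × 20
  samples, 200 pathways of 15–40 genes over 6000 genes, 10 active pathways
  per class — large enough to exercise selection, small enough that the
  end-to-end recovery run completes in a couple of minutes on one CPU.
* **miRNA counts**: per sample, a composition is drawn from a group-specific
  Dirichlet and counts from a multinomial at the library size. The default
  two-group specification places 21.5% of the tumor group's mass on
  hsa-miR-10a-5p and 14.5% of the benign group's on hsa-miR-143-3p, with 446
  expressed species in total, 4 samples per group and 5M reads per library —
  the composition structure of a deeply sequenced clinical small-RNA
  contrast. Total Dirichlet concentration 5000 keeps sample-to-sample
  compositional noise small.
* **Target lists**: each source contains the designed consensus genes plus
  extras disjoint across sources, so the true intersection is known.

Not emulated: negative-binomial count dispersion, batch effects, library
preparation biases, correlated pathway memberships of real gene-set
collections, and tumor-microenvironment admixture. Passing recovery tests on
these generators therefore demonstrates the *correctness of the machinery*
(scoring, selection, clustering behave as designed when their assumptions
hold), not the field performance of the method on real tumor/cell-line data.

## Reproducibility and sizes

All generators and fits take explicit integer seeds; no global random state
is touched. Pipeline runs write a manifest with a configuration hash and
SHA-256 checksums of every output, and re-running a stage from persisted
inputs reproduces its outputs bit-for-bit. The verification suite uses: 100
random instances for the PAS oracle comparison; the default 3-class planted
simulation for recovery; a reduced 2-class world (1500 genes, 80 pathways,
8 samples/class) for the 20-permutation null; 10^6 replicates for the
t-test Monte-Carlo and 10^5 for the ANOVA Monte-Carlo; exhaustive
enumeration up to a 12-gene universe for the hypergeometric test.
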