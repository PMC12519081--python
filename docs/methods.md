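# Methods

## Gaussian model and closed forms

All higher-order measures are computed under a multivariate Gaussian
assumption: every entropy reduces to a log-determinant of the covariance
matrix, so O-information and the redundancy-synergy index (RSI) become
ratios of determinants of Σ and its principal minors (see the README for
the formulas). This is a modeling choice, not an estimator of the true
(possibly non-Gaussian) information: for monotone-nonlinear but
rank-preserving dependence the Gaussian values understate the interaction,
and for purely nonlinear dependence with zero covariance they are blind.
Discrete, copula and kNN estimators are out of scope.

Units are nats throughout (natural logarithm), matching the closed forms.
Log-determinants are computed by Cholesky factorization; a failed
factorization raises `SingularCovarianceError` rather than returning NaN,
because singular minors are meaningful findings (duplicated or perfectly
collinear variables) that should stop an analysis loudly.

Covariances are estimated with the unbiased (n−1) denominator and no
regularization by default. An opt-in ridge adds `ridge · trace(Σ)/p` to the
diagonal for near-singular empirical matrices; it is recorded on the
`CovarianceModel` so results are traceable.

### RSI sign conventions

The determinant form RSI(S;Y) = I(S;Y) − Σᵢ I(Xᵢ;Y) is *positive* for the
canonical synergistic construction Y = X₁ + X₂ + noise (the joint MI
exceeds the sum of the marginals). The interaction-analysis literature that
pairs RSI with O-info instead uses negative values to mean synergy. Both
conventions are implemented (`printed` = the determinant form, `results` =
its negation) and `rsi(printed) + rsi(results) = 0` exactly; the default is
`results` so that "negative ⇒ synergy" is consistent across O-info and RSI.
The two conventions are deliberately not reconciled silently — the flag is
part of every result record.

## Tuple scans

O-info is evaluated over variable tuples of increasing order k (k ≥ 3; RSI
predictor sets from k = 1). At each order the scan enumerates all C(N, k)
combinations when that count is within the per-order budget (default
20,000) and otherwise draws distinct combinations uniformly at random under
the scan seed, reporting an `exhaustive` flag. Singular tuples are skipped
and tallied, never fatal. Exhaustive and sampled scans agree exactly
whenever the budget covers the order.

Derived summaries:

- **Top-fraction frequency maps** select the ceil(fraction · n) most extreme
  tuples per order (minimum side for synergy, maximum for redundancy;
  default fraction 5%, minimum one tuple) and report each variable's
  appearance frequency normalized by the number of selected tuples.
- **Minimal synergistic set**: the global extremum is taken across orders
  and the minimal set is the smallest order whose per-order extremum lies
  within a tolerance of it (default 1% of the extremum's magnitude — a
  plateau criterion; the defining plateau width is not sharply defined in
  general, so the tolerance is exposed). Exact ties break to the
  lexicographically first tuple.
- **Stabilization point**: discrete second differences
  d2[i] = s[i+1] − 2s[i] + s[i−1] over interior indices; the default rule
  returns the index of the minimum second difference ("steepest
  concavity"), ties to the first interior index. For decay-to-plateau
  curves the discrete d2 is typically nonnegative and its minimum sits at
  the plateau onset; because the geometric reading of "steepest concavity"
  is ambiguous for such curves, an alternative knee rule (argmax |d2|) is
  selectable but non-default.

## Histogram MI and significance

Pairwise MI between continuous variables uses equal-width histograms
(default 10 bins per variable; the bin count is exposed because no
principled default exists at these sample sizes) and the plug-in estimator
in nats. Significance is a permutation test shuffling the second variable
(default 1,000 permutations) with the add-one p-value
p = (1 + #{MI_perm ≥ MI_obs})/(1 + n_perm); the permutation null absorbs the
plug-in estimator's positive bias, so no analytic bias correction is
applied. Multiple testing is controlled with Benjamini–Hochberg FDR
(α = 0.05) and a pair is called significant only if it also clears an
effect-size floor (MI > 0.1 nats). The floor is interpreted in nats; at 10
bins and n ≈ 1000 the null MI sits near 0.04–0.09 nats, so the floor is a
real effect-size requirement, not a formality.

## Resampling inference

- **Bootstrap bands** draw `sample_size` rows without replacement (defaults
  50 repetitions of 1,000 rows), re-estimate the covariance, and re-evaluate
  a tuple list drawn once from the full data, so band width isolates row
  sampling from tuple sampling. Bands are percentile (2.5/97.5) intervals
  of a per-order statistic across replicates; the default statistic is the
  mean trajectory, with replicate min/max trajectories retained.
- **Surrogates** permute every column independently (preserving marginals
  exactly, destroying all cross-column dependence); the reported band is
  the per-order extrema across surrogates (default 100).
- **AUC summaries** integrate a trajectory trapezoidally over orders and
  split it by sign into a synergy area (negative part, reported absolute)
  and a redundancy area (positive part). By default the synergy area
  integrates the per-order minimum curve and the redundancy area the
  per-order maximum curve; a single summary curve can be requested instead.
  Group comparisons use the two-sided Mann–Whitney U test (exact
  distribution for tie-free groups up to 25, tie-corrected normal
  approximation otherwise).
- **Guard**: datasets with fewer than 100 samples, or a labeled class
  below 10% of cells, are excluded from resampling analyses (resampling
  artifacts dominate below these sizes; the 10% imbalance threshold is a
  package default, configurable).

## High-covariance subset selection

Samples are z-scored per variable (biophysical parameters span different
scales; the flag can be disabled for pre-scaled data), projected onto the
top n_components = 5 principal components, reconstructed, and ranked by
residual L2 norm in the standardized space; the n_keep = 1,000
lowest-residual samples are retained, ties breaking by original order. The
realized cumulative explained variance is reported rather than targeted.

## Gene-panel clustering and the ARI null

Expression preprocessing is log(1+x) followed by per-gene z-scoring, with
zero-variance genes dropped (warning) and a state machine preventing double
transforms. Clustering on a gene panel is PCA (≤ 50 components) → kNN graph
(k = 15, Euclidean in PC space) → Leiden community detection (RB
configuration modularity, resolution 1.0, fixed seed), built directly on
scikit-learn + igraph/leidenalg for determinism and speed. Cluster quality
is the adjusted Rand index against ground-truth labels (two single-block
partitions are defined to agree perfectly). Differential expression is
one-vs-rest rank-sum per gene per class with BH correction, classes under 3
cells skipped; the DEG table ranks the union of significant genes by best
adjusted p. The ARI null clusters `n_draws` random panels of matched size
(default 500) drawn from a configurable pool (all genes, or the DEG set)
with exactly the focal panel's configuration, and reports the focal ARI's
percentile within the null.

## Synthetic generators

Every generator takes a mandatory seed, is bit-reproducible, and stores its
full configuration and planted structure in the returned dataset's truth
block. What they emulate — and do not:

- `gen_independent`: iid standard normals; the global null.
- `gen_redundant`: latent-factor model X = LZ + E (coexpression modules).
  With a single unit-loading factor and unit noise, any triple's population
  O-info is ½ ln(32/27) ≈ +0.085 nats — a closed-form anchor used in tests.
- `gen_synergistic`: exact Gaussian conditioning of N(0, Σ_base) on
  w·X = y₀ + η, η ~ N(0, τ²) (accept-reject would waste draws and bias
  tails). Emulates a population constrained to a shared phenotype: the
  conditioning carves a degenerate manifold with anti-correlated variables
  and negative O-info. Supports multi-dimensional phenotypes (weight
  matrices), constraint on a planted subset among background variables, and
  a latent-factor base covariance (coregulation and constraint together).
  For a sum constraint on k exchangeable variables,
  τ = sqrt(−1/ρ − (k−1)) yields pairwise correlation ρ — the ρ = −0.45
  triple used in tests has population O-info ≈ −0.440 nats.
- `gen_cluster_mixture`: K tight isotropic clusters whose centers lie on a
  constraint manifold (every cell solves the same phenotype; each cluster
  is one cell's solution neighborhood). Sampling modes: `pooled`, `unique`
  (one draw per cluster — inherits the manifold's synergy) and
  `oversampled` (many draws from few clusters — the between-cluster
  separation acts as a shared discrete factor and reads as redundancy).
- `gen_feature_map`: target features as functions of parameters. The
  compact form is a 2-variable weighted sum plus noise (noise sd 0.5, so
  the planted RSI plateau is deep relative to sampling noise). The
  distributed form sums pairwise products of ~10 variables evaluated at a
  +1 offset: around a positive operating point (conductance-like
  parameters) each participating variable covaries with the product
  target, which keeps the nonlinear map visible to covariance-based
  measures — centered products would have exactly zero covariance with
  their inputs and be invisible by construction.
- `gen_counts`: zero-inflated rounded log-normal counts
  (π = 0.3, log-mean 1.0, log-sd 0.5) with per-subtype log-space shifts
  N(0, 1) on a planted panel (default 150 genes) and none on background
  genes; an optional per-cell latent factor plants coexpression on the
  panel. This is an input emulator for the clustering analyses, not a
  calibrated model of any sequencing protocol: it has no library-size
  variation, no gene-length effects, and mean-variance coupling only
  through the log-normal.

Because the generators are Gaussian (or log-normal) and low-dimensional,
passing tests demonstrates correctness of the measures and the *structural*
logic of the analyses — sign recovery, sampling-structure effects, panel
identifiability — not performance on real ensembles, whose marginals,
dimensionality and noise are richer.

## Experiment recipes and problem sizes

The `recipes` module fixes each end-to-end experiment's ensemble structure
(factor loadings, constraint weights) with an internal structure seed, so
the experiment is one well-defined study and the caller's seed drives
sampling only. Desk-scale problem sizes were chosen so each experiment's
effect is far from marginal at that scale:

- sign recovery: n = 800, p = 8, orders 3–6, 20 surrogates, 50 seeds;
- sampling structure: 72 clusters in 10 dimensions, 72 samples per draw,
  20 replicate draws per condition;
- high-covariance flip: n = 10,000, p = 12, 3 weak factors + 2 constraints,
  keep 1,000 of 10,000 on 5 components, orders 3–9, dominance judged by
  the sign-split AUC of the mean trajectory;
- minimal sets: n = 3,000, exhaustive scans to order 4, 20 seeds;
- FDR calibration: 30 variables, n = 1,000, 300 permutations per pair
  (p-resolution 1/301, which cannot inflate the rejection fraction);
- ARI null: 300 cells × 2,000 genes, 150-gene planted panel, 500 draws;
  percentile-uniformity check at 200 cells × 600 genes, 40 draws, 50 seeds.

## Known limitations

- Gaussian closed forms only; heavy tails or nonlinear dependence are
  outside the model (rank-transforming inputs first is a reasonable
  workaround the package does not automate).
- Sampled (non-exhaustive) scans estimate per-order extrema from a budgeted
  draw; extrema are biased toward zero relative to the true combinatorial
  extrema when the budget is a tiny fraction of C(N, k).
- The minimal-set plateau tolerance and the stabilization rule are
  conventions; both are exposed and logged rather than hidden.
- `adjusted_rand_index` of two single-block partitions is defined as 1, a
  determinism convention for degenerate clustering outputs.
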