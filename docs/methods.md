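# Methods

## Model

A dataset of paired nominal observations {(x_i, y_i)}, x_i ∈ V, y_i ∈ W,
optionally with a numeric weight per pair, is a bipartite network with
biadjacency (incidence) matrix `A` (m rows = V, n columns = W) and a
boolean mask marking which cells were observed. The package's central
assumption is that an unobserved cell is an *unknown* interaction, not a
zero: zero weights are valid observations, missing cells are excluded from
every statistic, and the arrangement of missing cells is itself an object
of analysis ("informative missingness"). Duplicate (row, col) pairs are
aggregated (mean by default; median/sum/first available) and node order is
first appearance in the input, so outputs are byte-reproducible.

## Nestedness temperature

The temperature quantifies how far an observedness pattern deviates from a
perfectly nested one (specialists interacting with subsets of generalists'
partners).

1. **Packing.** Rows and columns are sorted by decreasing presence count;
   ties break by the summed opposite-margin counts over the line's
   presences, then by the line's presence pattern in the current opposite
   order, then by original index. Sorting is iterated to stability (≤ 20
   passes). The pattern tie-key makes the packed matrix — and hence T —
   invariant under row/column permutation of the input up to identical
   lines.
2. **Geometry.** Cell (i, j) of the packed matrix (1-based, row 1 on top)
   maps to (x, y) = ((j − 0.5)/n, 1 − (i − 0.5)/m) in the unit square.
   The *isocline* is the curve y = (1 − (1 − x)^a)^(1/a), increasing from
   (0, 0) to (1, 1); the area above it is 1 − Γ(1 + 1/a)²/Γ(1 + 2/a), and
   the shape parameter `a` is solved (Brent's method on log a) so this
   area equals the observed fill. This one-parameter family was chosen
   because every diagonal of slope −1 crosses it exactly once, making the
   distance construction below total, and because the perfectly nested
   mask it induces is realisable on any grid (see the generator).
3. **Unexpectedness.** A presence strictly below the isocline or an
   absence strictly above it is *unexpected* (cells on the curve, within
   1e-12 in the signed superellipse residual, are not). For an unexpected
   cell, d is the distance from its point to the isocline along the slope
   −1 diagonal through the point (vectorised bisection, 80 iterations) and
   D the length of that diagonal inside the square; u = (d/D)². U is the
   mean of u over **all** m·n cells and T = 100·U/0.04145 (the classic
   scaling constant), clipped to [0, 100]. Fully empty or full matrices
   return T = 0 by convention; 1×n inputs are rejected.

By default the presence matrix is the observedness mask itself (the
temperature characterises the dispersion of missingness); a `positive`
criterion (observed weight > 0) serves the ecological binary use.

## Runs test and FDR

For a categorical sequence, the statistic is the number of maximal
constant-label runs. The observed count is compared with `n_perm` (default
5000) uniform random permutations of the same sequence — marginal label
frequencies preserved — and the lower-tail empirical p is
(1 + #{runs_perm ≤ runs_obs})/(n_perm + 1), floor 1/(n_perm + 1). The test
is one-sided because few runs mean clustered, non-random ordering; other
run statistics (e.g. longest run) are possible but not implemented.
Multiple tests are corrected with Benjamini–Hochberg step-up FDR
(delegated to statsmodels and cross-checked against the closed form in the
tests). Significance codes are the conventional ***/**/*/ns.

## Complete-submatrix extraction

Finding the largest missing-free block is NP-hard, so `extract_submatrix`
runs a deterministic two-member portfolio and keeps the better result:

* **greedy peel** — repeatedly remove the admissible line (row/column)
  with the most missing cells, preferring the removal that keeps the shape
  objective (remaining cells, or min(r, c)² for Square) largest; ties go
  to the larger dimension, rows before columns, lowest index;
* **forward selection** — add lines one at a time, in each step the line
  that maximises the resulting complete block, sweeping both orientations
  and keeping the best prefix.

Both candidates then pass a fixpoint **re-add** step restoring any removed
line that is fully observed on the survivors (for Square, re-adds happen in
row/column pairs after trimming the larger dimension), so the result is
always missing-free and maximal in the single-line sense. On random 4×4 to
6×6 masks with observedness in the range seen across the case-study
datasets (0.45–0.9), the portfolio attains at least 80 % — in practice
usually 100 % — of the exhaustive optimum; under far heavier missingness
(> 70 % missing) rare adversarial masks can fall below that ratio, which
is the price of polynomial time. Exact reproduction of block sizes
published for other heuristics is approximate by nature: multiple
similarly dense blocks usually exist.

The fixed-dimension modes keep one side whole; when that is infeasible
(some opposite line has no chance of completion) the most-missing opposite
lines are dropped first, with a warning.

## Projection and clustering

The projection on V has adjacency A·Aᵀ computed with missing cells set to
0 — the edge weight counts shared *observed* partners only, consistent
with the unknown-interaction reading; raw sums are used without
normalisation. Self-similarities (the product diagonal) are stored
separately; zero-weight pairs carry no edge. Weak edges can be pruned by
absolute threshold or weight quantile (node set unchanged; pruning all
edges warns).

Community detection delegates to python-igraph (walktrap, multilevel,
infomap, label propagation, leading eigenvector, spinglass, fast greedy);
the stochastic methods are seeded through igraph's RNG, and spinglass runs
per connected component with offset cluster ids. Each partition is scored
with hand-implemented Newman–Girvan modularity Q = Σ_c (e_cc − a_c²)
(weighted degrees; cross-checked against igraph in the tests) and with the
average silhouette width under a fixed metric convention: pairwise
distances are shortest paths with edge length 1/weight, unreachable pairs
are assigned twice the largest finite distance, single-cluster partitions
are undefined (NaN), and all-singleton partitions score 0. Under this
convention two disconnected cliques with the clique partition score
exactly 0.5 (within-distance d, between-distance 2d), independent of the
edge weight. External validation against prior labels uses pair counting:
Rand = (a + d)/total, Jaccard = a/(a + b + c).

## Imputation

* **mean/median** — missing cell (i, j) gets the average of the row-i and
  column-j statistics over observed cells; empty margins fall back to the
  global statistic. The row/column-symmetric form was chosen because it
  treats the two nominal variables identically.
* **ALS** (rank r = 2, ridge λ = 0.01, tol 1e-6, ≤ 100 iterations) —
  factors U, V minimise Σ_observed (A_ij − u_i·v_j)² + λ(‖U‖² + ‖V‖²) by
  exact alternating ridge solves over observed cells, so the penalised
  loss is non-increasing (asserted in tests). Initialisation is a warm
  start from the SVD of the mean-completed matrix plus a small seeded
  jitter: random initialisation of observed-only factorisation has poor
  local minima, while the warm start recovers e.g. a masked cell of a
  rank-1 matrix to within 0.05 for every seed tested.
* **CA** (n_dims k = 2, tol 1e-6, ≤ 100 iterations) — missing cells start
  at the mean-rule value; each sweep decomposes the completed
  correspondence matrix Z = D_r^(−1/2) P D_c^(−1/2) by SVD and rebuilds
  missing cells from the leading k dimensions, clipped at 0. The first
  dimension is the trivial (independence) one, so k = 1 reproduces the
  independence expectation r_i c_j N exactly and k = 2 adds the strongest
  association axis — the smallest structure-bearing choice, hence the
  default. Negative observed weights are rejected (use ALS).

Observed cells are never modified by any method (bitwise-preservation is
asserted), and convergence is measured on the missing cells only.

## Structure-preservation validation

`validate_edge_prediction` extracts the element-max complete submatrix,
projects and clusters it once (the benchmark), then imputes the full
matrix with each method, projects, clusters with the *same* algorithm and
seed — so index differences reflect imputation, not clustering
stochasticity — and restricts the candidate membership to the benchmark's
node set. Agreement is summarised by Sørensen–Dice, Fowlkes–Mallows,
Jaccard, Minkowski (lower is better) and Rand, all derived from the pair
counts (a, b, c, d); degenerate denominators yield 0 (or NaN for
Minkowski when a + b = 0). Methods are ranked by Jaccard by default
(Minkowski inverted when chosen). A single-cluster benchmark produces NaN
indices and no ranking. This deliberately measures preservation of
structure found in well-observed regions, not reconstruction accuracy in
the missing ones.

## Synthetic generator

The generator fixes the study conditions used throughout the tests:

* **modular** — k contiguous row blocks matched to k column blocks
  (defaults k = 2 on 40×30 matrices); weights ~ Normal(μ_in = 10, σ = 0.5)
  within blocks, Normal(μ_out = 1, σ = 0.5) between, clipped at 0 to stay
  CA-compatible. μ_in ≫ μ_out gives a clear planted partition that
  multilevel clustering recovers exactly from the row projection.
* **nested(fill)** — the fixed point of the isocline construction: the
  mask induced by the isocline is recomputed at its own empirical fill
  until stable (the fill map is monotone, so the iteration converges), so
  the generated staircase scores T = 0 exactly.
* **random(fill)** — i.i.d. Bernoulli presences; at fill 0.5 on 30×30
  grids the mean temperature is far from 0 (> 20), providing the hot
  baseline.
* Missingness: **MCAR(rate)** cell-wise i.i.d. masking; **block(regions)**
  rectangular regions masked entirely (the stand-in for the block-like
  gaps of survey/retail-style data); **threshold(τ)** masks cells with
  weight < τ (value-dependent, i.e. MNAR censoring). With τ between μ_out
  and μ_in on a modular matrix, missingness concentrates almost entirely
  between blocks. Note this produces a *modular* (block) missingness
  pattern: its nestedness temperature is typically **higher** than an
  MCAR mask at matched rate — anti-nested, rather than disordered — so
  structure should be read from the block concentration and the
  temperature together, not from a low temperature alone.

What the generator does **not** emulate: realistic mass-spectrometry
intensity distributions, correlated noise, degree heterogeneity within
blocks, or MAR mechanisms driven by observed covariates. Passing tests on
these synthetics show the pipeline recovers planted structure under clean
conditions; they do not certify behaviour on heavy-tailed or confounded
real data.

## Numerical choices and scales

Problem sizes in the tests (40×30 pipelines, 25-seed sweeps, 4×4–8×8
oracle comparisons, 5,000-permutation runs tests) were chosen so the whole
suite completes in well under a minute while keeping Monte-Carlo error
well below the asserted margins. Temperature's isocline parameter is
solved to 1e-14; diagonal crossings use 80 bisection iterations; ALS/CA
stop at 1e-6 improvements. The silhouette unreachable-pair penalty
(2× finite diameter) and the pruning rule (strictly-greater survival,
`weight ≤ t` removed) are fixed conventions. All randomness flows from
integer seeds (numpy `default_rng`, igraph RNG); identical seeds give
byte-identical JSON reports.

## Known limitations

* Temperature compares against a fixed isocline family; other families
  (and other published packings) yield numerically different T for the
  same matrix, so cross-package comparisons should be qualitative.
* The submatrix heuristic certifies only single-line maximality, not
  global optimality, and its near-optimality guarantee degrades under
  extreme (> 70 %) missingness.
* Null-model calibration of T and Q (e.g. degree-preserving
  randomisation) is out of scope.
* Spinglass on very small components (≤ 4 nodes) can fragment cliques;
  prefer the deterministic methods on tiny graphs.
* Imputation validation scores structure preservation in well-observed
  regions; it says nothing about accuracy inside large structurally
  missing blocks, particularly under MNAR censoring.
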