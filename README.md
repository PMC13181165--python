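# gapmine

Graph-theoretic mining of **structured missingness** in nominal data.

Paired nominal observations — drugs × patients, proteins × samples,
pollinators × plants, customers × products — form a bipartite network whose
biadjacency (incidence) matrix `A` is almost never complete. `gapmine`
treats the missing cells not as noise to impute away but as a signal in
their own right: the *shape* of the gaps (nestedness, modularity, blocks)
often encodes biological constraints, acquisition biases, or behavioural
structure. It is aimed at computational biologists and data scientists who
work with incomplete categorical association tables and want to
characterise the missingness before (or instead of) filling it in.

## What it computes

* **Incidence matrices** from long tables (`read_nominal_table`,
  `build_incidence`), with an explicit observedness mask — missing cells
  are unknown interactions, never true zeros — plus summaries and degree
  filtering.
* **Nestedness temperature** `T ∈ [0, 100]` (Atmar–Patterson style): after
  canonical packing, each cell is mapped to the unit square and scored
  against the isocline of the perfectly nested pattern with the same fill;
  `u_ij = (d_ij / D_ij)²`, `U = mean(u)`, `T = 100·U / 0.04145`. `T = 0`
  for a perfect staircase, large `T` for disordered missingness.
* **Runs-based permutation test**: the number of maximal constant-label
  runs in a sequence versus `n` random permutations of itself, lower-tail
  `p = (1 + #{runs ≤ obs}) / (n + 1)`, with Benjamini–Hochberg FDR
  correction across tests.
* **Complete-submatrix extraction** (`extract_submatrix`): deterministic
  peel/forward-selection heuristics for the NP-hard largest missing-free
  block, in element-max, square, row-preserving and column-preserving
  flavours.
* **Projections and clustering**: row projection `A·Aᵀ` (columns `Aᵀ·A`),
  optional weak-edge pruning, seven igraph community-detection algorithms
  (walktrap, multilevel, infomap, label propagation, leading eigenvector,
  spinglass, fast greedy), Newman–Girvan modularity
  `Q = Σ_c (e_cc − a_c²)`, average silhouette width, and external
  validation against prior labels (Rand, Jaccard).
* **Edge imputation and structure-preservation scoring**: mean/median,
  iterative correspondence analysis, and regularised alternating least
  squares; `validate_edge_prediction` ranks the methods by whether
  clustering the imputed network reproduces the complete-submatrix
  benchmark (Sørensen–Dice, Fowlkes–Mallows, Jaccard, Minkowski, Rand).
* **Synthetic generators** (`simulate_bipartite`): modular, nested and
  random weighted bipartite matrices with MCAR, block and value-threshold
  (MNAR) missingness — every pipeline stage is testable without downloads.

## Worked example

`examples/02_missingness_structure.py` generates a perfectly nested and a
random observedness pattern at the same fill and tests a blocked organism
label sequence for ordering randomness:

```
temperature, perfectly nested mask: T = 0.000 (fill 0.50)
temperature, random mask:           T = 64.210 (fill 0.47)
blocked organism labels: 3 runs, empirical p = 0.000200
BH-adjusted across 8 tests: p_adj = 0.00027 (***) -> ordering is non-random (clustered)
```

A nested mask scores exactly `T = 0` (every specialist's partners nest
inside a generalist's), a random mask runs hot, and three homogeneous
blocks of 100 labels produce the minimum attainable empirical p at 5,000
permutations (`1/5001`), which BH-adjusts to `0.00027` when six of eight
jointly corrected tests share that floor.

`examples/05_impute_and_validate.py` ranks the four imputation methods on
a 2-block synthetic matrix with 20 % MCAR missingness:

```
benchmark: 16 x 8 complete block, 2 clusters (multilevel)
method     dice     fm   jacc   mink   rand
mean      1.000  1.000  1.000  0.000  1.000
median    1.000  1.000  1.000  0.000  1.000
ca        1.000  1.000  1.000  0.000  1.000
als       1.000  1.000  1.000  0.000  1.000
ranking (best first): mean, median, ca, als
```

Indices of 1 (Minkowski 0) mean the clustering of the imputed network
coincides exactly with the non-missing benchmark — at this missingness
level every method preserves the planted 2-block structure.

The other examples cover incidence construction (`01`), submatrix
extraction (`03`) and projection clustering (`04`). A thin CLI mirrors the
library: `gapmine summarize|structure|extract|cluster|impute|validate|simulate --help`.

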