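# Methods

## Model and assumptions

The embedder places N points in 2-D (or 3-D) by minimizing

    L_total = L_t + α·L_g + β·L_s

where each term is a KL divergence between two pairwise-similarity
distributions over the N(N−1) ordered pairs:

* **L_t = KL(P‖Q)** — the classic t-SNE loss. P comes from Gaussian
  conditional affinities of the expression vectors with per-point
  bandwidths σ_i calibrated so that the base-2 Shannon entropy of every
  conditional distribution equals log₂(perplexity), then symmetrized as
  p_ij = (p_{i|j}+p_{j|i})/2N. Q is the Student-t (1 df) kernel of the
  embedding. This term preserves local neighborhoods only.
* **L_g = KL(P̂‖Q̂)** — "global" affinities proportional to
  1 + squared distance, computed on expression (P̂) and on the
  embedding (Q̂). Larger distances receive larger weight, so this term
  responds to large-scale geometry the Gaussian/Student-t kernels are
  blind to.
* **L_s = KL(Ŝ‖Q̂)** — the same construction on the 2-D image
  coordinates.

The closed-form gradient is

    4 Σ_j [(p_ij−q_ij) − α(p̂_ij−q̂_ij) − β(ŝ_ij−q̂_ij)] (y_i−y_j)(1+‖y_i−y_j‖²)⁻¹

and is verified against central finite differences of the full loss
(including all normalizations) in the test suite and the acceptance
script. With α=β=0 the gradient and the whole optimization reduce
exactly to t-SNE; `tsne_embed` is literally `spasne_embed` with both
weights zero.

The underlying assumption is that spatial position carries information
about cell state: when phenotype and position are uncorrelated, the
spatial term can only distort the expression structure, and β should be
set to 0.

All five similarity matrices are symmetric, zero-diagonal, nonnegative
and normalized to unit off-diagonal mass. The distance-proportional
denominators are taken over i≠j and the diagonals zeroed, so the five
matrices are directly comparable entry-wise; self-pairs carry no
structure. Everything is computed exactly and densely — O(N²) memory
and time — which is the regime the method targets (single tissue
sections, 10²–10⁴ points). No tree or sampling approximations are
implemented.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α | 10 (5 if no coordinates) | weight of the global expression term; raises r_g |
| β | 5 (0 if no coordinates) | weight of the spatial term; raises r_s, trades against r_g |
| perplexity | 50 | effective neighbor count for σ_i calibration; clipped to (N−1)/3 with a warning when N < 3·perplexity |
| max_iter | 1000 | the only stopping rule; "converged" means the budget completed |
| init_dim | 50 | PCA truncation used for the initialization |
| learning_rate | 200 | nominal step; see the step-scaling note below |
| momentum | 0.5 → 0.8 at iteration 250 | standard t-SNE schedule |
| early exaggeration | ×12 for 250 iterations | applied to P **only** — exaggerating P̂/Ŝ would silently rescale α and β, so the global terms are never exaggerated |
| k (trustworthiness) | 12 | neighborhood size; clipped to (N−1)/2 for small inputs and reported in the output |

### Numerical and design choices

* **Log transform.** "Natural log scale" is implemented as ln(1+x):
  UMI matrices are mostly zeros and the +1 shift keeps them at zero.
  PCA (200 components by default) centers but does not variance-scale
  features; panels with fewer genes than components (e.g., a 161-gene
  MERFISH panel) are used without reduction. PCA component signs are
  fixed so the largest-magnitude loading is positive, making results
  independent of the SVD backend.
* **Coordinate scaling.** The distance-proportional kernel is not
  scale-invariant, so raw pixel/micron units would implicitly rescale
  β. Spatial coordinates are therefore centered and scaled to unit
  root-mean-square radius before Ŝ is built (config-overridable). The
  expression matrix enters the global term exactly as produced by
  preprocessing. r_g and r_s are likewise computed against the
  processed (post-PCA) expression and the raw coordinates; Pearson
  correlation makes the coordinate scaling immaterial there.
* **Step scaling.** The gradient magnitude grows with 1+α+β. The
  update therefore uses step = learning_rate/(1+α+β), so each loss term
  sees the step size the classic schedule (lr 200, adaptive gains,
  momentum) was designed for; at α=β=0 the optimizer is the standard
  t-SNE optimizer unchanged. Without this rescaling, runs with α ≈ 10
  oscillate without settling and embedding quality degrades.
* **Initialization.** Top-50 PC scores of X, first 2 columns, rescaled
  so the leading column has standard deviation 1e-4 (scaling by the
  leading column preserves the scores' aspect ratio), plus seeded
  Gaussian jitter of the same 1e-4 scale. The jitter is what makes
  repeated runs with distinct seeds explore distinct optima — the
  screening protocol's repeat statistics (max over repeats, std of r_g)
  are meaningless for a fully deterministic run. Setting
  `init_jitter=0` recovers a deterministic, permutation-equivariant
  initialization (the equivariance property is tested in that mode,
  since seeded jitter is drawn by row position).
* **Floors and tolerances.** Affinity entries are floored at 1e-12
  before logs/divisions. The σ binary search runs at most 50 iterations
  or until the entropy is within 1e-5 bits of the target, with the
  precision bracket expanded geometrically. Losses are recorded every
  50 iterations (with the un-exaggerated P, so values are comparable
  across the exaggeration boundary).
* **Degenerate inputs.** Cells with zero total counts, single-label
  silhouettes, constant distance vectors, perplexity ≥ N, and β > 0
  without coordinates all raise descriptive errors. Rank-deficient
  initializations are padded with seeded Gaussian noise and logged.

## Screening protocol

The α/β trade-off is resolved empirically in two stages. First,
repeated plain t-SNE runs set a floor r_thres = max r_g. Then a rough
grid (α ∈ {2,5,10,20,30,50}, β ∈ {1,5,10,15,25}, 10 repeats/cell) and a
fine grid (α ∈ 5…20, β ∈ 1…10, 20 repeats/cell) are screened: per
repeat, r_g is zeroed when r_g ≤ r_thres, each cell reports the repeat
maximizing r_g·r_s, and the fine stage adds the standard deviation of
the (by default thresholded — the alternative is switchable) r_g values
as a stability penalty. The winner maximizes r_g·r_s·exp(1−std), ties
broken toward smaller α then smaller β; if every score is zero the
defaults (10, 5) are returned with a warning. A final best-of-100 run
at the chosen weights, ranked by r_g·r_s, produces the embedding.

The fine-grid range is automated as the bounding box of rough cells
within 80% of the best rough score, expanded by one rough grid step
(the canonical grids above ship as presets and everything is
overridable). Every repeat's seed is a documented arithmetic function
of (base seed, stage, cell index, repeat index) — no hashing — so
reports are exactly reproducible and cells are independent. Repeat
counts default to 100/10/20/100 (threshold/rough/fine/final); tests and
the acceptance script scale them down (3 repeats, 2×2 and 3×3 grids) to
keep runtimes in seconds.

## Synthetic data

The generator emulates what the embedder targets: spatially compact
clusters with cluster-specific expression. Gene baseline log-means are
drawn once from N(1, 0.5); each cluster's marker genes are shifted up
by `marker_effect` log units; per-cell log-normal noise (sd 0.3) is
added; counts are Poisson draws of the exponentiated rates, giving
realistic zero inflation without extra parameters. Cluster centers are
placed on a square lattice, parallel bands, or a ring (spacing 10
units), with Gaussian positional jitter (sd 1).

Defaults: 4 clusters × 50 cells × 100 genes, 10 markers/cluster,
marker effect 2.0 — strong, well-separated clusters, small enough for
seconds-scale runs. The layered variant instead defaults to 7 bands ×
30 cells with subtle markers (1.0 log unit, 8 genes/band) plus one
gradient gene whose log-mean rises 0.5 per band — a cortex-like section
where adjacent layers differ subtly in expression and the global layer
order is carried by the spatial arrangement. That is precisely the
regime where a spatially informed embedding should outperform t-SNE at
ordering the bands, and the trajectory tests confirm it does; with
strong markers or a dominant gradient gene both methods saturate and
the comparison is uninformative. Band jitter is centered per band so
band centroids are exactly collinear.

What the generator does **not** emulate: platform artifacts (Visium
spot mixing, segmentation errors), batch effects, gene–gene correlation
beyond the shared cluster signal, or library-size variation between
cell types. Passing tests therefore demonstrate the algorithm's
behavior under its own model assumptions, not performance on any real
tissue.

## Problem sizes

The test suite and acceptance script run the full pipeline at 200-cell
(4×50) and 210-cell (7×30) fixture sizes with the default 1000-iteration
schedule, 10 seeds per stochastic comparison, and reduced screening
grids (2×2 rough, 3×3 fine, 3 repeats/cell) — sizes chosen so the whole
suite completes in about a minute while keeping perplexity 50
meaningful (N > 3·perplexity).

## Known limitations

* O(N²) dense matrices: ~8 GB at N ≈ 30k; the method is not intended
  for atlas-scale data.
* The spatial term assumes a single coherent section; stitched or
  multi-sample coordinates would need alignment first.
* Pearson-based r_g/r_s measure linear distance agreement only, and
  r_g is computed on the same processed matrix the embedding consumed
  (post-PCA where PCA applies) — distances in raw gene space are not
  consulted.
* Trustworthiness neighbor ranks break ties by index; on continuous
  data ties have measure zero, but integer-valued inputs could differ
  between backends at machine precision.
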