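# Methods

## Model and objective

The data are an n × p real matrix X (molecular signals × spatial pixels)
with pixel coordinates s_j ∈ R². The model is a hard cocluster structure
with spatially correlated column noise:

    X ~ N_{n,p}( F μ Gᵀ , I_n , Σ ),      Σ = τ · K(S; φ),
    K[j, j′] = exp( −‖s_j − s_j′‖ / φ ),

where F ∈ {0,1}^{n×K} and G ∈ {0,1}^{p×R} are cluster indicators, μ ∈
R^{K×R} the centroid matrix (real-valued: the "semi" relaxation, so
log-transformed or centred data are admissible), τ > 0 the marginal noise
variance and φ > 0 the kernel scale, in the raw units of the coordinate
file (no internal rescaling — φ is only interpretable in those units).
Writing Σ = LLᵀ (lower Cholesky), minimising

    ℓ(F, μ, G) = ‖(X − FμGᵀ)(L⁻¹)ᵀ‖²_F = tr[(X − FμGᵀ) Σ⁻¹ (X − FμGᵀ)ᵀ]

in F, μ, G is maximum-likelihood estimation under the matrix-normal model.
ℓ is monotonically decreasing in τ, so the variance is estimated from the
penalized objective ℓ + n·log|Σ| (the Σ part of the matrix-normal
normalising constant), whose unique stationary point in τ,

    τ̂ = tr[(X − FμGᵀ) K(S;φ)⁻¹ (X − FμGᵀ)ᵀ] / (np),

is a conditional minimum. φ admits no closed-form update and its profile
objective can be multimodal; it is held fixed per fit and compared across a
user grid.

All Σ⁻¹-products are two triangular solves against L; no inverse is ever
formed. The Cholesky factor is computed once per (coordinates, φ) pair on
the correlation matrix only, so the per-iteration τ update is a rescaling
(chol(τK) = √τ·chol(K)). A numerically singular correlation (duplicated
pixels, φ far below the pixel spacing) is retried once with 1e−8 diagonal
jitter, then raises.

## Update steps

One outer iteration applies, in order:

1. **Centroids** — μ ← (FᵀF)⁻¹ FᵀXΣ⁻¹G (GᵀΣ⁻¹G)⁻¹, the exact minimiser
   given the labels (block means under Σ = I). Empty clusters make the
   Gram matrices singular: the update is computed over nonempty clusters
   only and empty clusters keep their previous centroids, so emptying —
   the mechanism by which superfluous clusters are discarded — cannot
   crash a fit. An optional nonnegativity clamp [μ]₊ is available for
   strictly nonnegative data (off by default; it forfeits the exact-
   minimiser property).
2. **Rows** — with X̃ = X(L⁻¹)ᵀ and G̃ = L⁻¹G, each row independently joins
   argmin_k ‖X̃_{i·} − μ_{k·}G̃ᵀ‖² (classification step), or, in the
   stochastic variant, draws its label with probabilities ∝ exp(−criterion)
   after subtracting the per-row minimum (the raw weights underflow for any
   realistic loss; the shift cancels in the normalisation).
3. **Columns** — one of:
   * *exact*: a sequential sweep j = 1..p, each column taking the label
     minimising the full loss among its R relabellings. The rank-one
     structure of a single-column change lets each candidate be scored
     from one whitening of the leave-column-out residual plus O(nR) work,
     instead of R full re-whitenings; the current label is always a
     candidate, so the sweep never increases the loss.
   * *approximate*: each column independently joins the nearest composite
     centroid Fμ_{·r} in plain Euclidean norm. This ignores Σ, is
     embarrassingly parallel, and does not guarantee descent of the full
     loss — the driver therefore tracks the best state visited.
   * *stochastic*: the sequential sweep with labels drawn from
     Multinomial(1, softmax(−full loss)), a stochastic-EM move intended to
     escape local minima.
4. **Variance** — the closed-form τ̂ above; values below 1e−12 (zero
   residual, i.e. a degenerate noiseless fit) are clamped with a warning so
   Σ stays factorisable.

With the exact column step, every one of these steps is non-increasing in
the penalized loss at fixed φ (steps 1–3 decrease ℓ at fixed τ; step 4
minimises the penalized form in τ), which the test suite asserts step-by-
step on random instances. Ties in every argmin go to the smallest cluster
index, making all variants bit-reproducible under a seed.

## Fitting protocol

Each run iterates steps 1–4 from a random start until the relative
decrement of the running-minimum penalized loss falls below `rel_tol`
(default 0.1%), optionally until the labels are unchanged for `patience`
consecutive iterations, with a hard cap `max_iter` (default 100). Fits are
restarted `n_restarts` times (default 50) with sub-seed `seed + r`, and the
restart with the lowest penalized loss is returned together with all
restart losses and τ estimates for stability diagnostics.

**Which loss is compared.** The raw whitened loss evaluated after a τ
update equals n·p identically (τ̂ is exactly the mean whitened squared
residual), so it cannot rank restarts or φ values. Selection therefore uses
the penalized loss — the matrix-normal profile objective — which at fixed φ
orders solutions exactly as τ̂ does, and across φ additionally accounts for
log|K(φ)|. The φ-grid table reports both losses, τ̂, iteration counts and
nonempty cluster counts per φ.

**Initialisation.** Restarts draw K seed rows and R seed columns by
D²-weighted sampling (k-means++ style: first seed uniform, later seeds with
probability proportional to squared distance from the nearest chosen seed)
and assign every row/column to its nearest seed; centroids and τ then
follow from steps 1 and 4. Two simpler schemes were rejected on measured
grounds. Uniformly random labels produce Step-1 centroids that are block
means of near-uniform subsamples — all close to the grand mean — so the
first assignment passes are driven by noise, restarts lose their diversity
(they funnel into one basin), and well-separated clusters can merge
irrecoverably: on clearly separated synthetic data the best of 50 such
restarts can miss the generating solution entirely. Plain Forgy seeding
(uniform seed draws) fixes the scale problem but covers all clusters with
small probability (e.g. ≈ 0.15 for three clusters of sizes 23/8/9), capping
the fraction of successful restarts at that coverage rate. D² seeding
covers separated groups with high probability: on well-separated instances
≥ 90% of restarts reach the same minimum, and the noiseless block-constant
recovery test passes for both the exact and approximate variants.

A known consequence: because every seeded cluster starts with a nonempty
nearest-seed catchment, fits initialised with more clusters than the data
support tend to keep the surplus clusters populated whenever reassigning
their members would increase the loss. Under the matrix-normal objective a
solution that splits a true cluster is never worse and is typically
slightly better (it absorbs noise; measured ≈ 0.1–0.3% in τ̂ on the
standard simulation conditions), so minimum-loss selection across restarts
retains such refinements whenever any restart finds them. Selecting the
number of column clusters purely by "start large and let clusters empty"
is therefore unreliable under this implementation; inspecting the loss/τ̂
trajectory across a grid of R (the gains beyond the true R are an order of
magnitude smaller than those up to it) is the recommended practice.

## Synthetic data generator

The generator reproduces the standard study conditions: n = 90 rows
partitioned into K = 3 clusters and p = 100 (or 1000) columns into R = 4
clusters, sizes uniform over compositions with minimum cluster size 5;
pixels laid out on a near-square integer grid with each column cluster
occupying a contiguous vertical band (so within-cluster kernel correlation
strictly exceeds between-cluster correlation); centroids drawn
μ_{kr} ~ N(m_{kr}, 1) around a preset grid m; noise matrix-normal with row
covariance I and column covariance τ·K(S;φ) at τ = 3, φ = 10 (grid units),
or Σ = I for the no-spatial-correlation scenario. The preset mean grid is
m_{kr} = 4·((k+r) mod max(K,R)), centred — every pair of row/column
clusters differs in at least one block by 4, i.e. more than two noise
standard deviations (√3 ≈ 1.73), keeping recovery nontrivial but
well-posed; it is user-overridable. A zero-noise hook and a zero-spread
centroid hook exist for exact-recovery tests.

What the generator does *not* emulate: MALDI-MSI peak-intensity
distributions, nonnegativity, missingness, instrument noise, or irregular
tissue boundaries. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the model's own assumptions,
not robustness to real-instrument artefacts; real data should be
log-transformed (`log(Y+1)`) and results inspected across a φ grid.

## Agreement metric

The classification error rate (CER) between two partitions is the fraction
of unordered unit pairs whose co-membership differs; it is relabelling-
invariant, symmetric, zero iff the partitions coincide up to renaming, and
equals 1 − Rand index, which is how it is computed (the O(m²) enumeration
is kept as the test oracle). Concordance = 1 − CER.

## Numerical choices and problem sizes

* Tolerances: loss-form identity holds to 1e−8 relative; whitening round
  trips to 1e−10; monotonicity is asserted with a 1e−7 relative slack for
  accumulated round-off; τ̂ matches 1-D numeric minimisation to 4
  significant digits.
* Tie-breaks: smallest index everywhere; Step-3 sweeps ascend in column
  index.
* Degenerate inputs: duplicate pixels (jitter retry), empty clusters
  (centroids frozen), zero residual (τ clamp at 1e−12), K > n or R > p
  (warn).
* The test suite exercises the full pipeline at reduced problem sizes
  (n ≤ 90, p ≤ 100, 10–50 restarts; exact-step oracles at n, p ≤ 8), and
  the reproduction script runs the complete 30-dataset × 50-restart
  protocol — a deliberate choice keeping the whole suite in seconds and
  the script under a minute on a single CPU.

## Known limitations

Only the exponential kernel is implemented (no anisotropy, no sparse or
nearest-neighbour approximations), so kernel construction and
factorisation are O(p²)–O(p³): practical to a few thousand pixels. φ is
never optimised numerically. The objective is nonconvex; no global
optimality is claimed — restart diagnostics (`restart_losses`,
`restart_taus`) are exposed precisely so users can judge convergence
stability, as recommended for the stochastic variants whose loss is not
monotone.
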