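# Methods

## Model

`omiclust` clusters n samples observed in V omics views by jointly
learning, for each view, a sparse self-representation Z⁽ᵛ⁾ (X⁽ᵛ⁾ ≈
X⁽ᵛ⁾Z⁽ᵛ⁾ + E⁽ᵛ⁾, diag Z = 0, ℓ₁ on both Z and the error E), a shared
nonnegative spectral embedding F ∈ ℝ^{n×c}, and a discrete indicator G
tied to F by an orthonormal rotation R. Cross-view exclusivity
(ℓ₁ of the Hadamard product Z⁽ᵛ⁾ ⊙ Z⁽ʷ⁾) keeps the views' affinity
supports complementary; consistency enters through Tr(FᵀLF), where L sums
the view Laplacians (affinity S⁽ᵛ⁾ = (|Z⁽ᵛ⁾| + |Z⁽ᵛ⁾ᵀ|)/2, which
guarantees a PSD Laplacian) and the co-membership Laplacians of any
supplied base partitions, each base weighted by β_p = 1/(2 Tr(FᵀL_pF))
(trace floored at 1e-8). The β rule is parameter-free self-weighting: a
base partition that agrees with the current embedding has a small trace
and hence a large weight.

Assumptions worth stating plainly: samples must be shared and aligned
across views; cluster structure is assumed expressible as (approximate)
union-of-subspaces after preprocessing; the number of clusters c is an
input, not an output; base partitions are treated as fixed evidence — a
bad base is down-weighted but never corrected.

## Optimization

Outer iteration t (1-based) uses the weight schedule ξ₁ = ν^{1−t},
ξ₂ = α, ξ₃ = β·ν^{t−1} with ν = 1.2 — sparsity pressure decays while the
graph-consistency term grows. Each outer iteration:

1. β_p from the current F (skipped without bases; δ is forced to 0).
2. Per view, ADMM on (Z, E) with auxiliary copy C, duals Q₁, Q₂ and
   penalty μ: shrink-update of Z with elementwise threshold
   (ξ₁ + ξ₂ Σ_{w≠v}|Z⁽ʷ⁾| + ξ₃ D)/μ where D_ij = ½‖f_i − f_j‖², shrink
   of E at 1/μ, a cached-Cholesky solve of (XᵀX + I)C = rhs, dual ascent,
   μ ← min(ρμ, 1e8), ρ = 1.2; stop at ‖X − XC − E‖_∞ < 2e-4 or 30
   iterations. Views are swept Gauss–Seidel style, each seeing the
   others' latest Z. Z, E, C and the duals warm-start across outer
   iterations; μ restarts at 0.1 each call, otherwise the 1/μ shrinkage
   would be dead after the first outer iteration.
3. Spectral rotation on L = ξ₃(ΣL⁽ᵛ⁾ + δ Σβ_pL_p): multiplicative update
   of F built from the positive/negative split L = L⁺ − L⁻ (denominators
   floored at 1e-12), nearest-row assignment G_ik = 1 for
   k = argmin ‖f_i − r_k‖² (ties to the smallest k), and the orthogonal
   Procrustes solve R = UVᵀ from the SVD of GᵀF; stop when
   ‖R_{t+1} − R_t‖₂ < 2e-4 or after 3000 iterations. F and R warm-start
   across outer iterations; G restarts from the assignment step.

The outer loop stops when the binary co-clustering matrix GGᵀ is
unchanged between consecutive iterations (threshold 0.05 on the ∞-norm of
the difference, which for binary matrices means identical partitions) or
after T = 10 iterations. On the synthetic study conditions it converges
in 2–4 outer iterations. The full objective is recorded per outer
iteration; it is empirically non-increasing on essentially all default
runs, though the alternating scheme with a drifting schedule carries no
monotonicity guarantee.

Two numerical guards matter in practice, both objective-neutral:

- **F floor.** Zero is an absorbing state of the multiplicative F update;
  once an indicator column deflates to zero its cluster can never regrow,
  and the partition degenerates. Iterates are floored at 1e-8 inside the
  rotation loop (the bare update operator is untouched).
- **Empty-cluster rotation rows.** If G has an empty cluster, its row of
  GᵀF is zero and the corresponding row of R is arbitrary in the
  Procrustes optimum. Among the equally optimal solutions we point such
  rows at the currently worst-fit samples (re-orthonormalized against the
  determined rows), so an emptied cluster can recapture members at the
  next assignment instead of staying dead. Without these two guards a few
  percent of replicate runs collapse to fewer than c populated clusters.

## Preprocessing

Views are z-scored per feature (zero-variance features dropped with a
warning), reduced to k principal components per view, and each sample
column is scaled to unit norm. Defaults: k = 10. The rationale: after
z-scoring, cluster-informative and noise features have equal variance, so
retaining many components buries the (low-dimensional) cluster signal
under retained noise directions and the self-representation graph loses
its block structure; k ≈ 10 keeps the mean-separation subspace plus
little else. Unit-norming sample columns turns mean-shifted clusters into
directional clusters — approximate rank-1 subspaces — which is the
geometry the sparse self-representation model expects; this is the
standard preprocessing in sparse-subspace clustering. PCA signs are fixed
by making each component's largest-magnitude loading positive, so results
are reproducible across linear-algebra backends.

## Default hyperparameters

| parameter | default | role |
|---|---|---|
| α (ξ₂) | 0.1 | cross-view exclusivity weight |
| β (scale of ξ₃) | 3 | graph-consistency weight, grows as 3·1.2^{t−1} |
| δ | 10 | base-ensemble weight relative to view Laplacians |
| η | 1 | rotation coupling ‖F − GR‖² |
| σ | 100 | soft orthogonality penalty on FᵀF = I |
| ν, ρ | 1.2 | schedule and ADMM penalty growth |
| ϵ | 2e-4 | inner stopping thresholds |
| T / T₁ / T₂ | 10 / 30 / 3000 | outer / ADMM / rotation iteration caps |
| μ₀ / μ_max | 0.1 / 1e8 | initial / capped ADMM penalty |

η, σ, δ and the α/β pair are the parameters that matter; all were chosen
once from coarse grids on the synthetic study conditions and then frozen.
The balance to understand when re-tuning: the graph term (scaled by ξ₃, δ
and the self-reinforcing β_p) must dominate the rotation coupling η early
enough that F organizes around graph structure rather than locking onto
the random initial assignment, while σ must be large enough to keep F's
columns near-orthonormal as the ensemble weights grow. Base-free runs
(δ = 0 or no bases) lean entirely on the view Laplacians, whose degrees
are small; they typically need a much larger β (≈ 30–100) — this is the
single-omic operating mode. F is initialized entrywise uniform(0,1) with
unit-norm columns, R as an orthonormalized Gaussian matrix, G as zeros;
all randomness flows from the single seed in the configuration.

## Synthetic generator

The generator emulates a three-view multi-omics cohort with a shared
planted partition: n = 200 samples, c = 4 balanced clusters, views named
methylation / miRNA / mRNA with d_v = 100 features each, of which 30 are
cluster-informative. Each informative feature assigns every cluster a
random level in {0, …, c−1} and draws Normal(effect · quality · level,
1); the other 70 features are Normal(0, 1) noise. The miRNA view gets a
quality multiplier of 1.2 (it is the "best" layer), the others 1.0.
"Extra noise" replaces a uniformly chosen fraction (0%, 5% or 15%) of all
entries with fresh standard-normal draws — corruption, not additive
noise. The default effect size is 0.5, chosen once so that the
similarity-based baselines sit near (not past) their recovery threshold —
SNF attains mean NMI ≈ 0.95 at 0% extra noise and degrades with
corruption — because a generator in the saturated regime (every method at
NMI 1 at every noise level) cannot exhibit the noise-robustness contrasts
the study is about. What the generator does *not* emulate: count
distributions and library-size effects of sequencing data, beta-value
compression of methylation arrays, batch effects, missing values, and
unbalanced subtype sizes. Passing the simulation study therefore shows
correct mechanics and the expected method ordering under Gaussian
mean-shift signal, not performance on raw TCGA-like data.

Replicate seeds are spawned from a single master seed via
`numpy.random.SeedSequence`, so every table is bit-reproducible from
(conditions, methods, master seed).

## Benchmark protocol

`run_noise_benchmark` evaluates, per replicate: the one-step fit with
three base clusterings (built-in SNF on all views plus spectral
clustering of the first two views), the no-ensemble variant (δ = 0), the
two-step variant (k-means with 10 seeded restarts on the final F), SNF
alone, spectral clustering per view, and k-means on the z-scored
concatenation. `scripts/acceptance.py` runs 50 replicates per noise
condition (~2 minutes total); the test suite uses a 20-replicate smoke
tier for the same checks and 12 replicates for the directional
ablation/two-step comparisons. Method-ordering assertions use a
one-sided paired t-test across replicates, since the one-step fit and its
strongest base frequently tie exactly and a strict sample inequality
would reject true ties on single-replicate noise.

## Known limitations

- The ensemble term dominates once β_p grows, so with one clearly best
  base the one-step result frequently equals that base's partition; the
  gain over the best base appears mainly when bases err independently.
- β_p is unbounded above (floor 1e-8 on the trace); by the final outer
  iterations the best-agreeing base can dominate L entirely. This is
  inherent to the 1/(2Tr) weighting.
- No automatic selection of c, no missing-value handling, no
  omics-specific normalization (RNA-seq library size, methylation
  M-values); inputs are assumed numeric, complete and aligned.
- The alternating scheme has no convergence proof; the objective trace is
  monitored instead.
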