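# omiclust

One-step multi-view subspace clustering for multi-omics subtyping.

Molecular subtypes of a cancer (or any sample stratification problem) are
best identified by integrating several omics layers — mRNA expression,
miRNA expression, DNA methylation — measured on the same patients. Most
integration methods are *two-step*: they first learn a fused similarity or
a continuous spectral embedding, then run k-means on it, losing
information at the hand-off and producing unstable clusters. `omiclust`
implements a *one-step* alternative: the discrete cluster indicator is
learned inside the joint optimization, together with per-view sparse
self-representations and a self-weighted ensemble over base clusterings
supplied by other methods (a compact SNF, spectral clustering and k-means
providers are built in).

## The model

Given views X⁽ᵛ⁾ ∈ ℝ^{d_v×n} over the same n samples and base partitions
Y_p ∈ {0,1}^{n×c_p}, the joint objective is

```
min  Σ_v ( ‖E⁽ᵛ⁾‖₁ + ξ₁‖Z⁽ᵛ⁾‖₁ + ξ₂ Σ_{w≠v} ‖Z⁽ᵛ⁾ ⊙ Z⁽ʷ⁾‖₁ )
     + Tr(FᵀLF) + η‖F − GR‖²_F
s.t. X⁽ᵛ⁾ = X⁽ᵛ⁾Z⁽ᵛ⁾ + E⁽ᵛ⁾,  diag(Z⁽ᵛ⁾) = 0,
     FᵀF = I, F ≥ 0,  RᵀR = I,  G a one-1-per-row indicator,
```

where L = ξ₃(Σ_v L⁽ᵛ⁾ + δ Σ_p β_p L_p) combines the Laplacians of the
symmetrized self-representation affinities S⁽ᵛ⁾ = (|Z⁽ᵛ⁾|+|Z⁽ᵛ⁾ᵀ|)/2 and
of the base co-membership graphs S_p = Y_pY_pᵀ. The pieces:

- **Sparse self-representation** (ℓ₁ on Z and on the error E) expresses
  each sample as a sparse combination of the others; Z⁽ᵛ⁾ doubles as a
  sample-affinity graph for view v.
- **Relaxed exclusivity** ‖Z⁽ᵛ⁾ ⊙ Z⁽ʷ⁾‖₁ pushes different views toward
  disjoint supports, so each view contributes *specific* structure rather
  than redundantly encoding the consensus.
- **Self-weighted ensemble**: each base partition enters with weight
  β_p = 1 / (2·Tr(FᵀL_pF)) — partitions that agree with the current
  embedding F get large weight automatically, with no extra parameter.
- **Spectral rotation**: G and an orthonormal rotation R minimize
  ‖F − GR‖², extracting the hard partition inside the optimization
  instead of a post-hoc k-means.

Optimization alternates (i) per-view ADMM for (Z⁽ᵛ⁾, E⁽ᵛ⁾) with shrinkage
thresholds coupled to the other views and to the embedding distances,
(ii) the β weights, and (iii) a multiplicative update for F ≥ 0 with
nearest-row assignment for G and an orthogonal-Procrustes solve for R.
The outer loop stops when the co-clustering matrix GGᵀ stops changing
(usually 2–4 iterations) with the schedule ξ₁ = ν^{1−t}, ξ₂ = α,
ξ₃ = β·ν^{t−1}, ν = 1.2.

## Worked example

Simulate a three-view dataset (200 samples, 4 planted subtypes, 5% of all
entries replaced by noise), build base clusterings, then fit:

```
$ omiclust simulate --out-dir demo --noise 0.05 --seed 7
wrote 3 views + truth to demo

$ omiclust base-cluster --view demo/methylation.tsv --view demo/miRNA.tsv \
    --view demo/mRNA.tsv --method snf --clusters 4 --out demo/snf.tsv
wrote 4-cluster labels to demo/snf.tsv

$ omiclust base-cluster --view demo/methylation.tsv --method spectral \
    --clusters 4 --out demo/sc_meth.tsv
$ omiclust base-cluster --view demo/miRNA.tsv --method spectral \
    --clusters 4 --out demo/sc_mirna.tsv

$ omiclust fit --view demo/methylation.tsv --view demo/miRNA.tsv \
    --view demo/mRNA.tsv --clusters 4 --pca 10 \
    --base demo/snf.tsv --base demo/sc_meth.tsv --base demo/sc_mirna.tsv \
    --seed 1 --out demo/labels.tsv --truth demo/truth.tsv
{"n_iter": 3, "beta": [0.2592884833625542, 0.018269876310213245,
 0.032194820964830693], "n_clusters_populated": 4,
 "nmi": 0.9232038730172536}
```

The run converged in 3 outer iterations. The β vector shows the
self-weighting at work: the SNF base (NMI 0.93 against truth by itself)
received ~8–14× the weight of the two weaker single-view spectral bases.
The final partition agrees with the planted subtypes at NMI 0.92 despite
the injected noise. `omiclust eval` produces the full agreement report:

```
$ omiclust eval --pred demo/labels.tsv --truth demo/truth.tsv
{
  "nmi": 0.9232038730172537,
  "ari": 0.9335997254530195,
  "contingency": [[48, 0, 0, 0], [1, 50, 3, 0], [0, 0, 47, 0], [1, 0, 0, 50]]
}
```

The same pipeline is available programmatically:

```python
from omiclust import (Config, SyntheticSpec, generate, prepare_views,
                      snf_fuse, spectral_cluster, fit, nmi)

ds, truth = generate(SyntheticSpec(extra_noise_frac=0.05, seed=7))
bases = [snf_fuse(ds, c=4, seed=7),
         spectral_cluster(ds.views[0], c=4, seed=8),
         spectral_cluster(ds.views[1], c=4, seed=9)]
res = fit(prepare_views(ds, 10, seed=7), bases, Config(c=4, seed=1))
print(nmi(res.labels, truth), res.n_iter)
```

Other subcommands: `benchmark` (replicated noise-robustness study,
mean ± SD NMI per method and noise level), `sweep` (hyperparameter grid
scored by NMI against truth, or by cross-seed stability when no truth is
available).

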