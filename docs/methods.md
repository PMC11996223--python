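# Methods

`sgtcca` infers phenotype-specific multi-omics networks by maximizing a
weighted sum of higher- and lower-order canonical correlations across K
omics views and one quantitative phenotype, with sparsity obtained by
covariance-density-biased feature subsampling rather than a penalty term.
This note records the model, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Higher-order covariance

All views are standardized column-wise with population (1/N) scaling, so
the self-covariance of a feature is exactly 1 and the pairwise covariance
tensor is an absolute Pearson correlation matrix.  For k standardized
N-vectors the higher-order covariance is

- even k:  ρ = | (1/N) Σ_i z_1i … z_ki |
- odd k:   ρ = (1/(N·k)) Σ_j | Σ_i z_1i … |z_ji| … z_ki |

The odd branch replaces one vector at a time by its absolute value and
averages, which prevents the exact cancellation of the naive signed product
statistic for an odd number of views (for a symmetric z used in all three
slots, Σ z³ = 0 while the odd branch is strictly positive).  The order-k
covariance tensor over feature blocks evaluates this entrywise; every
tensor entry is nonnegative.

## GTCCA: joint rank-1 factorization

Given a set of correlation structures — by default every subset of views
that contains the phenotype (seven structures for three omics plus one
phenotype) — the generalized tensor CCA objective is

    max_{‖h_j‖=1}  Σ_m a_m ρ_m²,   ρ_m = C_m ×₁ h_{m1}ᵀ ×₂ … ×ₖ h_{mk}ᵀ,

which is equivalent to jointly fitting rank-1 approximations
ρ_m·h_{m1}∘…∘h_{mk} to all structure tensors by minimizing the weighted sum
of squared Frobenius residuals.  The solver is nonlinear conjugate gradient
with the Dai–Yuan β and restart to steepest descent when the direction
loses descent; an Armijo backtracking line search; weights renormalized to
unit norm after every accepted step with the norms absorbed into the ρ's,
which are always at their closed-form optimum (the full contraction).
Gradients are analytic (matricized-residual × Khatri–Rao form, implemented
as shared partial contractions) and follow the convention of differentiating
half the residual, so for a single pairwise structure ∂/∂ρ = ρ − h₁ᵀCh₂.
Convergence: gradient norm ≤ 1e-6 or relative objective change ≤ 1e-9,
max 500 iterations.  Output signs are canonicalized (largest-magnitude
entry of each h_j positive).  Initialization is a warm start from the
leading singular vectors of the pairwise structure matrices (for a d×1
pairwise tensor, the tensor itself), falling back to seeded random unit
vectors; pure random initialization is available (`init="random"`).

Two numerical choices matter at realistic dimensions (d ≈ 100 per
subsampled view, N ≈ 100):

- **Tensor centering** (`center_tensors=True`).  The rectified tensors have
  a strictly positive sampling-noise floor E|N(0,σ)| ≈ 0.8σ in every entry.
  That floor is a near-uniform rank-1 component whose contraction grows
  like √(d₁…d_k); left in place it dominates the factorization (measured
  ρ ≈ 119 against ≈ 2 for a pairwise structure) and flattens the canonical
  weights toward uniform.  Each structure tensor is therefore centered (its
  mean entry subtracted) before the fit.
- **Structure normalization** (`scale_structures=True`).  Each structure's
  scaling is multiplied by 1/‖C_m‖²_F, so the objective sums normalized
  squared correlations (ρ_m/‖C_m‖_F)² ≤ 1.  Without this, raw ρ² grows with
  tensor size and the highest-order structure — whose empirical moment
  tensor is also the noisiest when N ≪ d, being a sum of N sample-wise
  rank-1 terms that outlier samples can dominate — drowns the reliable
  lower-order structures.  This uses the scaling freedom a_{m,j} that the
  model itself provides; user-specified scalings multiply on top, and both
  behaviours can be disabled.

A grid-search utility (`equivalence_check`) verifies on small instances
(d_j ≤ 3) that the maximization and factorization forms pick the same
weights; it is a test utility, not a pipeline stage.

## Sparsity by biased subsampling

Sparsity comes from solving GTCCA on s = 10 feature subsets per view —
8% of features shared across all subsamples (the common set) plus 2%
distinct per subsample — and scattering each solution into canonical weight
matrices H_j ∈ R^{d_j×s} with exact zeros off-support.  Subsets are drawn
without replacement with probability proportional to the square of each
feature's *covariance density* (squaring in the spirit of leverage-score
sampling; exponent configurable via `bias_power`).

The density itself is estimated without ever building the full tensors:
features are partitioned into stratified sweeps (chunks of a fresh random
permutation, 10% of each view per chunk, 50 chunks by default, so every
feature is observed ~5 times), the structure tensors are built on each
chunk, and each feature is credited with the sum of tensor entries
involving it.  Two details:

- contributions are z-scored per structure before being combined, because
  raw entry sums live on incomparable scales (an order-k structure
  contributes ~∏ d_m entries per feature, a pairwise one a single entry)
  and the rectified noise floor of the highest-order tensor otherwise
  drowns the discriminative lower-order terms;
- the combined average is clipped at zero and given a small floor (5% of
  the view maximum), so no feature is permanently frozen out of selection.

Stratified sweeps matter: with independent uniform draws at a 10% fraction
and 20 iterations, ~12% of features are never observed, and an unobserved
signal feature can never be selected downstream.

The phenotype (a d = 1 view) is always fully included.  Per-subsample
solves are seeded independently from the scheme seed (spawned seed
sequences), so the cascade is deterministic and order-insensitive.

## Network construction, pruning, and filtering

The global adjacency is the average over subsamples of |w wᵀ| for the
concatenated per-subsample canonical weights, restricted to features with a
nonzero weight in at least one subsample; the phenotype is not a node.
Pruning ranks nodes by weighted PageRank (damping 0.85, power iteration to
1e-14, ties broken by node id) and scans candidate prefix sizes from 30 to
min(300, n) in steps of 10.  Each candidate is scored by the best absolute
Pearson correlation between the phenotype and the first 3 topology-aware
summary components — the PCA scores of the node data concatenated with the
node data times the graph Laplacian of the candidate's adjacency (an
edgeless candidate reduces exactly to ordinary PCA).  The smallest
candidate within 5% of the best correlation is selected.  Finally, edges
whose endpoints have |Pearson correlation| < 0.2 are removed and surviving
edges annotated with the correlation sign.

## Synthetic benchmark

The simulator draws 11 independent latent factors (mean 0, variance 1) and
builds three 1000-feature views in fixed 20- or 60-feature blocks: each
feature is its block's factor plus N(0, 0.5²) noise, noise-only blocks are
standard normal, and the phenotype is the sum of a case-dependent factor
subset plus N(0, 1) noise (stronger noise on the phenotype than on the
omics, matching the weak omics-phenotype / strong omics-omics regime).
Factors 8–11 drive purely inter-omics blocks and are never signal; they
exist to interfere with selection.  Cases: (1) phenotype = factors 1–7, so
4-way, 3-way and pairwise phenotype structures are all signal (80 signal
features per view); (2) phenotype = factor 1 only (20 per view); (3)
phenotype = factors 2–7 (60 per view, no 4-way signal).  Settings: `normal`
(Gaussian factors), `skewed` (factors through the Fleishman cubic with
skewness 3.5 and excess kurtosis 22, solved from the moment equations),
and `noisy` (extra N(0, 1) noise on every omics feature).  The noise
standard deviations (omics 0.5, phenotype 1.0, extra 1.1) and the Fleishman
targets are package defaults, config-exposed.

Evaluation is node-level: each feature's prediction is its maximum edge
weight in the global adjacency (features absent from the network score 0),
min-max scaled, compared with the binary signal labels by ROC AUC (rank
based with midrank ties).  The replication harness runs simulate → pipeline
→ AUC over 25 seeded replications and reports the median and interquartile
range; `scripts/acceptance.py` does exactly this for the seven benchmark
cells (cases 1–3 at n = 100, case 1 at n = 200, three settings).  The
harness evaluates the global adjacency (pruning does not change it), so the
pruning stage is switched off there for speed; `evaluate` supports either
adjacency.

What this does and does not show: the generator produces block-structured,
homoscedastic, factor-driven data with independent Gaussian noise and
equal loadings — no count-data marginals, batch effects, missingness, or
correlated noise.  Passing the benchmark demonstrates that the estimator
recovers planted higher- and lower-order phenotype-specific structure at
realistic n/d ratios, not that it is calibrated for any particular assay.

## Known limitations

- Tensor memory is O(∏ d_j) per structure; the subsampled dimensions
  (p_c + p_d)·d_j keep this manageable, but very large views need smaller
  fractions.
- The rank-1-per-subsample design extracts one dominant joint axis per
  subsample; several distinct signal axes are represented only through the
  diversity of subsample supports.
- The conjugate-gradient solve is non-convex; different seeds can reach
  different local optima (the pairwise warm start makes this rare in
  practice).
- No consensus penalty couples the per-view weights beyond the shared
  structures: a term of the form λ(h_j − h̄) is dimensionally undefined
  across views with different feature counts (the weight vectors do not
  live in a common space), so the objective is used with λ = 0.
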