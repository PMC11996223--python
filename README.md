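# sgtcca

Phenotype-specific multi-omics network inference by **sparse generalized
tensor canonical correlation analysis** (SGTCCA-Net).

Given K omics matrices (samples × features, shared sample set) and one
quantitative phenotype, the pipeline finds the features that participate in
higher- *and* lower-order correlation structures with the phenotype and
assembles them into a compact, phenotype-relevant network.  Pairwise
canonical correlation methods miss simultaneous associations among three or
more views; plain tensor CCA captures only the single highest-order
structure.  SGTCCA-Net optimizes all of them at once:

    max_{‖h_j‖₂ = 1}   Σ_m  a_m · ρ_m² ,
    ρ_m = C_{S_m} ×₁ h_{m1}ᵀ ×₂ … ×ₖ h_{mk}ᵀ ,

where each S_m is a subset of views containing the phenotype, C_{S_m} is
the nonnegative higher-order covariance tensor of those views (an
absolute-mean elementwise product for an even number of views, an averaged
absolute-value variant for odd, which avoids odd-order effect
cancellation), and h_j is the canonical weight vector of view j.  The
problem is solved as an equivalent joint rank-1 tensor factorization by
nonlinear conjugate gradient (Dai–Yuan update with restart).  Sparsity
comes from *covariance-density-biased subsampling*: GTCCA runs on many
small feature subsets drawn with probability increasing in each feature's
total covariance involvement, and the per-subsample solutions are averaged
into a global adjacency |w wᵀ|.  The network is then pruned with weighted
PageRank plus a topology-aware principal-component summary score and
finally edge-filtered by Pearson correlation.

The package also ships the latent-factor simulator and node-level AUC
evaluation used to benchmark the method, so the whole pipeline is testable
end-to-end without any external data.

## Worked example

Simulate three 1000-feature omics views driven by shared latent factors
(case 2: only the 4-way omics₁–omics₂–omics₃–phenotype structure carries
signal), run the pipeline, and score the result:

```python
import numpy as np
from sgtcca import (SimulationDesign, assemble_dataset, run_arrays,
                    feature_scores, auc)

design = SimulationDesign(case=2, setting="normal", n_samples=100, seed=1)
data = assemble_dataset(design)                  # 3 × (100 × 1000) + phenotype

result = run_arrays(data.omics, data.phenotype, seed=1)
print("global network:", result.global_module.n_nodes, "nodes")
print("final subnetwork:", result.final_module.n_nodes, "nodes")

scores = feature_scores(result.global_module, [1000, 1000, 1000])
print("node-level AUC:", round(auc(scores, np.concatenate(data.signal_labels)), 3))
```

Output:

```
global network: 696 nodes
final subnetwork: 30 nodes
node-level AUC: 1.0
```

The global network contains every feature selected in at least one of the
10 subsamples (696 of 3000 here).  The pruned, edge-filtered subnetwork
keeps the 30 nodes whose summary score correlates best with the phenotype —
in this planted design, latent-1 signal features.  The AUC of 1.0 says the
maximum-edge score perfectly separates the 60 planted signal features from
the 2940 noise features.

The same pipeline runs from the shell on delimited files:

```sh
sgtcca simulate --case 2 --n-samples 100 --seed 1 --out sim/
sgtcca run --block sim/omics1.csv --block sim/omics2.csv \
           --block sim/omics3.csv --phenotype sim/phenotype.csv \
           --out run/ --seed 1
sgtcca evaluate --case 2 --n-replications 25 --seed 1
```

`run/` then holds the node table (PageRank, phenotype correlation,
BH-adjusted p-values), a TSV edge list with correlation signs, a GraphML
export, a JSON run summary, and the exact config for reproduction.

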