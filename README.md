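# hyperblock

Mixed-membership stochastic block models for **hypergraphs with node
attributes**: probabilistic community detection that combines group
interactions (hyperedges of any size) with categorical node covariates, for
researchers studying higher-order systems — social contact networks,
gene–disease associations, co-sponsorship data — where nodes come with
metadata such as a class, a role, or a department.

## The model

A weighted hypergraph `H = (V, E, A)` and a binary attribute matrix
`X ∈ {0,1}^{N×Z}` are modeled jointly through a shared membership matrix
`u ∈ [0,1]^{N×K}`:

* hyperedge weights are Poisson,
  `A_e ~ Pois(λ_e / κ_e)` with `λ_e = Σ_{i<j∈e} u_i^T w u_j`, where `w` is a
  symmetric K×K affinity matrix and `κ_e` a size normalization; summed over
  all candidate edges this gives the tractable log-likelihood
  `L_A = −C Σ_{i<j∈V} u_i^T w u_j + Σ_{e∈E} A_e log λ_e`;
* attributes are Bernoulli, `x_iz ~ Bern(π_iz)` with
  `π_iz = Σ_k u_ik β_kz`, where the loadings `β` link communities to
  attribute levels.

The fitted objective `L = (1−γ) L_A + γ L_X` balances the two sources with
a hyperparameter `γ ∈ [0,1]` (0 = structure only, 1 = attributes only),
selected by cross-validation, so uninformative attributes are down-weighted
or discarded automatically. Inference is variational EM with closed-form
multiplicative updates; one iteration is linear in the number of nodes and
hyperedge incidences. See `docs/methods.md` for the updates, numerical
choices and limitations.

## Worked example

```python
import numpy as np
from hyperblock import (HypergraphBlockModel, cosine_membership_similarity,
                        planted_instance)

# planted data: 2 assortative communities, attributes matching 90% of nodes
inst = planted_instance(N=30, K=2, D=3, assortativity=5.0, mixing=0.2,
                        Z=2, match_fraction=0.9, seed=42)
print("hyperedges:", inst.hypergraph.n_edges)

model = HypergraphBlockModel(n_communities=2, gamma=0.5, n_restarts=5,
                             random_state=0)
model.fit(inst.hypergraph, inst.attributes)
print(f"objective: {model.objective_:.3f}  converged: {model.converged_}")
print(f"recovery (cosine to truth): "
      f"{cosine_membership_similarity(model.u_, inst.u_true):.3f}")

baseline = HypergraphBlockModel(n_communities=2, gamma=0.0, n_restarts=5,
                                random_state=0).fit(inst.hypergraph)
print(f"structure-only recovery:   "
      f"{cosine_membership_similarity(baseline.u_, inst.u_true):.3f}")
print(np.round(model.w_, 3))
```

Output:

```
hyperedges: 63
objective: -87.174  converged: True
recovery (cosine to truth): 0.937
structure-only recovery:   0.636
[[0.218 0.   ]
 [0.    0.357]]
```

On this sparse instance the structure-only fit recovers the planted
communities imperfectly (cosine 0.64); adding the 90%-matching attribute at
γ = 0.5 lifts recovery to 0.94, and the inferred affinity matrix is
diagonal-dominant, i.e. assortative, as planted. The estimator follows
scikit-learn conventions (`get_params`/`set_params`, fitted attributes
`u_`, `w_`, `beta_`); `hyperblock.em.fit` / `fit_best_of` expose the same
machinery functionally, and `hyperblock.cross_validate` grid-searches
(K, γ) by held-out hyperedge-prediction AUC.

## Command line

```bash
hyperblock generate --n 30 --k 2 --match-fraction 0.9 --seed 1 --out-prefix toy
hyperblock fit --hypergraph toy.hyperedges.txt --attributes toy.attributes.csv \
               --k 2 --gamma 0.5 --seed 0 --out fitdir
hyperblock cv  --hypergraph toy.hyperedges.txt --attributes toy.attributes.csv \
               --k-grid 2,3 --gamma-grid 0.0,0.5,0.9 --out cvrun
hyperblock auc --hypergraph toy.hyperedges.txt --params-dir fitdir --mode soo
hyperblock subsample --hypergraph toy.hyperedges.txt --keep-fraction 0.5 --out sub.txt
```

Hypergraphs are plain-text hyperedge lists (one edge per line, optional
`w=<int>` weight); attributes are CSVs with a node-label column plus
categorical columns. Every command writes a JSON manifest (resolved
configuration, seed, input checksums) for reproducibility.

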