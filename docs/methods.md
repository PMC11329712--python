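# Methods

## Model

`hyperblock` fits a mixed-membership stochastic block model to a weighted
hypergraph `H = (V, E, A)` with optional binary node attributes
`X ∈ {0,1}^{N×Z}` (one-hot expanded categorical covariates). Two observation
models share the membership matrix `u ∈ [0,1]^{N×K}`:

**Structure.** Every candidate hyperedge `e` (any node subset of size 2..D,
with D the maximum observed size) carries an independent Poisson weight

    A_e ~ Pois(λ_e / κ_e),     λ_e = Σ_{i<j∈e} u_i^T w u_j,

with `w` a symmetric nonnegative K×K affinity matrix and the size
normalization `κ_d = d(d−1)/2 · binom(N−2, d−2)`. Summed over all candidate
edges, the expected-rate term collapses to a pairwise node sum scaled by
`C = Σ_{d=2}^{D} binom(N−2, d−2)/κ_d`, which under this κ telescopes to
`2(1 − 1/D)` independent of N (the package computes the sum in log space and
the closed form is kept as a test oracle only). The resulting structural
log-likelihood is

    L_A(u, w) = −C Σ_{i<j∈V} u_i^T w u_j + Σ_{e∈E} A_e log λ_e.

**Attributes.** Each attribute cell is Bernoulli with propensity
`π_iz = Σ_k u_ik β_kz`, where `β ∈ R_{≥0}^{K×Z}` has columns summing to one
over k. The attribute objective is written with the complement term
`Σ_k (1−u_ik) β_kz`; because of the column-simplex constraint this equals
`1 − π_iz` identically, so the objective coincides with the plain Bernoulli
log-likelihood at every feasible point. Both evaluators are exposed (the
complement form drives inference; the Bernoulli form is a diagnostic).

**Combination.** The fitted objective is

    L = (1 − γ) L_A + γ L_X,      γ ∈ [0, 1],

where γ balances the two information sources (they live on different
scales, so intermediate γ values are not interpretable as percentage
contributions). γ = 0 ignores attributes and reduces exactly to the
structure-only mixed-membership model; γ = 1 ignores structure. γ is a
hyperparameter, selected in practice by cross-validation on held-out
hyperedge prediction.

## Inference

Jensen's inequality with auxiliary distributions ρ (community pairs per
edge-node-pair), h and h′ (communities per node-attribute cell) gives a
lower bound that is tight at

    ρ^{(e)}_{ijkq} = u_ik u_jq w_kq / λ_e,
    h_izk  ∝ β_kz u_ik,      h′_izk ∝ β_kz (1 − u_ik).

Maximizing the bound blockwise yields closed-form updates:

* `w_kq ← w_kq · [Σ_e (A_e/λ_e)(s_ek s_eq − t_ekq)] / [C (S_k S_q − T_kq)]`
  with `s_e = Σ_{i∈e} u_i`, `t_e = Σ_{i∈e} u_i u_i^T`, `S = Σ_i u_i`,
  `T = Σ_i u_i u_i^T`. Because `w_kq = w_qk` is a single parameter, the
  (k,q) and (q,k) responsibility sums are aggregated, which keeps the
  update symmetric entrywise. Zero denominators map to 0 (no mass to
  distribute) and are counted on the fit result.
* `β_kz ∝ Σ_i x_iz h_izk + (1 − x_iz) h′_izk`, columns renormalized.
* each `u_ik` solves `a u² − (a+b+c) u + b = 0` with nonnegative
  coefficients `a` (expected-rate pressure), `b` (structural responsibility
  mass plus matched-attribute responsibility) and `c` (unmatched-attribute
  responsibility); the smallest root, computed by the numerically stable
  form `2b / (a+b+c + sqrt((a+b+c)² − 4ab))`, always lies in [0, 1] so the
  box constraint stays inactive. At γ = 0 the update degenerates to the
  multiplicative structure-only update, clipped to [0, 1] (the KKT
  multiplier is active only when the unconstrained value exceeds 1).

ρ is never materialized: substituting its closed form turns all structural
sums into per-edge accumulators, so one iteration costs
O(K(K+Z)(N + Σ_e |e|)) time and O((N + Σ_e |e|)K) memory. An explicit-ρ
evaluator exists for diagnostics and small-instance tests.

**Update order.** Within one iteration the membership update uses
responsibilities at the current (u, w, β); the affinity update re-tightens ρ
at the fresh u; the loading update re-tightens h, h′ at the fresh u. Each
parameter block therefore performs an exact maximization of a bound that
touches the objective at the current point, which is what makes the
recorded objective non-decreasing in practice (verified to slack 1e-8 on
every monitored fit; the simultaneous membership update is not covered by a
blockwise MM guarantee because the expected-rate term couples membership
rows, so monotonicity is asserted empirically rather than proved).

**Numerics.** Inside the EM loop every log/division argument is floored at
1e-300 so degenerate iterates (e.g. an observed edge with zero rate under
the current parameters) survive restarts; the exact evaluators never floor
and return −inf with a structured flag instead. Convergence is declared
when the relative objective change between checks (every `check_every = 5`
iterations by default) falls below `tol = 1e-6`; defaults `max_iter = 2000`
and `n_restarts = 10` with restart r seeded at `seed + r`, keeping the run
with the highest final objective (ties: lowest restart index).
Initialization is i.i.d. uniform on [0,1] for u, uniform symmetrized for w,
and uniform column-normalized for β.

## Synthetic data

The generator emulates planted assortative communities: each node gets a
primary community uniformly at random; a `mixing` fraction of nodes split
their unit mass evenly between the primary and one other community; the
affinity matrix has off-diagonal base `1/N` and diagonal
`assortativity / N`. This scale gives sparse hypergraphs (average incidence
degree in the single digits at the default recovery settings N = 30,
assortativity = 5, mixing = 0.2), deliberately in the regime where
structure alone is informative but imperfect — informative attributes can
then be seen to help. Hyperedge weights are sampled exactly from the model:
every candidate subset of sizes 2..D draws `A_e ~ Pois(λ_e/κ_e)` and
positive draws are kept (enumeration guarded to N ≤ 40, D ≤ 5; beyond that
an explicitly flagged stratified approximation matches per-size expected
counts with rejection sampling proportional to each subset's success
probability). Attributes copy the planted community (argmax of the true
membership, ties to the lowest index) for an exact `round(ρN)` uniformly
chosen nodes and are uniform over the Z levels otherwise — coincidental
matches in the random fraction are allowed, and the exact matched count
(rather than i.i.d. coin flips) reduces variance in recovery experiments.

What this does **not** emulate: degree heterogeneity, size-dependent edge
formation mechanisms, attribute noise structured by community, or multiple
covariates — so passing recovery tests demonstrates correctness of the
inference machinery under the model's own assumptions, not robustness to
real-data misspecification.

## Evaluation

Hyperedge prediction draws one same-size negative per held-out positive and
compares Poisson rates `λ/κ` (rank-equivalent to comparing Poisson
probabilities at equal size, and weight-free), scoring
`AUC = (#(R1>R0) + 0.5·#(R1==R0)) / |R1|`. Uniform negatives are resampled
(up to 100 times) when they collide with an observed hyperedge — a positive
drawn as its own negative would be a guaranteed tie biasing the AUC
downward; switch-one-out negatives replace exactly one member node with a
uniformly chosen outside node, leaving Jaccard overlap `(m−1)/(m+1)`.
Cross-validation shuffles hyperedges into disjoint folds (80/20 at the
default 5 folds), fits on the complement and scores the held-out fold; the
best (K, γ) maximizes mean test AUC with no multiple-testing adjustment.
Membership recovery is scored by mean node-wise cosine similarity after an
optimal column matching; the matching is a linear assignment problem (the
score is linear in the permutation), solved exactly for any K, with
zero-padding when community counts differ and all-zero rows contributing 0.

Connectivity-preserving subsampling (for partial-observation experiments)
removes uniformly chosen hyperedges, skipping any whose removal would
disconnect the shared-edge projection over all N nodes; skipped candidates
never become removable again (removing edges only reduces connectivity), so
rejection terminates after one pass over candidates and warns if every
remaining edge is a bridge before the target is reached.

## Problem sizes and design choices

The test and acceptance workloads use desk-scale instances chosen for
statistical clarity: exact-oracle comparisons at N ≤ 12 (full enumeration),
EM guarantee checks at N = 100 with ~300 hyperedges, and recovery/prediction
experiments at N = 30, D = 3, K = Z = 2 over 5–10 instance seeds with fold
AUCs averaged over 5 negative-sampling realizations to control Monte-Carlo
error. Known limitations: no degree correction; hyperedge conditional
independence is assumed; γ is global (one balance for all covariate types);
the approximate large-N sampler matches expected counts but not the exact
joint distribution; and monotonicity of the simultaneous membership update
is empirical, not proved.
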