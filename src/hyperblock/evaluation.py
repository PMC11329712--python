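"""Hyperedge prediction (AUC), negative sampling and K/gamma cross-validation.

The AUC is estimated by one comparison per held-out hyperedge: each positive
is paired with one negative of the same size and the model's Poisson rates
lambda_e / kappa_e are compared (for equal sizes the rate is a strictly
monotone transform of the Poisson probability of observing the edge, so the
comparison is rank-equivalent and weight-free):

    AUC = (#(R1 > R0) + 0.5 #(R1 == R0)) / |R1|.

Negatives come in two flavours: ``uniform`` (a uniformly random node subset
of the same size, resampled up to 100 times if it collides with an observed
hyperedge) and ``soo`` (switch-one-out: one member node of the positive is
replaced by a uniformly chosen outside node, leaving Jaccard similarity
(m-1)/(m+1) for a size-m edge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .em import FitConfig, fit_best_of
from .io import AttributeTable, Hypergraph
from .likelihood import ModelParams, edge_rate, log_kappa

__all__ = [
    "CVResult",
    "cosine_membership_similarity",
    "sample_negative",
    "auc_from_scores",
    "hyperedge_auc",
    "cross_validate",
]


@dataclass
class CVResult:
    """Grid-search records and the (K, gamma) pair with maximal mean AUC."""

    grid: list = field(default_factory=list)  # dicts: K, gamma, fold, auc
    best_K: int = None
    best_gamma: float = None
    best_mean_auc: float = None


def cosine_membership_similarity(U: np.ndarray, V: np.ndarray) -> float:
    """Mean node-wise cosine similarity between two membership matrices,
    maximized over a matching of the columns.

    All-zero rows contribute 0.  When column counts differ, the smaller
    matrix is zero-padded; the optimal column permutation is found exactly
    by linear assignment (the score is linear in the permutation:
    score(pi) = sum_k M[k, pi(k)] with M the node-normalized cross-product).
    """
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if U.shape[0] != V.shape[0]:
        raise ValueError("membership matrices must share the node dimension")
    N = U.shape[0]
    K = max(U.shape[1], V.shape[1])
    Up = np.zeros((N, K))
    Vp = np.zeros((N, K))
    Up[:, :U.shape[1]] = U
    Vp[:, :V.shape[1]] = V

    def normalize(M):
        norms = np.linalg.norm(M, axis=1, keepdims=True)
        return np.divide(M, norms, out=np.zeros_like(M), where=norms > 0)

    M = normalize(Up).T @ normalize(Vp) / N
    rows, cols = linear_sum_assignment(M, maximize=True)
    return float(M[rows, cols].sum())


def sample_negative(edge, h: Hypergraph, mode: str = "uniform", seed=0,
                    rng: np.random.Generator | None = None):
    """Draw one negative hyperedge of the same size as ``edge``.

    uniform: a uniformly random size-|edge| subset of V, resampled (at most
    100 times) if it equals an observed hyperedge of ``h``.
    soo: one node of the edge (chosen uniformly) is switched with a
    uniformly chosen node outside the edge.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    edge = tuple(sorted(edge))
    m = len(edge)
    if mode == "soo":
        if m >= h.N:
            raise ValueError("switch-one-out needs |edge| < N")
        drop = edge[rng.integers(m)]
        outside = np.setdiff1d(np.arange(h.N), edge, assume_unique=False)
        add = int(outside[rng.integers(len(outside))])
        return tuple(sorted(set(edge) - {drop} | {add}))
    if mode != "uniform":
        raise ValueError(f"unknown negative-sampling mode {mode!r}")
    if m > h.N:
        raise ValueError("edge size cannot exceed N")
    observed = set(h.edges)
    draw = None
    for _ in range(100):
        draw = tuple(sorted(rng.choice(h.N, size=m, replace=False).tolist()))
        if draw not in observed:
            return draw
    warnings.warn("negative resampling exhausted; returning an observed edge",
                  stacklevel=2)
    return draw


def auc_from_scores(r1, r0) -> float:
    """(#(R1 > R0) + 0.5 #(R1 == R0)) / |R1| for paired score vectors."""
    r1 = np.asarray(r1, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    if r1.size == 0 or r1.shape != r0.shape:
        raise ValueError("need equally sized, nonempty score vectors")
    return float((np.sum(r1 > r0) + 0.5 * np.sum(r1 == r0)) / r1.size)


def hyperedge_auc(test_edges, params: ModelParams, h: Hypergraph,
                  mode: str = "uniform", seed: int = 0) -> float:
    """AUC of ``params`` on held-out hyperedges: one same-size negative per
    positive, rates lambda/kappa compared with ties counted half.

    ``h`` supplies the node universe and the observed edges that uniform
    negatives must avoid (typically the full hypergraph, train + test).
    """
    test_edges = list(test_edges)
    if not test_edges:
        raise ValueError("empty test set")
    rng = np.random.default_rng(seed)
    r1 = np.empty(len(test_edges))
    r0 = np.empty(len(test_edges))
    for idx, e in enumerate(test_edges):
        neg = sample_negative(e, h, mode=mode, rng=rng)
        scale = np.exp(-log_kappa(len(e), h.N))
        r1[idx] = edge_rate(e, params.u, params.w) * scale
        r0[idx] = edge_rate(neg, params.u, params.w) * scale
    return auc_from_scores(r1, r0)


def _make_folds(n_edges: int, n_folds: int, rng: np.random.Generator):
    perm = rng.permutation(n_edges)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def cross_validate(h: Hypergraph, X, K_grid, gamma_grid, n_folds: int = 5,
                   config: FitConfig | None = None, seed: int = 0,
                   mode: str = "uniform") -> CVResult:
    """Grid search over (K, gamma) by n-fold hyperedge-holdout AUC.

    Hyperedges are split into ``n_folds`` disjoint folds by a seeded shuffle
    (an 80/20 train/test split per fold at the default n_folds = 5); for
    each grid point and fold the model is fitted on the remaining folds and
    scored by AUC on the held-out one.  The best pair maximizes the mean
    test AUC.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    base = config if config is not None else FitConfig()
    rng = np.random.default_rng(seed)
    folds = _make_folds(h.n_edges, n_folds, rng)
    if any(len(f) == 0 for f in folds):
        raise ValueError("a fold has zero hyperedges; fewer folds needed")
    result = CVResult()
    for K in K_grid:
        for gamma in gamma_grid:
            fold_aucs = []
            for fold_idx, test_idx in enumerate(folds):
                train_mask = np.ones(h.n_edges, dtype=bool)
                train_mask[test_idx] = False
                train = Hypergraph(
                    list(h.node_labels),
                    [h.edges[i] for i in np.flatnonzero(train_mask)],
                    h.weights[train_mask],
                )
                cfg = FitConfig(K=K, gamma=gamma, max_iter=base.max_iter,
                                tol=base.tol, check_every=base.check_every,
                                n_restarts=base.n_restarts,
                                seed=base.seed + 1000 * fold_idx)
                res = fit_best_of(train, X, cfg)
                test_edges = [h.edges[i] for i in test_idx]
                score = hyperedge_auc(test_edges, res.params, h, mode=mode,
                                      seed=seed + fold_idx)
                fold_aucs.append(score)
                result.grid.append({"K": K, "gamma": gamma,
                                    "fold": fold_idx, "auc": score})
            mean_auc = float(np.mean(fold_aucs))
            if result.best_mean_auc is None or mean_auc > result.best_mean_auc:
                result.best_K, result.best_gamma = K, gamma
                result.best_mean_auc = mean_auc
    return result
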