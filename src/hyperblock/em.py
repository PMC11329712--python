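"""Variational EM for the attributed hypergraph block model.

The combined objective L = (1-gamma) L_A + gamma L_X is maximized by
alternating closed-form multiplicative updates.  Jensen's inequality with
auxiliary distributions rho (over community pairs, per edge-node-pair), h and
h' (over communities, per node-attribute cell) yields a lower bound that is
tight at

    rho^{(e)}_{ijkq} = u_ik u_jq w_kq / lambda_e,
    h_izk   = beta_kz u_ik       / sum_k' beta_k'z u_ik',
    h'_izk  = beta_kz (1 - u_ik) / sum_k' beta_k'z (1 - u_ik').

The pairwise responsibilities rho are never materialized during fitting:
substituting their closed form turns every structural sum into per-edge
accumulators built from s_e = sum_{i in e} u_i, which keeps one EM iteration
at O(K(K+Z)(N + |E|)) after the per-edge node sums.

Per iteration (each parameter block re-tightens its own responsibilities, so
each update is an exact maximization of a touching lower bound):

1. u update: coefficients a, b, c from (u, w, h(u, beta)); each entry solves
   a u^2 - (a+b+c) u + b = 0 (smallest root, guaranteed in [0, 1]).  At
   gamma = 0 the multiplicative update with KKT clipping to [0, 1] is used.
2. w update (gamma != 1): w_kq <- w_kq * sum_e (A_e/lambda_e)(s_ek s_eq -
   t_ekq) / (C (S_k S_q - T_kq)), evaluated at the fresh u.
3. beta update (gamma != 0): beta_kz proportional to
   sum_i x_iz h_izk + (1 - x_iz) h'_izk, columns renormalized over k.

Logs and divisions inside the EM loop floor their arguments at 1e-300 so that
degenerate iterates (zero-rate observed edges) survive restarts; the exact
evaluators in :mod:`hyperblock.likelihood` never floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AttributeTable, Hypergraph
from .likelihood import ModelParams, constant_C, pairwise_interaction_sum

logger = logging.getLogger(__name__)

FLOOR = 1e-300

__all__ = [
    "FitConfig",
    "FitResult",
    "update_h",
    "update_h_prime",
    "update_w",
    "update_beta",
    "u_coefficients",
    "solve_u_entry",
    "update_u_gamma0",
    "fit",
    "fit_best_of",
    "compute_rho",
    "structural_elbo",
    "attribute_elbo",
    "elbo",
]


@dataclass
class FitConfig:
    """EM hyperparameters.

    tol is the relative change of the objective between successive checks
    (every ``check_every`` iterations) below which the run stops.
    """

    K: int = 2
    gamma: float = 0.0
    max_iter: int = 2000
    tol: float = 1e-6
    check_every: int = 5
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class FitResult:
    params: ModelParams
    objective_trajectory: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    restart_index: int = 0
    n_zero_denominator: int = 0

    @property
    def objective(self) -> float:
        return self.objective_trajectory[-1]


# ---------------------------------------------------------------------------
# edge bookkeeping
# ---------------------------------------------------------------------------

class _EdgeArrays:
    """Flat index arrays for vectorized per-edge accumulation."""

    def __init__(self, h: Hypergraph):
        self.n_edges = h.n_edges
        self.weights = h.weights.astype(np.float64)
        if h.n_edges:
            self.flat = np.concatenate([np.asarray(e, dtype=np.intp) for e in h.edges])
            sizes = np.array([len(e) for e in h.edges])
            self.ptr = np.concatenate([[0], np.cumsum(sizes)])
            self.edge_of_flat = np.repeat(np.arange(h.n_edges), sizes)
        else:
            self.flat = np.empty(0, dtype=np.intp)
            self.ptr = np.array([0])
            self.edge_of_flat = np.empty(0, dtype=np.intp)

    def edge_sums(self, u):
        """s_e = sum_{i in e} u_i, shape (|E|, K)."""
        if not self.n_edges:
            return np.zeros((0, u.shape[1]))
        return np.add.reduceat(u[self.flat], self.ptr[:-1], axis=0)

    def edge_rates(self, u, w, edge_sums=None):
        """lambda_e for every observed edge, shape (|E|,)."""
        if not self.n_edges:
            return np.zeros(0)
        s = self.edge_sums(u) if edge_sums is None else edge_sums
        d = np.einsum("ij,jk,ik->i", u, w, u)  # u_i^T w u_i per node
        dsum = np.add.reduceat(d[self.flat], self.ptr[:-1])
        return 0.5 * (np.einsum("ej,jk,ek->e", s, w, s) - dsum)


def _node_sums(arrays: _EdgeArrays, n_nodes, per_edge):
    """sum over edges containing each node of a per-edge quantity."""
    out = np.zeros((n_nodes,) + per_edge.shape[1:])
    if arrays.n_edges:
        np.add.at(out, arrays.flat, per_edge[arrays.edge_of_flat])
    return out


# ---------------------------------------------------------------------------
# closed-form updates
# ---------------------------------------------------------------------------

def update_h(X: np.ndarray, u: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """h_izk = beta_kz u_ik / sum_k' beta_k'z u_ik', shape (N, Z, K)."""
    num = u[:, None, :] * beta.T[None, :, :]
    den = np.maximum(num.sum(axis=2, keepdims=True), FLOOR)
    return num / den


def update_h_prime(X: np.ndarray, u: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """h'_izk = beta_kz (1-u_ik) / sum_k' beta_k'z (1-u_ik')."""
    return update_h(X, 1.0 - u, beta)


def update_w(h: Hypergraph, u: np.ndarray, w_current: np.ndarray,
             arrays: _EdgeArrays | None = None, C: float | None = None):
    """Closed-form affinity update with rho evaluated at (u, w_current).

    Since w_kq = w_qk is a single parameter, the (k,q) and (q,k)
    responsibility sums aggregate, giving

        w_kq <- w_kq * [sum_e (A_e/lambda_e)(s_ek s_eq - t_ekq)]
                       / [C (S_k S_q - T_kq)],

    with t_e = sum_{i in e} u_i u_i^T, S = sum_i u_i, T = sum_i u_i u_i^T.
    Entries with zero denominator are set to 0.
    """
    arrays = arrays if arrays is not None else _EdgeArrays(h)
    C = C if C is not None else constant_C(h.N, h.D)
    K = u.shape[1]
    if not arrays.n_edges:
        return np.zeros((K, K))
    s = arrays.edge_sums(u)
    lam = np.maximum(arrays.edge_rates(u, w_current, edge_sums=s), FLOOR)
    r = arrays.weights / lam
    g = _node_sums(arrays, u.shape[0], r)
    num = w_current * (s.T @ (s * r[:, None]) - u.T @ (u * g[:, None]))
    S = u.sum(axis=0)
    den = C * (np.outer(S, S) - u.T @ u)
    w_new = np.where(den > 0, num / np.maximum(den, FLOOR), 0.0)
    return np.maximum(0.5 * (w_new + w_new.T), 0.0)


def update_beta(X: np.ndarray, u: np.ndarray, h: np.ndarray, hp: np.ndarray) -> np.ndarray:
    """beta_kz = sum_i (x_iz h_izk + (1-x_iz) h'_izk), normalized over k."""
    X = np.asarray(X, dtype=np.float64)
    num = np.einsum("iz,izk->kz", X, h) + np.einsum("iz,izk->kz", 1.0 - X, hp)
    return num / np.maximum(num.sum(axis=0, keepdims=True), FLOOR)


def _structural_u_terms(arrays, u, w, C):
    """Returns (a_struct, b_struct): the gamma-free structural pieces of the
    u-update coefficients, with rho substituted analytically."""
    N = u.shape[0]
    S = u.sum(axis=0)
    a = C * ((S[None, :] - u) @ w)
    if arrays.n_edges:
        s = arrays.edge_sums(u)
        lam = np.maximum(arrays.edge_rates(u, w, edge_sums=s), FLOOR)
        r = arrays.weights / lam
        g = _node_sums(arrays, N, r)
        G = _node_sums(arrays, N, s * r[:, None])
        b = u * (G @ w - (u @ w) * g[:, None])
    else:
        b = np.zeros_like(u)
    return a, b


def _attribute_u_terms(X, u, beta):
    """(b_attr, c) = (sum_z x_iz h_izk, sum_z (1-x_iz) h'_izk), fused."""
    pi = np.maximum(u @ beta, FLOOR)
    pic = np.maximum((1.0 - u) @ beta, FLOOR)
    b = u * ((X / pi) @ beta.T)
    c = (1.0 - u) * (((1.0 - X) / pic) @ beta.T)
    return b, c


def u_coefficients(i: int, k: int, h: Hypergraph, X, params: ModelParams,
                   variational=None):
    """Coefficients (a, b, c) of the stationarity quadratic for u_ik:

        a = (1-gamma) C sum_{j != i} sum_q u_jq w_kq
        b = (1-gamma) sum_{e: i in e} A_e sum_{j != i in e} sum_q rho_ijkq
            + gamma sum_z x_iz h_izk
        c = gamma sum_z (1-x_iz) h'_izk

    ``variational`` is unused (rho, h, h' are recomputed from params); the
    argument is kept for signature compatibility.
    """
    arrays = _EdgeArrays(h)
    C = constant_C(h.N, h.D)
    g = params.gamma
    a_s, b_s = _structural_u_terms(arrays, params.u, params.w, C)
    a = 0.0 if g == 1.0 else (1.0 - g) * a_s[i, k]
    b = 0.0 if g == 1.0 else (1.0 - g) * b_s[i, k]
    c = 0.0
    if g > 0.0:
        Xm = X.X if isinstance(X, AttributeTable) else np.asarray(X, dtype=float)
        b_a, c_a = _attribute_u_terms(Xm, params.u, params.beta)
        b += g * b_a[i, k]
        c = g * c_a[i, k]
    return float(a), float(b), float(c)


def solve_u_entry(a: float, b: float, c: float) -> float:
    """Smallest root of a u^2 - (a+b+c) u + b = 0, which lies in [0, 1].

    a = 0 degenerates to the linear solution b/(b+c) (0 if b+c = 0).
    """
    if a < 0 or b < 0 or c < 0:
        raise ValueError("coefficients must be nonnegative")
    s = a + b + c
    if a > 0:
        disc = max(s * s - 4.0 * a * b, 0.0)
        denom = s + np.sqrt(disc)
        return float(2.0 * b / denom) if denom > 0 else 0.0
    return float(b / (b + c)) if (b + c) > 0 else 0.0


def _solve_u(a, b, c):
    """Vectorized smallest-root solver; output clipped to [0, 1]."""
    s = a + b + c
    disc = np.maximum(s * s - 4.0 * a * b, 0.0)
    denom = s + np.sqrt(disc)
    quad = np.divide(2.0 * b, denom, out=np.zeros_like(b), where=denom > 0)
    lin = np.divide(b, b + c, out=np.zeros_like(b), where=(b + c) > 0)
    u = np.where(a > 0, quad, lin)
    return np.clip(u, 0.0, 1.0)


def update_u_gamma0(h: Hypergraph, u: np.ndarray, w: np.ndarray,
                    arrays: _EdgeArrays | None = None, C: float | None = None):
    """Pure-structural membership update (gamma = 0 case):

        u_ik <- [sum_{e: i in e} A_e sum_{j != i in e} sum_q rho_ijkq]
                / [C sum_{j != i} sum_q u_jq w_kq],

    clipped to [0, 1] (the upper-bound Lagrange multiplier is active only
    when the unconstrained value exceeds 1).  Zero denominators map to 0.
    """
    arrays = arrays if arrays is not None else _EdgeArrays(h)
    C = C if C is not None else constant_C(h.N, h.D)
    a, b = _structural_u_terms(arrays, u, w, C)
    u_new = np.divide(b, a, out=np.zeros_like(b), where=a > 0)
    return np.clip(u_new, 0.0, 1.0)


# ---------------------------------------------------------------------------
# objective (floored, EM-internal) and the fit loop
# ---------------------------------------------------------------------------

def _em_objective(arrays, X, u, w, beta, gamma, C):
    total = 0.0
    if gamma < 1.0:
        L_A = -C * pairwise_interaction_sum(u, w)
        lam = np.maximum(arrays.edge_rates(u, w), FLOOR)
        L_A += float(arrays.weights @ np.log(lam))
        total += (1.0 - gamma) * L_A
    if gamma > 0.0:
        pi = np.maximum(u @ beta, FLOOR)
        pic = np.maximum((1.0 - u) @ beta, FLOOR)
        on = X > 0.5
        L_X = float(np.log(pi[on]).sum() + np.log(pic[~on]).sum())
        total += gamma * L_X
    return total


def _init_params(rng, N, K, Z):
    u = rng.uniform(size=(N, K))
    w = rng.uniform(size=(K, K))
    w = 0.5 * (w + w.T)
    beta = rng.uniform(size=(K, Z))
    if Z:
        beta /= beta.sum(axis=0, keepdims=True)
    return u, w, beta


def fit(h: Hypergraph, X, config: FitConfig, callback=None) -> FitResult:
    """One EM run from a seeded random initialization.

    ``X`` may be an :class:`AttributeTable` or a binary (N, Z) array; it may
    be None only when gamma = 0.  ``callback(iteration, u, w, beta)`` is
    invoked after every iteration (used for invariant monitoring).
    """
    gamma = config.gamma
    if X is None:
        if gamma > 0:
            raise ValueError("gamma > 0 requires an attribute table")
        Xm = None
        Z = 0
    else:
        Xm = X.X if isinstance(X, AttributeTable) else np.asarray(X, dtype=np.float64)
        if Xm.shape[0] != h.N:
            raise ValueError("attribute table and hypergraph disagree on N")
        Z = Xm.shape[1]

    arrays = _EdgeArrays(h)
    C = constant_C(h.N, h.D)
    rng = np.random.default_rng(config.seed)
    u, w, beta = _init_params(rng, h.N, config.K, Z)

    n_zero_den = 0
    obj = _em_objective(arrays, Xm, u, w, beta, gamma, C)
    trajectory = [obj]
    converged = False
    n_iter = 0
    for it in range(1, config.max_iter + 1):
        n_iter = it
        # membership update (responsibilities at current u, w, beta)
        if gamma == 0.0:
            a, b = _structural_u_terms(arrays, u, w, C)
            n_zero_den += int(np.count_nonzero((a <= 0) & (b > 0)))
            u = np.clip(np.divide(b, a, out=np.zeros_like(b), where=a > 0), 0.0, 1.0)
        else:
            b_a, c = _attribute_u_terms(Xm, u, beta)
            b = gamma * b_a
            c = gamma * c
            if gamma < 1.0:
                a_s, b_s = _structural_u_terms(arrays, u, w, C)
                a = (1.0 - gamma) * a_s
                b = b + (1.0 - gamma) * b_s
            else:
                a = np.zeros_like(b)
            u = _solve_u(a, b, c)
        # affinity update (rho re-tightened at the fresh u); frozen at gamma=1
        if gamma != 1.0:
            w_new = update_w(h, u, w, arrays=arrays, C=C)
            n_zero_den += int(np.count_nonzero((w_new == 0) & (w > 0)))
            w = w_new
        # attribute-loading update (h, h' at the fresh u)
        if gamma != 0.0:
            pi = np.maximum(u @ beta, FLOOR)
            pic = np.maximum((1.0 - u) @ beta, FLOOR)
            num = beta * (u.T @ (Xm / pi) + (1.0 - u).T @ ((1.0 - Xm) / pic))
            beta = num / np.maximum(num.sum(axis=0, keepdims=True), FLOOR)
        if callback is not None:
            callback(it, u, w, beta)
        if it % config.check_every == 0:
            new_obj = _em_objective(arrays, Xm, u, w, beta, gamma, C)
            trajectory.append(new_obj)
            rel = abs(new_obj - obj) / max(abs(obj), 1e-12)
            if rel < config.tol:
                converged = True
                obj = new_obj
                break
            obj = new_obj
    if n_iter % config.check_every != 0:
        trajectory.append(_em_objective(arrays, Xm, u, w, beta, gamma, C))

    params = ModelParams(u=u, w=w, beta=beta if Z else None, gamma=gamma)
    return FitResult(params=params, objective_trajectory=trajectory,
                     converged=converged, n_iter=n_iter,
                     n_zero_denominator=n_zero_den)


def fit_best_of(h: Hypergraph, X, config: FitConfig, callback=None) -> FitResult:
    """Run ``config.n_restarts`` EM fits with seeds seed, seed+1, ... and
    return the run with the highest final objective (ties: lowest index)."""
    best = None
    for r in range(config.n_restarts):
        cfg = FitConfig(K=config.K, gamma=config.gamma, max_iter=config.max_iter,
                        tol=config.tol, check_every=config.check_every,
                        n_restarts=1, seed=config.seed + r)
        res = fit(h, X, cfg, callback=callback)
        res.restart_index = r
        logger.info("restart %d: objective %.6f after %d iterations",
                    r, res.objective, res.n_iter)
        if best is None or res.objective > best.objective:
            best = res
    return best


# ---------------------------------------------------------------------------
# explicit variational objects (testing / diagnostics only)
# ---------------------------------------------------------------------------

def compute_rho(h: Hypergraph, u: np.ndarray, w: np.ndarray):
    """Materialize rho^{(e)}_{ijkq} = u_ik u_jq w_kq / lambda_e per edge.

    Returns a list (one entry per observed edge) of ``(pairs, rho)`` with
    ``pairs`` the (m, 2) array of ordered node pairs i < j within the edge
    and ``rho`` of shape (m, K, K).  Quadratic in edge size; diagnostics and
    small-instance tests only.
    """
    out = []
    for e in h.edges:
        idx = np.asarray(e, dtype=np.intp)
        ii, jj = np.triu_indices(len(idx), k=1)
        pairs = np.stack([idx[ii], idx[jj]], axis=1)
        contrib = u[pairs[:, 0], :, None] * u[pairs[:, 1], None, :] * w[None, :, :]
        lam = contrib.sum()
        rho = contrib / lam if lam > 0 else np.zeros_like(contrib)
        out.append((pairs, rho))
    return out


def _xlogy(x, y):
    out = np.zeros_like(np.broadcast_arrays(x, y)[0], dtype=float)
    mask = x > 0
    with np.errstate(divide="ignore"):
        out[mask] = (x * np.log(y))[mask]
    return out


def structural_elbo(h: Hypergraph, u, w, rho) -> float:
    """Jensen lower bound on L_A with explicit rho:
    -C sum_{i<j in V} u^T w u + sum_e A_e sum_{i<j in e} sum_kq
    rho log(u_ik u_jq w_kq / rho)."""
    C = constant_C(h.N, h.D)
    total = -C * pairwise_interaction_sum(u, w)
    for (pairs, r), a in zip(rho, h.weights):
        val = u[pairs[:, 0], :, None] * u[pairs[:, 1], None, :] * w[None, :, :]
        total += a * _xlogy(r, val / np.where(r > 0, r, 1.0)).sum()
    return float(total)


def attribute_elbo(X, u, beta, h_arr, hp_arr) -> float:
    """Jensen lower bound on L_X with explicit h, h'."""
    X = np.asarray(X, dtype=np.float64)
    val = u[:, None, :] * beta.T[None, :, :]
    valp = (1.0 - u)[:, None, :] * beta.T[None, :, :]
    t1 = _xlogy(h_arr, val / np.where(h_arr > 0, h_arr, 1.0))
    t2 = _xlogy(hp_arr, valp / np.where(hp_arr > 0, hp_arr, 1.0))
    return float((X[:, :, None] * t1).sum() + ((1.0 - X)[:, :, None] * t2).sum())


def elbo(h: Hypergraph, X, params: ModelParams, rho, h_arr, hp_arr) -> float:
    """(1-gamma) * structural bound + gamma * attribute bound (Jensen)."""
    g = params.gamma
    total = 0.0
    if g < 1.0:
        total += (1.0 - g) * structural_elbo(h, params.u, params.w, rho)
    if g > 0.0:
        Xm = X.X if isinstance(X, AttributeTable) else X
        total += g * attribute_elbo(Xm, params.u, params.beta, h_arr, hp_arr)
    return total
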