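"""Exact log-likelihood evaluation for the attributed hypergraph block model.

Structural part: hyperedge weights A_e are independent Poisson variables with
rate lambda_e / kappa_e, where

    lambda_e = sum_{i<j in e} u_i^T w u_j,
    kappa_d  = d(d-1)/2 * binom(N-2, d-2)   (d = |e|),

over the set Omega of all node subsets of sizes 2..D.  Summed over Omega the
expected-rate term collapses to a pairwise node sum scaled by the constant

    C = sum_{d=2}^{D} binom(N-2, d-2) / kappa_d  (= 2(1 - 1/D) for this kappa),

giving the tractable log-likelihood

    L_A(u, w) = -C sum_{i<j in V} u_i^T w u_j + sum_{e in E} A_e log lambda_e.

Attribute part: the binary covariate matrix X follows Bernoulli propensities
pi_iz = sum_k u_ik beta_kz, and the objective maximized during inference is

    L_X(u, beta) = sum_{iz} x_iz log(sum_k u_ik beta_kz)
                 + sum_{iz} (1 - x_iz) log(sum_k (1 - u_ik) beta_kz),

whose second term is *not* the Bernoulli complement log(1 - pi_iz); the plain
Bernoulli log-likelihood is exposed separately as a diagnostic
(:func:`bernoulli_loglik_attributes`).  The two objectives coincide when each
row of u is one-hot, and L_X is the quantity the variational updates bound.

A brute-force Poisson evaluator over the full Omega serves as the testing
oracle for L_A on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import poisson

from .io import AttributeTable, Hypergraph

__all__ = [
    "ModelParams",
    "LikelihoodBreakdown",
    "edge_rate",
    "log_kappa",
    "kappa",
    "constant_C",
    "pairwise_interaction_sum",
    "loglik_structure",
    "brute_force_loglik_structure",
    "attribute_propensity",
    "loglik_attributes",
    "bernoulli_loglik_attributes",
    "total_loglik",
]

_BETA_COL_TOL = 1e-8


@dataclass
class ModelParams:
    """Model parameters (u, w, beta, gamma).

    u : (N, K) memberships, entries in [0, 1].
    w : (K, K) symmetric nonnegative affinity.
    beta : (K, Z) attribute loadings, each column summing to 1 over k
        (may have Z = 0 columns when no attributes are modeled).
    gamma : balancing weight in [0, 1] between structure and attributes.
    """

    u: np.ndarray
    w: np.ndarray
    beta: np.ndarray = None
    gamma: float = 0.0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.beta is None:
            self.beta = np.zeros((self.K, 0))
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.validate()

    @property
    def N(self) -> int:
        return self.u.shape[0]

    @property
    def K(self) -> int:
        return self.u.shape[1]

    @property
    def Z(self) -> int:
        return self.beta.shape[1]

    def validate(self):
        if self.u.ndim != 2:
            raise ValueError("u must be 2-D")
        if np.any(self.u < -1e-12) or np.any(self.u > 1 + 1e-12):
            raise ValueError("u entries must lie in [0, 1]")
        if self.w.shape != (self.K, self.K):
            raise ValueError("w must be K x K")
        if np.any(self.w < -1e-12):
            raise ValueError("w must be nonnegative")
        if not np.allclose(self.w, self.w.T, atol=1e-10):
            raise ValueError("w must be symmetric")
        if self.beta.shape[0] != self.K:
            raise ValueError("beta must be K x Z")
        if self.Z and not np.allclose(self.beta.sum(axis=0), 1.0, atol=_BETA_COL_TOL):
            raise ValueError("each beta column must sum to 1 over k")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


@dataclass
class LikelihoodBreakdown:
    """Structural, attribute and combined log-likelihood values."""

    L_A: float
    L_X: float
    L_total: float
    n_zero_rate_edges: int = 0


def edge_rate(edge, u: np.ndarray, w: np.ndarray) -> float:
    """Poisson rate numerator lambda_e = sum_{i<j in e} u_i^T w u_j."""
    idx = np.fromiter(edge, dtype=np.intp)
    if idx.size < 2:
        raise ValueError("edge must have at least 2 nodes")
    ue = u[idx]
    s = ue.sum(axis=0)
    diag = np.einsum("ij,jk,ik->", ue, w, ue)
    return float(0.5 * (s @ w @ s - diag))


def log_kappa(edge_size: int, N: int) -> float:
    """log of kappa_d = d(d-1)/2 * binom(N-2, d-2), stable for large N, d."""
    d = int(edge_size)
    if not 2 <= d <= N:
        raise ValueError(f"edge size must be in [2, N], got {d} with N={N}")
    log_binom = gammaln(N - 1) - gammaln(d - 1) - gammaln(N - d + 1)
    return float(np.log(d * (d - 1) / 2.0) + log_binom)


def kappa(edge_size: int, N: int) -> float:
    """kappa_d itself; overflows to inf for very large binomials, use
    :func:`log_kappa` in that regime."""
    return float(np.exp(log_kappa(edge_size, N)))


def constant_C(N: int, D: int) -> float:
    """C = sum_{d=2}^{D} binom(N-2, d-2) / kappa_d.

    Evaluated in log space; under the default kappa the sum telescopes to
    2(1 - 1/D), independent of N (used as a test oracle, not assumed here).
    """
    if D < 2:
        raise ValueError("D must be >= 2")
    if D > N:
        raise ValueError("D cannot exceed N")
    total = 0.0
    for d in range(2, D + 1):
        log_binom = gammaln(N - 1) - gammaln(d - 1) - gammaln(N - d + 1)
        total += np.exp(log_binom - log_kappa(d, N))
    return float(total)


def pairwise_interaction_sum(u: np.ndarray, w: np.ndarray) -> float:
    """sum_{i<j in V} u_i^T w u_j via the aggregate identity
    (s^T w s - sum_i u_i^T w u_i)/2 with s = sum_i u_i; O(NK + K^2)."""
    s = u.sum(axis=0)
    diag = np.einsum("ij,jk,ik->", u, w, u)
    return float(0.5 * (s @ w @ s - diag))


def loglik_structure(h: Hypergraph, u: np.ndarray, w: np.ndarray) -> float:
    """Structural log-likelihood L_A(u, w); -inf if an observed edge has
    zero rate (see :func:`total_loglik` for the flagged count)."""
    val, _ = _loglik_structure_flagged(h, u, w)
    return val


def _loglik_structure_flagged(h, u, w):
    total = -constant_C(h.N, h.D) * pairwise_interaction_sum(u, w)
    n_zero = 0
    for e, a in zip(h.edges, h.weights):
        lam = edge_rate(e, u, w)
        if lam <= 0:
            n_zero += 1
        else:
            total += a * np.log(lam)
    if n_zero:
        return float("-inf"), n_zero
    return float(total), 0


def brute_force_loglik_structure(h: Hypergraph, u: np.ndarray, w: np.ndarray) -> float:
    """Full Poisson log-likelihood over every subset in Omega (sizes 2..D),
    including the A_e log(1/kappa_e) and log(A_e!) terms.

    Enumeration oracle; guarded to N <= 12, D <= 4.  Differs from
    :func:`loglik_structure` only by a (u, w)-independent constant.
    """
    if h.N > 12 or h.D > 4:
        raise ValueError("brute-force oracle limited to N <= 12, D <= 4")
    observed = {e: int(a) for e, a in zip(h.edges, h.weights)}
    total = 0.0
    for d in range(2, h.D + 1):
        k_d = kappa(d, h.N)
        for e in itertools.combinations(range(h.N), d):
            lam = 0.0
            for a_pos in range(d):
                for b_pos in range(a_pos + 1, d):
                    lam += float(u[e[a_pos]] @ w @ u[e[b_pos]])
            total += poisson.logpmf(observed.get(e, 0), lam / k_d)
    return float(total)


def attribute_propensity(u: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Bernoulli propensities pi_iz = sum_k u_ik beta_kz (N x Z)."""
    u = np.asarray(u, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
        raise ValueError("u entries must lie in [0, 1]")
    if beta.size and not np.allclose(beta.sum(axis=0), 1.0, atol=_BETA_COL_TOL):
        raise ValueError("beta columns must sum to 1")
    return u @ beta


def loglik_attributes(X: np.ndarray, u: np.ndarray, beta: np.ndarray) -> float:
    """Attribute objective L_X(u, beta); -inf when a required log argument
    is nonpositive.  Terms with x_iz = 1 use sum_k u_ik beta_kz, terms with
    x_iz = 0 use sum_k (1 - u_ik) beta_kz."""
    X = np.asarray(X, dtype=np.float64)
    pi = u @ beta
    pi_c = (1.0 - u) @ beta
    total = 0.0
    on = X > 0.5
    if np.any(pi[on] <= 0) or np.any(pi_c[~on] <= 0):
        return float("-inf")
    total += np.log(pi[on]).sum()
    total += np.log(pi_c[~on]).sum()
    return float(total)


def bernoulli_loglik_attributes(X: np.ndarray, u: np.ndarray, beta: np.ndarray) -> float:
    """Diagnostic: plain Bernoulli log-likelihood sum log Bern(x_iz; pi_iz).

    Not the inference objective (its complement term is log(1 - pi_iz));
    coincides with :func:`loglik_attributes` when u rows are one-hot.
    """
    X = np.asarray(X, dtype=np.float64)
    pi = attribute_propensity(u, beta)
    on = X > 0.5
    if np.any(pi[on] <= 0) or np.any(1.0 - pi[~on] <= 0):
        return float("-inf")
    return float(np.log(pi[on]).sum() + np.log1p(-pi[~on]).sum())


def total_loglik(h: Hypergraph, X, params: ModelParams) -> LikelihoodBreakdown:
    """Combined objective L = (1 - gamma) L_A + gamma L_X."""
    params.validate()
    L_A, n_zero = _loglik_structure_flagged(h, params.u, params.w)
    if X is None:
        L_X = 0.0
    else:
        Xm = X.X if isinstance(X, AttributeTable) else X
        L_X = loglik_attributes(Xm, params.u, params.beta)
    g = params.gamma
    # 0 * (+-inf) must not poison the mixture at the endpoints
    L_total = 0.0
    if g < 1.0:
        L_total += (1.0 - g) * L_A
    if g > 0.0:
        L_total += g * L_X
    return LikelihoodBreakdown(L_A=L_A, L_X=L_X, L_total=float(L_total),
                               n_zero_rate_edges=n_zero)
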