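"""Planted-community hypergraphs with correlated node attributes.

The generator draws ground-truth memberships and an assortative affinity
matrix, samples hyperedge weights exactly from the model's Poisson
distribution over every candidate subset (desk scale), and produces
categorical attributes that copy the planted community for a controllable
fraction of nodes (the match fraction) while the rest are uniformly random.

The default affinity scale (off-diagonal base 1/N, diagonal equal to
``assortativity`` times the base) yields sparse hypergraphs, of the kind
where structural information alone is informative but not sufficient for
perfect recovery — the regime where attribute information can make a
measurable difference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .io import AttributeTable, Hypergraph
from .likelihood import log_kappa

__all__ = [
    "PlantedInstance",
    "planted_params",
    "sample_hypergraph",
    "generate_attributes",
    "planted_instance",
]

_EXACT_N_MAX = 40
_EXACT_D_MAX = 5


@dataclass
class PlantedInstance:
    """A sampled hypergraph with its generating truth and attributes."""

    hypergraph: Hypergraph
    attributes: AttributeTable
    u_true: np.ndarray
    w_true: np.ndarray
    match_fraction: float


def planted_params(N: int, K: int, assortativity: float, mixing: float, seed: int):
    """Ground-truth memberships and affinity.

    Each node gets a primary community uniformly at random.  With
    probability 1 - mixing its membership row is one-hot; otherwise the unit
    mass is split evenly between the primary community and one other
    community chosen uniformly.  The affinity matrix has constant
    off-diagonal base 1/N and diagonal assortativity/N.
    """
    if K > N:
        raise ValueError("K cannot exceed N")
    if not 0.0 <= mixing <= 1.0:
        raise ValueError("mixing must lie in [0, 1]")
    if assortativity < 0:
        raise ValueError("assortativity must be nonnegative")
    rng = np.random.default_rng(seed)
    primary = rng.integers(K, size=N)
    u = np.zeros((N, K))
    u[np.arange(N), primary] = 1.0
    if K > 1 and mixing > 0:
        mixed = rng.random(N) < mixing
        other = (primary + rng.integers(1, K, size=N)) % K
        u[mixed, primary[mixed]] = 0.5
        u[mixed, other[mixed]] = 0.5
    base = 1.0 / N
    w = np.full((K, K), base)
    np.fill_diagonal(w, assortativity * base)
    return u, w


def _lambda_for_combos(combos, u, w, node_quad):
    """lambda_e for an (m, d) array of node-index combinations."""
    s = u[combos].sum(axis=1)
    dsum = node_quad[combos].sum(axis=1)
    return 0.5 * (np.einsum("ej,jk,ek->e", s, w, s) - dsum)


def sample_hypergraph(u_true: np.ndarray, w_true: np.ndarray, D: int, seed: int,
                      approximate: bool = False) -> Hypergraph:
    """Sample hyperedge weights A_e ~ Poisson(lambda_e / kappa_|e|) for every
    node subset of sizes 2..D and keep those with A_e > 0.

    Exact enumeration is guarded to N <= 40 and D <= 5; pass
    ``approximate=True`` beyond that to use stratified expected-count
    matching (per size, the number of realized edges is drawn from the
    estimated Poisson-positive expectation and subsets are accepted in
    proportion to their success probability).
    """
    N, K = u_true.shape
    if D < 2:
        raise ValueError("D must be >= 2")
    rng = np.random.default_rng(seed)
    node_quad = np.einsum("ij,jk,ik->i", u_true, w_true, u_true)
    labels = [str(i) for i in range(N)]
    edges, weights = [], []

    if N <= _EXACT_N_MAX and D <= _EXACT_D_MAX:
        for d in range(2, min(D, N) + 1):
            combos = np.array(list(itertools.combinations(range(N), d)), dtype=np.intp)
            lam = _lambda_for_combos(combos, u_true, w_true, node_quad)
            rates = lam * np.exp(-log_kappa(d, N))
            counts = rng.poisson(rates)
            keep = counts > 0
            edges.extend(tuple(c) for c in combos[keep])
            weights.extend(counts[keep].tolist())
        return Hypergraph(labels, edges, np.asarray(weights, dtype=np.int64))

    if not approximate:
        raise ValueError(
            f"exact sampling limited to N <= {_EXACT_N_MAX}, D <= {_EXACT_D_MAX}; "
            "pass approximate=True for stratified sampling"
        )
    # stratified approximation: match the expected number of realized edges
    # per size, sampling subsets with probability proportional to their
    # Poisson-positive success probability via rejection
    from scipy.special import gammaln

    for d in range(2, min(D, N) + 1):
        n_probe = 2000
        probes = np.array([rng.choice(N, size=d, replace=False) for _ in range(n_probe)])
        lam = _lambda_for_combos(probes, u_true, w_true, node_quad)
        p = 1.0 - np.exp(-lam * np.exp(-log_kappa(d, N)))
        log_n_subsets = gammaln(N + 1) - gammaln(d + 1) - gammaln(N - d + 1)
        expected = float(np.exp(log_n_subsets + np.log(max(p.mean(), 1e-300))))
        m = rng.poisson(expected)
        p_max = max(p.max(), 1e-300)
        drawn = {}
        attempts = 0
        while len(drawn) < m and attempts < 50 * max(m, 1):
            attempts += 1
            e = tuple(sorted(rng.choice(N, size=d, replace=False)))
            if e in drawn:
                continue
            lam_e = _lambda_for_combos(np.array([e], dtype=np.intp),
                                       u_true, w_true, node_quad)[0]
            rate = lam_e * np.exp(-log_kappa(d, N))
            p_e = 1.0 - np.exp(-rate)
            if rng.random() < p_e / p_max:
                # weight from the zero-truncated Poisson at this rate
                a = 0
                while a == 0:
                    a = rng.poisson(rate) if rate > 0 else 1
                drawn[e] = int(a)
        edges.extend(drawn.keys())
        weights.extend(drawn.values())
    return Hypergraph(labels, edges, np.asarray(weights, dtype=np.int64))


def generate_attributes(u_true: np.ndarray, Z: int, match_fraction: float,
                        seed: int) -> AttributeTable:
    """One categorical covariate with Z levels that copies the planted
    community for an exact round(match_fraction * N) nodes (chosen uniformly)
    and is uniform over all Z levels for the rest.

    Randomly assigned levels may coincide with the matching level by chance.
    """
    N, K = u_true.shape
    if not 0.0 <= match_fraction <= 1.0:
        raise ValueError("match_fraction must lie in [0, 1]")
    if Z < K:
        raise ValueError("need Z >= K to match attributes to communities")
    rng = np.random.default_rng(seed)
    n_match = int(np.rint(match_fraction * N))
    matched = rng.choice(N, size=n_match, replace=False)
    levels = rng.integers(Z, size=N)
    levels[matched] = u_true[matched].argmax(axis=1)  # argmax ties -> lowest index
    X = np.zeros((N, Z))
    X[np.arange(N), levels] = 1.0
    labels = [str(i) for i in range(N)]
    return AttributeTable(labels, X, [f"attr={z}" for z in range(Z)], [Z])


def planted_instance(N: int, K: int, D: int, assortativity: float, mixing: float,
                     Z: int, match_fraction: float, seed: int,
                     approximate: bool = False) -> PlantedInstance:
    """Convenience wrapper: params, hypergraph and attributes from one seed."""
    u_true, w_true = planted_params(N, K, assortativity, mixing, seed)
    h = sample_hypergraph(u_true, w_true, D, seed + 1, approximate=approximate)
    X = generate_attributes(u_true, Z, match_fraction, seed + 2)
    return PlantedInstance(hypergraph=h, attributes=X, u_true=u_true,
                           w_true=w_true, match_fraction=match_fraction)
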