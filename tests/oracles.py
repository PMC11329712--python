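"""Independent oracles and instance factories shared across the test suite.

Everything here is deliberately naive (explicit Python loops, textbook
formulas) so it exercises none of the vectorized code paths it is used to
check.
"""

import numpy as np

from hyperblock import Hypergraph


def random_hypergraph(N, n_edges, max_size, seed, max_weight=3):
    """Random hypergraph with sizes uniform on [2, max_size]."""
    rng = np.random.default_rng(seed)
    edges, weights = [], []
    for _ in range(n_edges):
        d = int(rng.integers(2, max_size + 1))
        edges.append(tuple(sorted(rng.choice(N, size=d, replace=False).tolist())))
        weights.append(int(rng.integers(1, max_weight + 1)))
    return Hypergraph([str(i) for i in range(N)], edges, np.asarray(weights))


def random_params(N, K, Z, seed, low=0.05, high=0.95):
    """Interior random parameters (safe for unfloored log evaluation)."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(low, high, size=(N, K))
    w = rng.uniform(0.2, 1.0, size=(K, K))
    w = 0.5 * (w + w.T)
    beta = rng.uniform(0.1, 1.0, size=(K, Z))
    if Z:
        beta = beta / beta.sum(axis=0, keepdims=True)
    return u, w, beta


def random_onehot(N, Z, seed):
    rng = np.random.default_rng(seed)
    X = np.zeros((N, Z))
    X[np.arange(N), rng.integers(Z, size=N)] = 1.0
    return X


def pairwise_sum_bruteforce(u, w):
    """sum_{i<j in V} u_i^T w u_j by explicit double loop."""
    N = u.shape[0]
    total = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            total += float(u[i] @ w @ u[j])
    return total


def edge_rate_bruteforce(edge, u, w):
    edge = list(edge)
    total = 0.0
    for a in range(len(edge)):
        for b in range(a + 1, len(edge)):
            total += float(u[edge[a]] @ w @ u[edge[b]])
    return total


def bfs_connected(n_nodes, edges):
    """Connectivity of the shared-edge projection by hand-rolled BFS."""
    adj = {i: set() for i in range(n_nodes)}
    for e in edges:
        for i in e:
            adj[i].update(j for j in e if j != i)
    if n_nodes == 0:
        return True
    seen = {0}
    frontier = [0]
    while frontier:
        nxt = []
        for i in frontier:
            for j in adj[i]:
                if j not in seen:
                    seen.add(j)
                    nxt.append(j)
        frontier = nxt
    return len(seen) == n_nodes


def reference_structure_only_step(h, u, w, C):
    """One EM iteration of the pure-structural model written with explicit
    loops: membership update (clipped to [0, 1]) from responsibilities at
    (u, w), then affinity update with responsibilities re-tightened at the
    fresh memberships."""
    N, K = u.shape

    def rates(uu):
        return {e: edge_rate_bruteforce(e, uu, w) for e in h.edges}

    lam = rates(u)
    u_new = np.zeros_like(u)
    for i in range(N):
        for k in range(K):
            num = 0.0
            for e, a in zip(h.edges, h.weights):
                if i in e:
                    for j in e:
                        if j != i:
                            for q in range(K):
                                num += a * u[i, k] * u[j, q] * w[k, q] / lam[e]
            den = C * sum(u[j, q] * w[k, q]
                          for j in range(N) if j != i for q in range(K))
            u_new[i, k] = min(max(num / den if den > 0 else 0.0, 0.0), 1.0)

    lam2 = rates(u_new)
    w_new = np.zeros_like(w)
    for k in range(K):
        for q in range(K):
            num = 0.0
            for e, a in zip(h.edges, h.weights):
                for i in e:
                    for j in e:
                        if i != j:
                            num += a * u_new[i, k] * u_new[j, q] * w[k, q] / lam2[e]
            den = C * sum(u_new[i, k] * u_new[j, q]
                          for i in range(N) for j in range(N) if i != j)
            w_new[k, q] = num / den if den > 0 else 0.0
    return u_new, w_new
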