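"""Reading, writing and subsampling hypergraphs and node-attribute tables.

A hypergraph is stored as a list of unique node labels (mapped to contiguous
0-based ids), a list of hyperedges (each a sorted tuple of at least two
distinct node ids) and one positive integer weight per hyperedge.  Duplicate
hyperedges are merged by summing their weights, so a weight plays the role of
an interaction count.

Attributes are categorical node covariates, one-hot expanded into a binary
N x Z matrix whose columns are grouped into per-covariate blocks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Hypergraph",
    "AttributeTable",
    "MalformedEdgeError",
    "read_hypergraph",
    "write_hypergraph",
    "read_attributes",
    "write_attributes",
    "subsample_keep_connected",
    "is_connected",
]


class MalformedEdgeError(ValueError):
    """Raised when a hyperedge has fewer than two distinct nodes."""


def _normalize_edges(edges, weights, n_nodes):
    """Sort, validate and merge duplicate edges (weights are summed)."""
    merged: dict[tuple, int] = {}
    for e, a in zip(edges, weights):
        e = tuple(sorted(set(int(i) for i in e)))
        if len(e) < 2:
            raise MalformedEdgeError(f"hyperedge {e!r} has fewer than 2 distinct nodes")
        if e[0] < 0 or e[-1] >= n_nodes:
            raise IndexError(f"hyperedge {e!r} refers to node ids outside [0, {n_nodes})")
        a = int(a)
        if a < 1 or a != float(a):
            raise ValueError(f"hyperedge weight must be a positive integer, got {a!r}")
        merged[e] = merged.get(e, 0) + a
    out = sorted(merged.items())
    return [e for e, _ in out], np.array([a for _, a in out], dtype=np.int64)


@dataclass
class Hypergraph:
    """A weighted hypergraph with integer edge weights.

    Parameters
    ----------
    node_labels : list of str
        Unique labels; position in the list is the 0-based node id.
    edges : list of tuple of int
        Hyperedges as sorted tuples of node ids, each of size >= 2.
        Duplicates are merged by summing weights.
    weights : array of int
        One positive integer weight per edge.
    """

    node_labels: list
    edges: list = field(default_factory=list)
    weights: np.ndarray = None

    def __post_init__(self):
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be unique")
        if self.weights is None:
            self.weights = np.ones(len(self.edges), dtype=np.int64)
        self.edges, self.weights = _normalize_edges(self.edges, self.weights, self.N)

    @property
    def N(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def D(self) -> int:
        """Maximum observed hyperedge size (2 when the edge set is empty)."""
        return max((len(e) for e in self.edges), default=2)

    def add_nodes(self, labels) -> "Hypergraph":
        """Return a copy with extra isolated nodes appended."""
        new = [l for l in labels if l not in set(self.node_labels)]
        return Hypergraph(list(self.node_labels) + new, list(self.edges), self.weights.copy())

    def clique_projection(self) -> nx.Graph:
        """Pairwise graph where two nodes are linked iff they share a hyperedge.

        A star per hyperedge is sufficient for connectivity queries, but the
        full clique is cheap at the scales this package targets.
        """
        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        for e in self.edges:
            g.add_edges_from((e[0], j) for j in e[1:])
            g.add_edges_from(zip(e[:-1], e[1:]))
        return g


def is_connected(h: Hypergraph) -> bool:
    """True iff all N nodes are mutually reachable via shared hyperedges."""
    if h.N == 0:
        return True
    return nx.is_connected(h.clique_projection())


@dataclass
class AttributeTable:
    """One-hot encoded categorical node covariates.

    ``X`` is binary with shape (N, Z) where Z is the total number of levels
    over all covariates; within each covariate's column block every row sums
    to exactly 1.
    """

    node_labels: list
    X: np.ndarray
    attribute_names: list
    group_sizes: list

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.shape != (len(self.node_labels), len(self.attribute_names)):
            raise ValueError("X shape inconsistent with labels/attribute names")
        if not np.isin(self.X, (0.0, 1.0)).all():
            raise ValueError("X entries must be binary")
        if sum(self.group_sizes) != self.Z:
            raise ValueError("group_sizes must sum to Z")
        start = 0
        for gs in self.group_sizes:
            block = self.X[:, start:start + gs]
            if not np.all(block.sum(axis=1) == 1):
                raise ValueError("each covariate block must be one-hot per row")
            start += gs

    @property
    def N(self) -> int:
        return len(self.node_labels)

    @property
    def Z(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# file formats: plain-text hyperedge lists and attribute CSVs
# ---------------------------------------------------------------------------

def read_hypergraph(path) -> Hypergraph:
    """Parse a hyperedge-list file: one hyperedge per line, whitespace- or
    comma-separated node labels, optional trailing ``w=<int>`` weight token.

    Node labels are mapped to 0-based ids in first-appearance order and
    duplicate hyperedges are merged by summing weights.
    """
    labels: dict[str, int] = {}
    edges, weights = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if line.startswith("# nodes:"):
                # optional header fixing the label order (written by
                # write_hypergraph; lets isolated nodes round-trip)
                for t in line[len("# nodes:"):].split():
                    if t not in labels:
                        labels[t] = len(labels)
                continue
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            weight = 1
            if tokens and tokens[-1].startswith("w="):
                raw = tokens.pop()[2:]
                try:
                    weight = int(raw)
                except ValueError:
                    raise ValueError(f"line {lineno}: non-integer weight {raw!r}")
                if weight <= 0:
                    raise ValueError(f"line {lineno}: weight must be positive, got {weight}")
            node_set = set(tokens)
            if len(node_set) < 2:
                raise MalformedEdgeError(
                    f"line {lineno}: hyperedge needs >= 2 distinct nodes, got {sorted(node_set)}"
                )
            for t in tokens:
                if t not in labels:
                    labels[t] = len(labels)
            edges.append(tuple(labels[t] for t in node_set))
            weights.append(weight)
    order = sorted(labels, key=labels.get)
    return Hypergraph(order, edges, np.asarray(weights))


def write_hypergraph(h: Hypergraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# nodes: " + " ".join(h.node_labels) + "\n")
        for e, a in zip(h.edges, h.weights):
            fh.write(" ".join(h.node_labels[i] for i in e) + f" w={int(a)}\n")


def read_attributes(path, hypergraph: Hypergraph) -> AttributeTable:
    """Read a CSV (node-label column + >=1 categorical columns) and one-hot
    expand it, aligned to the hypergraph's node ids.

    Every hypergraph node must be present; nodes present only in the CSV are
    appended after the hypergraph's nodes (use :meth:`Hypergraph.add_nodes`
    to retain them on the hypergraph side).
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("attribute CSV needs a label column plus >= 1 categorical column")
    label_col = df.columns[0]
    if df[label_col].duplicated().any():
        dup = df[label_col][df[label_col].duplicated()].iloc[0]
        raise ValueError(f"duplicate attribute rows for node {dup!r}")
    present = set(df[label_col])
    missing = [l for l in hypergraph.node_labels if l not in present]
    if missing:
        raise KeyError(f"nodes missing from attribute table: {missing[:5]}")
    extra = [l for l in df[label_col] if l not in set(hypergraph.node_labels)]
    order = list(hypergraph.node_labels) + extra
    df = df.set_index(label_col).loc[order]

    blocks, names, sizes = [], [], []
    for col in df.columns:
        levels = sorted(df[col].dropna().unique())
        if df[col].isna().any():
            raise ValueError(f"column {col!r} has missing values")
        onehot = np.stack([(df[col] == lv).to_numpy(dtype=np.float64) for lv in levels], axis=1)
        blocks.append(onehot)
        names.extend(f"{col}={lv}" for lv in levels)
        sizes.append(len(levels))
    return AttributeTable(order, np.concatenate(blocks, axis=1), names, sizes)


def write_attributes(table: AttributeTable, path) -> None:
    """Write the categorical form back out (inverse of one-hot expansion)."""
    data = {"node": table.node_labels}
    start = 0
    for gs in table.group_sizes:
        names = table.attribute_names[start:start + gs]
        col = names[0].split("=", 1)[0]
        levels = [n.split("=", 1)[1] for n in names]
        idx = table.X[:, start:start + gs].argmax(axis=1)
        data[col] = [levels[i] for i in idx]
        start += gs
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

def subsample_keep_connected(h: Hypergraph, keep_fraction: float, seed: int) -> Hypergraph:
    """Remove hyperedges uniformly at random while keeping all N nodes
    connected through shared hyperedges (rejection scheme).

    Keeps ``ceil(keep_fraction * |E|)`` edges.  A removal candidate whose
    deletion would disconnect the current hypergraph is skipped; because
    removing other edges can only reduce connectivity, a skipped candidate
    never becomes removable again.  If no removable edge is left before the
    target is reached, the current state is returned with a warning.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if not is_connected(h):
        raise ValueError("input hypergraph must be connected")
    target = int(np.ceil(keep_fraction * h.n_edges))
    rng = np.random.default_rng(seed)
    edges = list(h.edges)
    weights = list(h.weights)
    candidates = list(range(len(edges)))
    alive = [True] * len(edges)

    def connected_without(skip_idx):
        g = nx.Graph()
        g.add_nodes_from(range(h.N))
        for idx, e in enumerate(edges):
            if alive[idx] and idx != skip_idx:
                g.add_edges_from((e[0], j) for j in e[1:])
        return nx.is_connected(g)

    n_alive = len(edges)
    while n_alive > target and candidates:
        pos = rng.integers(len(candidates))
        idx = candidates.pop(int(pos))
        if connected_without(idx):
            alive[idx] = False
            n_alive -= 1
    if n_alive > target:
        warnings.warn(
            f"subsampling stopped at {n_alive} edges (target {target}): "
            "every remaining hyperedge is a bridge",
            stacklevel=2,
        )
    kept = [i for i in range(len(edges)) if alive[i]]
    return Hypergraph(list(h.node_labels), [edges[i] for i in kept],
                      np.asarray([weights[i] for i in kept]))
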