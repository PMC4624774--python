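"""Weighted symptom networks: Spearman edges and graph/node metrics.

A symptom network is a complete weighted graph whose nodes are the merged
symptom variables and whose edge weights are groupwise Spearman rank
correlations (average ranks, pairwise-complete observations). Three
metrics summarise it:

* *density* -- the arithmetic mean of the upper-triangle edge weights
  (signed by default; an absolute-value variant is available for
  sensitivity checks);
* *node strength* (weighted degree centrality) -- the sum of a node's
  incident edge weights;
* *random-walk betweenness* -- Newman's current-flow betweenness: the
  expected net flow through a node over unit-current injections between
  every other source-target pair, with conductance |weight|, normalised
  by the (n-1)(n-2)/2 pairs that exclude the node.

Edges below a magnitude threshold may be pruned *for display/export
only*; every metric is always computed on the full matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

__all__ = [
    "SymptomNetwork",
    "NetworkError",
    "spearman_edge",
    "spearman_matrix",
    "build_network",
    "network_density",
    "node_strength",
    "random_walk_betweenness",
    "current_flow_betweenness",
    "prune_edges",
    "SpearmanNetwork",
    "export_network",
    "read_network",
]


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class SymptomNetwork:
    """Symmetric weighted graph over the merged symptom items.

    ``weights`` is a symmetric matrix with zero diagonal and off-diagonal
    entries in [-1, 1]; ``n_patients`` records the group size used for
    estimation.
    """

    items: tuple[str, ...]
    weights: np.ndarray
    n_patients: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        k = len(self.items)
        if w.shape != (k, k):
            raise NetworkError(f"weight matrix shape {w.shape} != ({k}, {k})")
        if not np.allclose(w, w.T, equal_nan=True):
            raise NetworkError("weight matrix is not symmetric")
        if not np.allclose(np.diag(w), 0.0):
            raise NetworkError("diagonal must be zero")
        off = w[~np.eye(k, dtype=bool)]
        finite = off[np.isfinite(off)]
        if finite.size and (np.abs(finite) > 1 + 1e-12).any():
            raise NetworkError("edge weights must lie in [-1, 1]")
        object.__setattr__(self, "weights", w)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.items, columns=self.items)

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangle edges as (item_a, item_b, weight) rows; absent
        (zeroed/pruned) edges are omitted."""
        rows = []
        for i in range(self.n_items):
            for j in range(i + 1, self.n_items):
                w = self.weights[i, j]
                if w != 0:
                    rows.append((self.items[i], self.items[j], w))
        return pd.DataFrame(rows, columns=["item_a", "item_b", "weight"])


# ---------------------------------------------------------------------------
# Spearman edges
# ---------------------------------------------------------------------------


def spearman_edge(x, y, min_pairs: int = 3) -> float:
    """Spearman's rho (average ranks) on pairwise-complete observations.

    Raises :class:`NetworkError` when fewer than ``min_pairs`` complete
    pairs remain or either vector is constant over them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise NetworkError("paired samples must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < min_pairs:
        raise NetworkError(
            f"only {x.size} pairwise-complete pairs (< {min_pairs})"
        )
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise NetworkError("constant vector: Spearman edge undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def spearman_matrix(X: np.ndarray, min_pairs: int = 3) -> np.ndarray:
    """Full Spearman matrix of the columns of ``X`` (zero diagonal).

    Complete data takes a vectorised rank-then-Pearson path; any missing
    entries fall back to pairwise-complete edges.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if np.isfinite(X).all():
        if n < min_pairs:
            raise NetworkError(f"group size {n} < {min_pairs}")
        sd = X.std(axis=0)
        if (sd == 0).any():
            const = list(np.nonzero(sd == 0)[0])
            raise NetworkError(f"constant columns {const}: edges undefined")
        ranks = np.apply_along_axis(stats.rankdata, 0, X)
        C = np.corrcoef(ranks, rowvar=False)
        np.fill_diagonal(C, 0.0)
        return np.clip(C, -1.0, 1.0)
    C = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            C[i, j] = C[j, i] = spearman_edge(X[:, i], X[:, j], min_pairs)
    return C


def build_network(group, items: tuple[str, ...] | None = None) -> SymptomNetwork:
    """Groupwise symptom network: all pairwise Spearman edges.

    ``group`` is a patients x items DataFrame (or array with ``items``
    given); needs at least 3 patients.
    """
    if isinstance(group, pd.DataFrame):
        items = tuple(group.columns)
        X = group.to_numpy(dtype=float)
    else:
        X = np.asarray(group, dtype=float)
        if items is None:
            items = tuple(f"item_{i}" for i in range(X.shape[1]))
    if X.shape[0] < 3:
        raise NetworkError(f"group size {X.shape[0]} < 3")
    return SymptomNetwork(items=tuple(items), weights=spearman_matrix(X),
                          n_patients=X.shape[0])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def network_density(net: SymptomNetwork, absolute: bool = False) -> float:
    """Mean of the upper-triangle edge weights (signed by default)."""
    k = net.n_items
    iu = np.triu_indices(k, 1)
    w = net.weights[iu]
    if absolute:
        w = np.abs(w)
    return float(w.mean())


def node_strength(net: SymptomNetwork, item: str | None = None,
                  absolute: bool = False):
    """Sum of incident signed edge weights (weighted degree centrality).

    With ``item`` given, returns that node's strength; otherwise a Series
    over all nodes.
    """
    w = np.abs(net.weights) if absolute else net.weights
    s = pd.Series(w.sum(axis=1), index=net.items, name="strength")
    if item is None:
        return s
    if item not in net.items:
        raise NetworkError(f"unknown item {item!r}")
    return float(s[item])


def _laplacian_pinv(A: np.ndarray) -> np.ndarray:
    L = np.diag(A.sum(axis=1)) - A
    return np.linalg.pinv(L)


def current_flow_betweenness(weights: np.ndarray) -> np.ndarray:
    """Newman random-walk betweenness of every node, vectorised.

    ``weights`` may be signed; conductances are |weights|. For each
    source-target pair a unit current is injected and the half-sum of
    absolute edge currents through each intermediate node is accumulated;
    the node's own endpoint pairs are excluded and the total is divided by
    (n-1)(n-2)/2. Invariant under uniform scaling of all conductances.
    """
    A = np.abs(np.asarray(weights, dtype=float))
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    if n < 3:
        raise NetworkError("betweenness needs at least 3 nodes")
    off_diag = ~np.eye(n, dtype=bool)
    if not (A[off_diag] > 0).all():  # complete graphs skip the nx check
        G = nx.from_numpy_array(A)
        if not nx.is_connected(G):
            comps = [sorted(c) for c in nx.connected_components(G)]
            raise NetworkError(f"graph disconnected; components: {comps}")
    T = _laplacian_pinv(A)
    src, tgt = np.triu_indices(n, 1)  # all unordered pairs
    P = T[:, src] - T[:, tgt]  # potentials, shape (n, n_pairs)
    ei, ej = np.nonzero(np.triu(A, 1))
    a = A[ei, ej][:, None]
    flow = np.abs(P[ei, :] - P[ej, :]) * a  # |current| per edge per pair
    M = np.zeros_like(P)
    np.add.at(M, ei, 0.5 * flow)
    np.add.at(M, ej, 0.5 * flow)
    # a node is no intermediate of its own pairs
    M[src, np.arange(src.size)] = 0.0
    M[tgt, np.arange(tgt.size)] = 0.0
    norm = (n - 1) * (n - 2) / 2.0
    return M.sum(axis=1) / norm


def random_walk_betweenness(net: SymptomNetwork, item: str | None = None):
    """Normalised random-walk (current-flow) betweenness.

    With ``item`` given, returns that node's value; otherwise a Series.
    """
    b = pd.Series(current_flow_betweenness(net.weights), index=net.items,
                  name="rw_betweenness")
    if item is None:
        return b
    if item not in net.items:
        raise NetworkError(f"unknown item {item!r}")
    return float(b[item])


def prune_edges(net: SymptomNetwork, threshold: float = 0.2) -> SymptomNetwork:
    """Display-only copy with |weight| < threshold edges removed.

    The analysis matrix is never pruned; use the pruned copy only for
    export/plotting.
    """
    if not 0 <= threshold <= 1:
        raise NetworkError(f"threshold {threshold} outside [0, 1]")
    w = net.weights.copy()
    w[np.abs(w) < threshold] = 0.0
    return replace(net, weights=w)


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------


class SpearmanNetwork:
    """Estimate a symptom network from a patients x items sample.

    Parameters
    ----------
    absolute:
        Use |rho| instead of signed rho in density and strength
        (sensitivity variant; default off).

    Attributes (after :meth:`fit`)
    ------------------------------
    network_ : SymptomNetwork
    weights_ : (k, k) ndarray of Spearman edges
    density_ : float
    strengths_ : Series of node strengths
    rw_betweenness_ : Series of normalised current-flow betweenness
    """

    def __init__(self, absolute: bool = False):
        self.absolute = absolute

    def fit(self, X, y=None) -> "SpearmanNetwork":
        net = build_network(X)
        self.network_ = net
        self.items_ = net.items
        self.weights_ = net.weights
        self.density_ = network_density(net, absolute=self.absolute)
        self.strengths_ = node_strength(net, absolute=self.absolute)
        self.rw_betweenness_ = random_walk_betweenness(net)
        return self

    def get_params(self, deep: bool = True) -> dict:
        return {"absolute": self.absolute}

    def set_params(self, **params) -> "SpearmanNetwork":
        for k, v in params.items():
            if k != "absolute":
                raise ValueError(f"unknown parameter {k!r}")
            self.absolute = v
        return self


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------


def export_network(net: SymptomNetwork, fmt: str, path) -> None:
    """Write a network as ``matrix`` (CSV), ``edgelist`` (CSV) or
    ``graphml`` (weight attribute, full float precision)."""
    if fmt == "matrix":
        net.to_frame().to_csv(path, float_format="%.17g")
    elif fmt == "edgelist":
        net.edge_list().to_csv(path, index=False, float_format="%.17g")
    elif fmt == "graphml":
        G = nx.Graph(n_patients=int(net.n_patients))
        G.add_nodes_from(net.items)
        for i in range(net.n_items):
            for j in range(i + 1, net.n_items):
                w = net.weights[i, j]
                if w != 0:
                    G.add_edge(net.items[i], net.items[j], weight=float(w))
        nx.write_graphml(G, path)
    else:
        raise NetworkError(f"unknown export format {fmt!r}")


def read_network(fmt: str, path, n_patients: int = 0) -> SymptomNetwork:
    """Inverse of :func:`export_network` (absent edges read back as 0)."""
    if fmt == "matrix":
        df = pd.read_csv(path, index_col=0)
        return SymptomNetwork(tuple(df.index), df.to_numpy(float), n_patients)
    if fmt == "edgelist":
        df = pd.read_csv(path)
        items = sorted(set(df["item_a"]) | set(df["item_b"]))
        idx = {it: i for i, it in enumerate(items)}
        w = np.zeros((len(items), len(items)))
        for _, r in df.iterrows():
            i, j = idx[r["item_a"]], idx[r["item_b"]]
            w[i, j] = w[j, i] = r["weight"]
        return SymptomNetwork(tuple(items), w, n_patients)
    if fmt == "graphml":
        G = nx.read_graphml(path)
        items = tuple(G.nodes)
        idx = {it: i for i, it in enumerate(items)}
        w = np.zeros((len(items), len(items)))
        for u, v, d in G.edges(data=True):
            w[idx[u], idx[v]] = w[idx[v], idx[u]] = float(d["weight"])
        return SymptomNetwork(items, w, int(G.graph.get("n_patients", n_patients)))
    raise NetworkError(f"unknown format {fmt!r}")
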