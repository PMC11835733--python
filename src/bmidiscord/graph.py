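"""Binary-weighted nearest-neighbour graph over standardized residuals.

The number of neighbours scales with cohort size as
``nn = max(10, 10 + 15*(log10(N) - 4))`` (rounded to the nearest
integer).  The k-nearest-neighbour graph is computed with an exact search
(Euclidean metric on z-units), symmetrized by union, and every edge
weight is set to 1.  A 2-D embedding is available for inspection only;
no inference depends on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
from sklearn.neighbors import NearestNeighbors

from .discordance import ResidualMatrix


@dataclass
class ProximityGraph:
    """Undirected unit-weight kNN graph over individuals."""

    g: ig.Graph
    nn_used: int

    @property
    def n_nodes(self) -> int:
        return self.g.vcount()

    @property
    def edges(self) -> np.ndarray:
        return np.asarray(self.g.get_edgelist(), dtype=int)

    def write_edgelist(self, path) -> None:
        np.savetxt(path, self.edges, fmt="%d")

    @classmethod
    def read_edgelist(cls, path, n_nodes: int, nn_used: int = 0) -> "ProximityGraph":
        e = np.loadtxt(path, dtype=int, ndmin=2)
        g = ig.Graph(n=n_nodes, edges=[tuple(x) for x in e], directed=False)
        return cls(g=g, nn_used=nn_used)


def neighbor_count(n_total: int) -> int:
    """Cohort-size dependent neighbour count, floored at 10."""
    if n_total < 2:
        raise ValueError("need at least two individuals")
    return int(np.rint(max(10.0, 10.0 + 15.0 * (np.log10(n_total) - 4.0))))


def build_graph(residuals: ResidualMatrix | np.ndarray, nn: int | None = None,
                seed: int = 0) -> ProximityGraph:
    """Exact symmetric kNN graph with all edge weights equal to 1.

    Ties and duplicate rows (zero distance) are allowed.  ``seed`` is
    accepted for interface stability; the exact search is deterministic.
    """
    X = residuals.values if isinstance(residuals, ResidualMatrix) else np.asarray(residuals, float)
    n = X.shape[0]
    if nn is None:
        nn = neighbor_count(n)
    if nn >= n:
        raise ValueError(f"nn={nn} must be smaller than the number of nodes ({n})")
    nbrs = NearestNeighbors(n_neighbors=nn + 1).fit(X)
    _, idx = nbrs.kneighbors(X)
    src = np.repeat(np.arange(n), nn)
    dst = idx[:, 1:].ravel()  # drop self
    # union symmetrization: undirected simple graph
    pairs = np.sort(np.column_stack([src, dst]), axis=1)
    pairs = np.unique(pairs, axis=0)
    g = ig.Graph(n=n, edges=[tuple(p) for p in pairs], directed=False)
    g.es["weight"] = 1.0
    return ProximityGraph(g=g, nn_used=nn)


def embed_2d(graph: ProximityGraph, residuals: ResidualMatrix | np.ndarray,
             seed: int = 0, densmap: bool = False) -> np.ndarray:
    """2-D manifold projection of the residual space (figures only).

    Deterministic for a fixed seed.  Warns when the proximity graph has
    many connected components, which the layout places independently.
    """
    import umap  # deferred: numba compilation is slow

    X = residuals.values if isinstance(residuals, ResidualMatrix) else np.asarray(residuals, float)
    ncomp = len(graph.g.connected_components())
    if ncomp > 10:
        warnings.warn(f"proximity graph has {ncomp} connected components")
    reducer = umap.UMAP(n_neighbors=graph.nn_used, n_components=2,
                        random_state=seed, densmap=densmap)
    return np.asarray(reducer.fit_transform(X))
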