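"""Undirected conditional-independence graphs and pattern-constrained precision matrices.

A graph ``G`` over ``p`` variables encodes conditional dependence: an edge
(i, j) is present exactly when the precision-matrix entry ``k_ij`` is nonzero,
i.e. variables i and j are conditionally dependent given all the others.
Edge indices are 0-based positions in the variable dictionary, with i < j.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Tuple

import numpy as np

from .errors import NumericalError, ValidationError

Edge = Tuple[int, int]


def all_pairs(p: int) -> list[Edge]:
    """Unordered variable pairs (i, j), i < j, in row-major order."""
    return [(i, j) for i in range(p) for j in range(i + 1, p)]


@dataclass(frozen=True)
class Graph:
    """Simple undirected graph on p labelled nodes."""

    p: int
    edges: FrozenSet[Edge]

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if not (0 <= i < j < self.p):
                raise ValidationError(f"invalid edge ({i}, {j}) for p={self.p}")

    @classmethod
    def from_edges(cls, p: int, edges: Iterable[Edge]) -> "Graph":
        norm = frozenset((min(i, j), max(i, j)) for i, j in edges)
        return cls(p=p, edges=norm)

    @classmethod
    def empty(cls, p: int) -> "Graph":
        return cls(p=p, edges=frozenset())

    @classmethod
    def complete(cls, p: int) -> "Graph":
        return cls(p=p, edges=frozenset(all_pairs(p)))

    @classmethod
    def from_adjacency(cls, adj: np.ndarray) -> "Graph":
        adj = np.asarray(adj, dtype=bool)
        p = adj.shape[0]
        edges = frozenset((i, j) for i in range(p) for j in range(i + 1, p) if adj[i, j])
        return cls(p=p, edges=edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges

    def flip(self, i: int, j: int) -> "Graph":
        e = (min(i, j), max(i, j))
        if e in self.edges:
            return Graph(self.p, self.edges - {e})
        return Graph(self.p, self.edges | {e})

    def adjacency(self) -> np.ndarray:
        adj = np.zeros((self.p, self.p), dtype=bool)
        for i, j in self.edges:
            adj[i, j] = adj[j, i] = True
        return adj


def is_spd(matrix: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(matrix)
        return True
    except np.linalg.LinAlgError:
        return False


@dataclass
class PrecisionMatrix:
    """Symmetric positive-definite K whose zero pattern matches a graph."""

    values: np.ndarray
    graph: Graph

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        if K.shape != (self.graph.p, self.graph.p):
            raise ValidationError("precision matrix shape does not match graph")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValidationError("precision matrix must be symmetric")
        if not is_spd(K):
            raise NumericalError("precision matrix is not positive definite")
        adj = self.graph.adjacency()
        off = ~adj & ~np.eye(self.graph.p, dtype=bool)
        if np.any(np.abs(K[off]) > 1e-8):
            raise ValidationError("precision matrix has nonzero entries at non-edges")
        K = np.where(off, 0.0, K)
        self.values = 0.5 * (K + K.T)

    @property
    def p(self) -> int:
        return self.graph.p

    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.values)


def partial_correlations(K: np.ndarray) -> np.ndarray:
    """Partial correlations rho_ij = -k_ij / sqrt(k_ii k_jj), zero diagonal."""
    K = np.asarray(K, dtype=float)
    if not is_spd(K):
        raise NumericalError("partial correlations require an SPD precision matrix")
    d = np.sqrt(np.diag(K))
    rho = -K / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho
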