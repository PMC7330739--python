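"""Graph containers, Laplacian construction and second-eigenvalue machinery.

The algebraic connectivity (Fiedler value) of a graph — the second-smallest
eigenvalue of its Laplacian ``L = D - A`` — measures how well connected the
graph is: it is zero exactly when the graph is disconnected, and small when
the graph has a sparse cut.  Everything in this package (the sparsity penalty
during structure learning and the edge-pruning summarizer) is driven by how
much this eigenvalue moves when an edge is added or deleted.

Two Laplacian variants are provided:

``undirected``
    The combinatorial Laplacian ``L = D - A`` with weighted degrees.

``directed_chung``
    A symmetrized Laplacian for directed graphs built from the random-walk
    transition matrix.  Because a DAG's walk is never ergodic, the walk is
    smoothed with PageRank-style teleportation (uniform restart with
    probability ``1 - teleport``); the stationary distribution of the
    smoothed walk then defines the symmetrization
    ``L = I - (Phi^{1/2} P Phi^{-1/2} + Phi^{-1/2} P^T Phi^{1/2}) / 2``.
    This matrix is symmetric positive semidefinite with smallest eigenvalue
    exactly zero (eigenvector ``Phi^{1/2} 1``).

``directed_simple``
    ``(L + L^T)/2`` with ``L = D_total - A`` and ``D_total`` the diagonal of
    total (in + out) weighted degree.  A cruder alternative offered behind
    the same configuration switch.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "TOL",
    "Graph",
    "LaplacianConfig",
    "LaplacianMatrix",
    "SpectralSummary",
    "DeltaLambda2",
    "build_adjacency",
    "undirected_laplacian",
    "directed_laplacian",
    "simple_directed_laplacian",
    "graph_laplacian",
    "second_eigenvalue",
    "lambda2",
    "delta_lambda2",
    "parse_temporal_label",
    "temporal_label",
]

#: numerical tolerance for zero-eigenvalue decisions
TOL = 1e-9

_LABEL_RE = re.compile(r"^(?P<cond>.+)_Y(?P<year>\d+)$")


def parse_temporal_label(label: str) -> tuple[str, int]:
    """Parse a condition-year node label like ``"TBI_Y1"`` into ``("TBI", 1)``."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"node label {label!r} does not match '<COND>_Y<k>'")
    return m.group("cond"), int(m.group("year"))


def temporal_label(condition: str, year: int) -> str:
    return f"{condition}_Y{year}"


class Graph:
    """A finite (di)graph with non-negative edge weights.

    Nodes are identified by position ``0..n-1`` and carry string labels
    (for temporal networks the label is ``"<COND>_Y<k>"``).  Edges are
    ordered pairs ``(i, j)``; for an undirected graph the pair is stored
    canonically with ``i < j``.  Self-loops are rejected.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        edges: Iterable[tuple] = (),
        directed: bool = True,
    ) -> None:
        self.nodes: tuple[str, ...] = tuple(str(x) for x in nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node labels")
        self.directed = bool(directed)
        self._index: dict[str, int] = {lab: i for i, lab in enumerate(self.nodes)}
        self._edges: dict[tuple[int, int], float] = {}
        for e in edges:
            if len(e) == 2:
                i, j = e
                w = 1.0
            else:
                i, j, w = e
            self.add_edge(int(i), int(j), float(w))

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def index(self, label: str) -> int:
        return self._index[label]

    def _key(self, i: int, j: int) -> tuple[int, int]:
        if not (0 <= i < self.n and 0 <= j < self.n):
            raise ValueError(f"edge ({i},{j}) out of range for n={self.n}")
        if i == j:
            raise ValueError(f"self-loop ({i},{i}) is not allowed")
        if not self.directed and i > j:
            i, j = j, i
        return (i, j)

    def add_edge(self, i: int, j: int, weight: float = 1.0) -> None:
        key = self._key(i, j)
        if weight < 0:
            raise ValueError(f"negative weight {weight} on edge {key}")
        if key in self._edges:
            raise ValueError(f"duplicate edge {key}")
        self._edges[key] = float(weight)

    def remove_edge(self, i: int, j: int) -> None:
        key = self._key(i, j)
        if key not in self._edges:
            raise ValueError(f"edge {key} not in graph")
        del self._edges[key]

    def has_edge(self, i: int, j: int) -> bool:
        try:
            return self._key(i, j) in self._edges
        except ValueError:
            return False

    def weight(self, i: int, j: int) -> float:
        return self._edges[self._key(i, j)]

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Edges as ``(i, j, weight)`` sorted by ``(i, j)`` — deterministic."""
        return [(i, j, w) for (i, j), w in sorted(self._edges.items())]

    def edge_keys(self) -> list[tuple[int, int]]:
        return sorted(self._edges)

    def copy(self) -> "Graph":
        g = Graph(self.nodes, directed=self.directed)
        g._edges = dict(self._edges)
        return g

    def without_edge(self, i: int, j: int) -> "Graph":
        g = self.copy()
        g.remove_edge(i, j)
        return g

    def with_edge(self, i: int, j: int, weight: float = 1.0) -> "Graph":
        g = self.copy()
        g.add_edge(i, j, weight)
        return g

    # -- structure queries -------------------------------------------------
    def parents(self, j: int) -> list[int]:
        if not self.directed:
            raise ValueError("parents() is defined for directed graphs")
        return sorted(i for (i, k) in self._edges if k == j)

    def children(self, i: int) -> list[int]:
        if not self.directed:
            raise ValueError("children() is defined for directed graphs")
        return sorted(k for (p, k) in self._edges if p == i)

    def undirected_neighbors(self, i: int) -> list[int]:
        """Neighbors in the undirected view, ascending index."""
        nb = set()
        for (a, b) in self._edges:
            if a == i:
                nb.add(b)
            elif b == i:
                nb.add(a)
        return sorted(nb)

    def topological_order(self) -> list[int]:
        """Topological order of a directed acyclic graph (Kahn; index tie-break)."""
        if not self.directed:
            raise ValueError("topological order requires a directed graph")
        indeg = [0] * self.n
        for (_, j) in self._edges:
            indeg[j] += 1
        import heapq

        ready = [i for i in range(self.n) if indeg[i] == 0]
        heapq.heapify(ready)
        order: list[int] = []
        while ready:
            i = heapq.heappop(ready)
            order.append(i)
            for j in self.children(i):
                indeg[j] -= 1
                if indeg[j] == 0:
                    heapq.heappush(ready, j)
        if len(order) != self.n:
            raise ValueError("graph contains a directed cycle")
        return order

    def is_dag(self) -> bool:
        try:
            self.topological_order()
            return True
        except ValueError:
            return False

    def connected_components(self) -> list[set[int]]:
        """Weakly connected components of the undirected view."""
        seen: set[int] = set()
        comps = []
        for s in range(self.n):
            if s in seen:
                continue
            comp = {s}
            stack = [s]
            while stack:
                u = stack.pop()
                for v in self.undirected_neighbors(u):
                    if v not in comp:
                        comp.add(v)
                        stack.append(v)
            seen |= comp
            comps.append(comp)
        return comps

    # -- interop -----------------------------------------------------------
    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        for i, j, w in self.edge_list():
            g.add_edge(self.nodes[i], self.nodes[j], weight=w)
        return g

    @classmethod
    def from_networkx(cls, g) -> "Graph":
        nodes = list(g.nodes())
        idx = {lab: i for i, lab in enumerate(nodes)}
        edges = [
            (idx[u], idx[v], float(d.get("weight", 1.0)))
            for u, v, d in g.edges(data=True)
        ]
        return cls(nodes, edges, directed=g.is_directed())

    def __repr__(self) -> str:  # pragma: no cover
        kind = "DiGraph" if self.directed else "Graph"
        return f"<eagl.{kind} n={self.n} edges={self.n_edges}>"


@dataclass(frozen=True)
class LaplacianConfig:
    """How to turn a graph into a Laplacian.

    variant
        ``"auto"`` picks ``undirected`` for undirected graphs and
        ``directed_chung`` for directed ones.
    teleport
        Restart weight of the smoothed random walk in ``(0, 1]``;
        ``1.0`` disables teleportation.
    """

    variant: str = "auto"
    teleport: float = 0.85
    tol: float = TOL

    def resolve(self, directed: bool) -> str:
        if self.variant != "auto":
            return self.variant
        return "directed_chung" if directed else "undirected"


@dataclass
class LaplacianMatrix:
    values: np.ndarray
    variant: str
    teleport: float | None = None


@dataclass
class SpectralSummary:
    """Ascending Laplacian spectrum; ``lambda2`` is the algebraic connectivity."""

    eigenvalues: np.ndarray
    lambda2: float
    tol: float = TOL


@dataclass
class DeltaLambda2:
    """Change in the second eigenvalue caused by deleting one edge.

    ``relative`` is True when the value is |Δλ₂|/λ₂ of the intact graph;
    when the intact graph already has λ₂ ≤ tol the absolute change is
    reported instead and the record is flagged (``relative=False``).
    """

    value: float
    relative: bool

    def __float__(self) -> float:
        return self.value


def build_adjacency(graph: Graph) -> np.ndarray:
    """Adjacency matrix with entry ``(i, j)`` the weight of edge ``i -> j``.

    Undirected edges are stored symmetrically.
    """
    A = np.zeros((graph.n, graph.n))
    for i, j, w in graph.edge_list():
        A[i, j] = w
        if not graph.directed:
            A[j, i] = w
    return A


def undirected_laplacian(A: np.ndarray) -> LaplacianMatrix:
    """Combinatorial Laplacian ``L = D - A`` of a symmetric adjacency matrix."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.allclose(A, A.T, atol=TOL):
        raise ValueError("undirected Laplacian requires a symmetric adjacency matrix")
    D = np.diag(A.sum(axis=1))
    return LaplacianMatrix(D - A, variant="undirected")


def _stationary(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix.

    Direct solve for n <= 200 (augmented least squares), power iteration
    beyond that.
    """
    n = P.shape[0]
    if n <= 200:
        M = np.vstack([P.T - np.eye(n), np.ones((1, n))])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        phi, *_ = np.linalg.lstsq(M, b, rcond=None)
    else:  # pragma: no cover - large graphs are a non-goal
        phi = np.full(n, 1.0 / n)
        for _ in range(100_000):
            nxt = phi @ P
            if np.abs(nxt - phi).max() < 1e-12:
                phi = nxt
                break
            phi = nxt
    phi = np.clip(phi, 0.0, None)
    return phi / phi.sum()


def directed_laplacian(A: np.ndarray, teleport: float = 0.85) -> LaplacianMatrix:
    """Symmetrized random-walk Laplacian of a directed graph.

    The transition matrix ``P`` row-normalizes ``A`` (rows with no
    out-edges become uniform), is smoothed to
    ``P' = teleport * P + (1 - teleport)/n`` to make the walk ergodic, and
    the stationary distribution ``Phi`` of ``P'`` symmetrizes it:
    ``L = I - (Phi^{1/2} P' Phi^{-1/2} + Phi^{-1/2} P'^T Phi^{1/2}) / 2``.
    ``L`` is symmetric PSD and ``L @ sqrt(Phi) = 0``, so the smallest
    eigenvalue is exactly zero.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if n == 0:
        raise ValueError("directed Laplacian of an empty graph is undefined")
    if not (0.0 < teleport <= 1.0):
        raise ValueError(f"teleport must be in (0, 1], got {teleport}")
    rowsum = A.sum(axis=1)
    P = np.full((n, n), 1.0 / n)
    nz = rowsum > 0
    P[nz] = A[nz] / rowsum[nz, None]
    P = teleport * P + (1.0 - teleport) / n
    phi = _stationary(P)
    # guard against exact zeros in reducible chains at teleport=1
    phi = np.clip(phi, 1e-300, None)
    s = np.sqrt(phi)
    M = (s[:, None] * P / s[None, :] + (P.T * s[None, :]) / s[:, None]) / 2.0
    L = np.eye(n) - M
    L = (L + L.T) / 2.0
    return LaplacianMatrix(L, variant="directed_chung", teleport=teleport)


def simple_directed_laplacian(A: np.ndarray) -> LaplacianMatrix:
    """Symmetrized ``D_total - A`` with total (in + out) weighted degree."""
    A = np.asarray(A, dtype=float)
    D = np.diag(A.sum(axis=1) + A.sum(axis=0))
    L = D - A
    return LaplacianMatrix((L + L.T) / 2.0, variant="directed_simple")


def graph_laplacian(graph: Graph, config: LaplacianConfig | None = None) -> LaplacianMatrix:
    """Laplacian of a :class:`Graph` under a :class:`LaplacianConfig`."""
    config = config or LaplacianConfig()
    variant = config.resolve(graph.directed)
    A = build_adjacency(graph)
    if variant == "undirected":
        if graph.directed:
            # undirected view of a directed graph: symmetrize the adjacency
            A = np.maximum(A, A.T)
        return undirected_laplacian(A)
    if variant == "directed_chung":
        return directed_laplacian(A, teleport=config.teleport)
    if variant == "directed_simple":
        return simple_directed_laplacian(A)
    raise ValueError(f"unknown Laplacian variant {variant!r}")


def second_eigenvalue(L: LaplacianMatrix | np.ndarray, tol: float = TOL) -> SpectralSummary:
    """Full ascending spectrum of a symmetric Laplacian; λ₂ is the second entry."""
    vals = L.values if isinstance(L, LaplacianMatrix) else np.asarray(L, dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("Laplacian must be a square matrix")
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise ValueError("second_eigenvalue requires a symmetric matrix")
    if vals.shape[0] < 2:
        raise ValueError("need at least two nodes for a second eigenvalue")
    ev = scipy.linalg.eigvalsh(vals)
    ev[(ev < 0) & (ev >= -tol)] = 0.0
    return SpectralSummary(eigenvalues=ev, lambda2=float(ev[1]), tol=tol)


def lambda2(graph: Graph, config: LaplacianConfig | None = None) -> float:
    """Convenience: λ₂ of the configured Laplacian of ``graph``."""
    return second_eigenvalue(graph_laplacian(graph, config)).lambda2


def delta_lambda2(
    graph: Graph,
    edge: tuple[int, int],
    config: LaplacianConfig | None = None,
) -> DeltaLambda2:
    """Spectral impact of deleting ``edge``: relative |Δλ₂|/λ₂ of the intact
    graph, or the absolute change (flagged) when λ₂ of the intact graph is
    numerically zero.  Pure: ``graph`` is not modified."""
    config = config or LaplacianConfig()
    i, j = edge
    if not graph.has_edge(i, j):
        raise ValueError(f"edge ({i},{j}) not present in graph")
    lam_full = lambda2(graph, config)
    lam_rm = lambda2(graph.without_edge(i, j), config)
    diff = abs(lam_full - lam_rm)
    if lam_full > config.tol:
        return DeltaLambda2(value=diff / lam_full, relative=True)
    return DeltaLambda2(value=diff, relative=False)
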