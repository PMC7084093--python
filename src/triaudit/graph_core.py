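"""Simple undirected graphs, SNAP-dialect edge-list I/O, and triangle-foundation statistics.

A graph has a (c, Δ)-triangle foundation when at least Δ·n triangles lie
entirely among vertices of degree at most c, where n is the *total* vertex
count of the graph (not the size of the retained set).  Sparse real-world
networks typically have Δ > 1 for modest c; graphs sampled from low-rank
dot-product models of the same networks do not, and the Δ(c) curve computed
here is the instrument that exposes the gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class EdgeListFormatError(ValueError):
    """Raised when an edge-list file cannot be parsed; names the offending line."""


@dataclass
class UndirectedGraph:
    """Simple undirected graph on vertices 0..n-1.

    ``edges`` holds each unordered pair once as ``(u, v)`` with ``u < v``;
    self-loops and multi-edges are disallowed.  ``labels`` optionally maps
    original external IDs to internal indices (kept so written edge lists
    round-trip through :func:`read_edge_list`).
    """

    n: int
    edges: set[tuple[int, int]] = field(default_factory=set)
    labels: dict[int, int] | None = None

    def __post_init__(self) -> None:
        self.edges = {(min(u, v), max(u, v)) for (u, v) in self.edges}
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop ({u},{u}) not allowed")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValueError(f"edge ({u},{v}) out of range for n={self.n}")

    @property
    def m(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def adjacency_sets(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n)]
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix."""
        a = np.zeros((self.n, self.n))
        for u, v in self.edges:
            a[u, v] = a[v, u] = 1.0
        return a

    def has_edge(self, u: int, v: int) -> bool:
        return (min(u, v), max(u, v)) in self.edges

    def inverse_labels(self) -> dict[int, int]:
        """Internal index -> original ID (identity when no label map)."""
        if self.labels is None:
            return {i: i for i in range(self.n)}
        return {v: k for k, v in self.labels.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UndirectedGraph):
            return NotImplemented
        return self.n == other.n and self.edges == other.edges


@dataclass
class DegreeTriangleCurve:
    """Triangle retention curve: for each degree threshold c, the count T(c) of
    triangles induced by the vertices of full-graph degree ≤ c, and the density
    Δ(c) = T(c)/n with n the source graph's total vertex count."""

    thresholds: np.ndarray
    triangle_counts: np.ndarray
    n: int

    @property
    def deltas(self) -> np.ndarray:
        if self.n == 0:
            return np.zeros_like(self.triangle_counts, dtype=float)
        return self.triangle_counts / self.n

    def delta_at(self, c: float) -> float:
        """Δ evaluated at arbitrary c by step-function extension: 0 below the
        smallest threshold, the total-triangle density above the largest."""
        if len(self.thresholds) == 0 or c < self.thresholds[0]:
            return 0.0
        idx = int(np.searchsorted(self.thresholds, c, side="right")) - 1
        return float(self.deltas[idx])

    def triangles_at(self, c: float) -> int:
        if len(self.thresholds) == 0 or c < self.thresholds[0]:
            return 0
        idx = int(np.searchsorted(self.thresholds, c, side="right")) - 1
        return int(self.triangle_counts[idx])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("c\tT\tdelta\n")
            for c, t, d in zip(self.thresholds, self.triangle_counts, self.deltas):
                fh.write(f"{int(c)}\t{int(t)}\t{d:.10g}\n")


def read_edge_list(
    path: str | Path,
    *,
    comment: str = "#",
    n_vertices: int | None = None,
) -> UndirectedGraph:
    """Read a whitespace-delimited edge list (SNAP dialect).

    Lines starting with ``comment`` are ignored; each remaining line must have
    at least two integer tokens (extra columns such as weights are ignored).
    Self-loops are dropped, duplicate and reversed-duplicate edges merged, and
    vertex IDs compacted to 0..n-1 in order of first appearance, with the
    original IDs retained in ``labels``.  ``n_vertices`` forces the vertex
    count (the only way isolated vertices are representable); otherwise n is
    the number of distinct endpoint IDs.
    """
    path = Path(path)
    raw_edges: set[tuple[int, int]] = set()
    seen_ids: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(comment):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: expected at least 2 tokens, got {len(tokens)}"
                )
            try:
                a, b = int(tokens[0]), int(tokens[1])
            except ValueError as exc:
                raise EdgeListFormatError(f"{path}:{lineno}: {exc}") from None
            seen_ids.update((a, b))
            if a == b:
                continue
            raw_edges.add((min(a, b), max(a, b)))
    # compact in sorted original-ID order: identity when IDs are already 0..n-1
    labels = {orig: idx for idx, orig in enumerate(sorted(seen_ids))}
    edges = {
        (labels[a], labels[b]) if labels[a] < labels[b] else (labels[b], labels[a])
        for a, b in raw_edges
    }
    n = len(labels)
    if n_vertices is not None:
        if n_vertices < n:
            raise EdgeListFormatError(
                f"{path}: n_vertices={n_vertices} smaller than {n} observed endpoints"
            )
        n = n_vertices
    return UndirectedGraph(n=n, edges=edges, labels=labels)


def write_edge_list(graph: UndirectedGraph, path: str | Path) -> None:
    """Write one "u v" line per edge, u < v in original labels when present."""
    inv = graph.inverse_labels()
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges):
            a, b = inv[u], inv[v]
            if a > b:
                a, b = b, a
            fh.write(f"{a} {b}\n")


def count_triangles(graph: UndirectedGraph) -> int:
    """Exact triangle count by degree-ordered neighbor intersection.

    Vertices are ranked by (degree, index); each edge is oriented toward the
    higher rank and each triangle counted exactly once at its highest-ranked
    vertex.  Work is O(m^{3/2}) on sparse graphs.
    """
    deg = graph.degrees()
    rank = {v: r for r, v in enumerate(sorted(range(graph.n), key=lambda v: (deg[v], v)))}
    fwd: list[set[int]] = [set() for _ in range(graph.n)]  # neighbors of higher rank
    for u, v in graph.edges:
        if rank[u] < rank[v]:
            fwd[u].add(v)
        else:
            fwd[v].add(u)
    count = 0
    for u in range(graph.n):
        fu = fwd[u]
        for v in fu:
            count += len(fu & fwd[v])
    return count


def _induced_subgraph(graph: UndirectedGraph, keep: Iterable[int]) -> UndirectedGraph:
    keep_set = set(keep)
    remap = {v: i for i, v in enumerate(sorted(keep_set))}
    edges = {
        (remap[u], remap[v])
        for u, v in graph.edges
        if u in keep_set and v in keep_set
    }
    return UndirectedGraph(n=len(keep_set), edges=edges)


def triangle_foundation(graph: UndirectedGraph, c: int) -> tuple[int, float]:
    """(T, Δ) at threshold c: T = triangles induced by S_c = {v : deg(v) ≤ c},
    degrees measured in the full graph; Δ = T/n with n the full vertex count."""
    if c < 0:
        raise ValueError(f"degree threshold must be >= 0, got {c}")
    if graph.n == 0:
        return 0, 0.0
    deg = graph.degrees()
    keep = [v for v in range(graph.n) if deg[v] <= c]
    t = count_triangles(_induced_subgraph(graph, keep))
    return t, t / graph.n


def degree_triangle_curve(graph: UndirectedGraph) -> DegreeTriangleCurve:
    """Δ(c) curve at every distinct degree value, in one pass.

    Vertices are inserted in nondecreasing (degree, index) order; a triangle is
    charged to its last-inserted vertex, found by intersecting that vertex's
    earlier-inserted neighbors.  The cumulative count after the last vertex of
    degree value c equals triangle_foundation(graph, c) pointwise, because
    S_c is exactly a prefix of the insertion order.
    """
    if graph.n == 0:
        return DegreeTriangleCurve(np.array([], dtype=np.int64), np.array([], dtype=np.int64), 0)
    deg = graph.degrees()
    order = sorted(range(graph.n), key=lambda v: (deg[v], v))
    adj = graph.adjacency_sets()
    inserted: set[int] = set()
    thresholds: list[int] = []
    counts: list[int] = []
    running = 0
    for pos, v in enumerate(order):
        earlier = adj[v] & inserted
        # triangles closed by v = adjacent pairs among its earlier neighbors;
        # each such pair (u, w) is seen from both endpoints, hence the halving
        closed2 = sum(len(adj[u] & earlier) for u in earlier)
        running += closed2 // 2
        inserted.add(v)
        last_of_value = pos == graph.n - 1 or deg[order[pos + 1]] != deg[v]
        if last_of_value:
            thresholds.append(int(deg[v]))
            counts.append(running)
    return DegreeTriangleCurve(
        thresholds=np.array(thresholds, dtype=np.int64),
        triangle_counts=np.array(counts, dtype=np.int64),
        n=graph.n,
    )
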