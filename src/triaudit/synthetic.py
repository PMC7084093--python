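"""Synthetic graphs and latent-vector families with known triangle foundations.

Real triangle-rich sparse networks (social graphs, protein-protein
interaction networks) combine low average degree with many triangles on
low-degree vertices.  The generators here realize that regime exactly or in
expectation, with machine-checkable ground truth, so the whole audit pipeline
is testable without external datasets.  The canonical extremal witness is m
disjoint triangles: n = 3m vertices, every degree 2, and Δ(2) = 1/3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np

from .embed import SignedEmbedding
from .graph_core import UndirectedGraph, write_edge_list


@dataclass
class FixtureSpec:
    """Generator provenance plus ground truth for the generated object."""

    generator: str
    parameters: dict
    ground_truth: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "generator": self.generator,
                    "parameters": self.parameters,
                    "ground_truth": self.ground_truth,
                },
                fh,
                indent=2,
            )

    def write_with_graph(self, graph: UndirectedGraph, edge_path: str | Path) -> None:
        """Write the edge list with a JSON sidecar describing its provenance."""
        edge_path = Path(edge_path)
        write_edge_list(graph, edge_path)
        self.to_json(edge_path.with_suffix(edge_path.suffix + ".fixture.json"))


def disjoint_cliques(m: int, k: int) -> tuple[UndirectedGraph, FixtureSpec]:
    """m vertex-disjoint k-cliques: n = m·k, every degree k−1,
    m·C(k,3) triangles, and Δ(k−1) = C(k,3)/k."""
    if m < 1:
        raise ValueError(f"need at least one clique (got m={m})")
    if k < 3:
        raise ValueError(f"clique size must be >= 3 to contain triangles (got k={k})")
    edges = {
        (c * k + a, c * k + b)
        for c in range(m)
        for a in range(k)
        for b in range(a + 1, k)
    }
    graph = UndirectedGraph(n=m * k, edges=edges)
    spec = FixtureSpec(
        generator="disjoint_cliques",
        parameters={"m": m, "k": k},
        ground_truth={
            "n": m * k,
            "degree": k - 1,
            "triangles": m * comb(k, 3),
            "c": k - 1,
            "delta": comb(k, 3) / k,
        },
    )
    return graph, spec


def planted_triangle_graph(
    n: int, base_p: float, planted: int, seed: int
) -> tuple[UndirectedGraph, FixtureSpec]:
    """Erdős–Rényi G(n, base_p) unioned with ``planted`` vertex-disjoint
    triangles on randomly chosen distinct vertices.

    The planted count is an exact lower bound on the total triangle count
    (the random part can only add), and vertex-disjointness keeps the degree
    impact at +2 per planted vertex.
    """
    if planted < 0 or 3 * planted > n:
        raise ValueError(f"need 3·planted <= n (got planted={planted}, n={n})")
    if not (0.0 <= base_p <= 1.0):
        raise ValueError(f"base_p must be a probability (got {base_p})")
    rng = np.random.default_rng(seed)
    edges: set[tuple[int, int]] = set()
    if base_p > 0:
        for i in range(n - 1):
            hits = np.nonzero(rng.random(n - i - 1) < base_p)[0]
            edges.update((i, int(i + 1 + j)) for j in hits)
    chosen = rng.permutation(n)[: 3 * planted]
    for t in range(planted):
        a, b, c = sorted(int(v) for v in chosen[3 * t : 3 * t + 3])
        edges.update({(a, b), (a, c), (b, c)})
    graph = UndirectedGraph(n=n, edges=edges)
    spec = FixtureSpec(
        generator="planted_triangle_graph",
        parameters={"n": n, "base_p": base_p, "planted": planted, "seed": seed},
        ground_truth={"min_triangles": planted},
    )
    return graph, spec


def rdpg_vectors(
    n: int, d: int, style: str = "clustered", seed: int = 0, clusters: int = 2
) -> tuple[SignedEmbedding, FixtureSpec]:
    """Latent vectors for a random dot product graph with all pair scores in
    [0, 1], so the truncated dot product equals the raw dot product.

    ``clustered``: vectors sit near one of ``clusters`` orthogonal centroids
    with within-cluster dots ≈ 0.9 and cross-cluster dots ≈ 0 — a stochastic
    block model in latent-position form.  ``spherical``: unit-norm vectors
    with nonnegative coordinates drawn uniformly on the positive orthant.
    """
    if d < 1:
        raise ValueError(f"dimension must be >= 1 (got {d})")
    if style not in ("clustered", "spherical"):
        raise ValueError(f"unknown style {style!r}")
    rng = np.random.default_rng(seed)
    if style == "spherical":
        coords = np.abs(rng.standard_normal((n, d)))
        coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    else:
        k = min(clusters, d)
        centroids = np.zeros((k, d))
        for c in range(k):
            centroids[c, c] = np.sqrt(0.9)  # self-dot 0.9, cross-dot 0
        assign = rng.integers(0, k, size=n)
        jitter = 0.01 * np.abs(rng.standard_normal((n, d)))
        coords = centroids[assign] + jitter
        # rescale any row whose worst-case pair score could leave [0, 1]
        norms = np.linalg.norm(coords, axis=1)
        coords[norms > 1.0] /= norms[norms > 1.0, None]
    emb = SignedEmbedding(coords=coords, signature=np.ones(d))
    spec = FixtureSpec(
        generator="rdpg_vectors",
        parameters={"n": n, "d": d, "style": style, "seed": seed, "clusters": clusters},
        ground_truth={"scores_in_unit_interval": True},
    )
    return emb, spec
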