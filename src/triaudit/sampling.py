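"""Bernoulli graph sampling from edge-probability models and the replicate audit.

Each unordered pair (i, j) becomes an edge independently with probability
p(i, j).  The audit draws many replicates and reports, at every degree
threshold, the *maximum* triangle density Δ seen across replicates — a
deliberately generous summary for the model under audit: if even the best of
100 samples retains orders of magnitude less low-degree triangle mass than
the original graph, statistical variation is not the explanation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .edge_models import EdgeProbabilityModel
from .graph_core import DegreeTriangleCurve, UndirectedGraph, degree_triangle_curve


@dataclass
class SampleSummary:
    """Replicate audit result: per-replicate Δ(c) curves, their pointwise
    maximum on the merged threshold grid, and sampled edge-count statistics."""

    replicates: int
    seed: int
    per_replicate_curves: list[DegreeTriangleCurve]
    max_curve: DegreeTriangleCurve
    edge_counts: list[int]

    @property
    def edge_count_stats(self) -> dict[str, float]:
        arr = np.asarray(self.edge_counts, dtype=float)
        return {"mean": float(arr.mean()), "min": float(arr.min()), "max": float(arr.max())}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("c\tT_max\tdelta_max\n")
            for c, t, d in zip(
                self.max_curve.thresholds,
                self.max_curve.triangle_counts,
                self.max_curve.deltas,
            ):
                fh.write(f"{int(c)}\t{int(t)}\t{d:.10g}\n")


def _replicate_seed_seq(base_seed: int, replicate: int) -> np.random.SeedSequence:
    # counter-based derivation: replicate r is independent of how many
    # replicates run and of execution order
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(replicate,))


def sample_graph(
    model: EdgeProbabilityModel,
    seed: int | np.random.SeedSequence,
) -> UndirectedGraph:
    """One Bernoulli draw: edge (i, j), i<j, present with probability p(i, j).

    Deterministic given (model, seed): uniforms are drawn row by row in vertex
    order regardless of block size.
    """
    rng = np.random.default_rng(seed)
    n = model.n
    edges: set[tuple[int, int]] = set()
    for rows, p in model.iter_blocks():
        for r, i in enumerate(rows):
            if i + 1 >= n:
                continue
            u = rng.random(n - i - 1)
            hits = np.nonzero(u < p[r, i + 1 :])[0]
            for j in hits:
                edges.add((int(i), int(i + 1 + j)))
    return UndirectedGraph(n=n, edges=edges)


def replicate_audit(
    model: EdgeProbabilityModel,
    replicates: int,
    seed: int,
) -> SampleSummary:
    """Sample ``replicates`` graphs and aggregate their Δ(c) curves.

    The max curve lives on the union of all replicate thresholds; each curve
    is evaluated on that grid by step-function extension (0 below its smallest
    threshold, its total-triangle density above its largest).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    curves: list[DegreeTriangleCurve] = []
    edge_counts: list[int] = []
    for r in range(replicates):
        g = sample_graph(model, _replicate_seed_seq(seed, r))
        edge_counts.append(g.m)
        curves.append(degree_triangle_curve(g))
    merged = np.unique(np.concatenate([c.thresholds for c in curves if len(c.thresholds)] or [np.array([], dtype=np.int64)]))
    t_max = np.zeros(len(merged), dtype=np.int64)
    for curve in curves:
        t_max = np.maximum(t_max, np.array([curve.triangles_at(c) for c in merged], dtype=np.int64))
    max_curve = DegreeTriangleCurve(thresholds=merged, triangle_counts=t_max, n=model.n)
    return SampleSummary(
        replicates=replicates,
        seed=seed,
        per_replicate_curves=curves,
        max_curve=max_curve,
        edge_counts=edge_counts,
    )
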