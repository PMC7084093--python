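"""Dot-product edge-probability models and their calibration.

Four symmetric pairwise edge-probability constructions over a vertex
embedding, all with zero diagonal and values in [0, 1]:

TDP (truncated dot product)
    p(i,j) = max(0, min(score(i,j), 1)).  The canonical random dot product
    graph rule; no free parameters.

LRDP (logistic regression on the dot product)
    p(i,j) = L · sigmoid(k·(score(i,j) − x0)).  (k, x0) are fit by logistic
    regression of observed edges against uniformly sampled non-edges; the
    ceiling L ∈ (0,1] is then calibrated by bisection so the model's expected
    edge count matches the observed count.

LRHP (logistic regression on the Hadamard product)
    p(i,j) = L · sigmoid(w·f(i,j) + b) with the signed elementwise feature
    f(i,j)[r] = signature[r]·x_ir·x_jr, whose coordinate sum is score(i,j); a
    richer linear model that specializes to LRDP when all weights are tied.

Softmax (degree-matched)
    directed mass q(i→j) = deg(i)·exp(score(i,j)) / Σ_{k≠i} exp(score(i,k)),
    whose rows sum to the true degrees exactly; the undirected probability is
    the symmetrized, clamped average (q(i→j)+q(j→i))/2.

Probabilities are evaluated in row blocks, never as a dense n×n matrix, so
models scale to graphs where n² floats would not fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from sklearn.linear_model import LogisticRegression

from .embed import SignedEmbedding
from .graph_core import UndirectedGraph

_BLOCK = 2048


class CalibrationError(RuntimeError):
    """Calibration failed to reach tolerance; carries the best residual seen."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (best relative residual {residual:.3g})")
        self.residual = residual


@dataclass
class EdgeProbabilityModel:
    """Symmetric pairwise edge-probability function p(i,j) ∈ [0,1], p(i,i)=0."""

    variant: str  # TDP | LRDP | LRHP | SOFTMAX
    emb: SignedEmbedding
    params: dict

    @property
    def n(self) -> int:
        return self.emb.n

    def prob_block(self, rows: np.ndarray | list[int]) -> np.ndarray:
        """Probabilities p(i, j) for i in ``rows``, all j (len(rows) × n),
        with the diagonal entries zeroed."""
        rows = np.asarray(rows)
        if self.variant == "TDP":
            p = np.clip(self.emb.score_block(rows), 0.0, 1.0)
        elif self.variant == "LRDP":
            s = self.emb.score_block(rows)
            L, k, x0 = self.params["L"], self.params["k"], self.params["x0"]
            p = L * _sigmoid(k * (s - x0))
        elif self.variant == "LRHP":
            w = np.asarray(self.params["w"])
            b, L = self.params["b"], self.params["L"]
            # w·f(i,j) = Σ_r w_r·sig_r·x_ir·x_jr = (x_i ∘ sig ∘ w)·x_j
            z = (self.emb.coords[rows] * self.emb.signature * w) @ self.emb.coords.T + b
            p = L * _sigmoid(z)
        elif self.variant == "SOFTMAX":
            p = self._softmax_block(rows)
        else:
            raise ValueError(f"unknown variant {self.variant!r}")
        for r, i in enumerate(rows):
            p[r, i] = 0.0
        return p

    def _directed_softmax_block(self, rows: np.ndarray) -> np.ndarray:
        """q(i→j) for i in rows; rows sum exactly to deg(i) before clamping."""
        deg = np.asarray(self.params["degrees"], dtype=float)
        shift = np.asarray(self.params["shift"])  # per-vertex max-subtraction
        logz = np.asarray(self.params["logz"])
        s = self.emb.score_block(rows)
        q = np.exp(s - shift[rows, None] - logz[rows, None]) * deg[rows, None]
        for r, i in enumerate(rows):
            q[r, i] = 0.0
        return q

    def _softmax_block(self, rows: np.ndarray) -> np.ndarray:
        deg = np.asarray(self.params["degrees"], dtype=float)
        shift = np.asarray(self.params["shift"])
        logz = np.asarray(self.params["logz"])
        s = self.emb.score_block(rows)
        q_fwd = np.exp(s - shift[rows, None] - logz[rows, None]) * deg[rows, None]
        q_bwd = np.exp(s - shift[None, :] - logz[None, :]) * deg[None, :]
        return np.clip(0.5 * (q_fwd + q_bwd), 0.0, 1.0)

    def prob(self, i: int, j: int) -> float:
        if not (0 <= i < self.n and 0 <= j < self.n):
            raise IndexError(f"vertex index out of range: ({i},{j})")
        return float(self.prob_block([i])[0, j])

    def iter_blocks(self, block: int = _BLOCK) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        for start in range(0, self.n, block):
            rows = np.arange(start, min(start + block, self.n))
            yield rows, self.prob_block(rows)

    def to_json_dict(self) -> dict:
        params = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.params.items()
        }
        return {"variant": self.variant, "n": self.n, "d": self.emb.d, "params": params}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def tdp_model(emb: SignedEmbedding) -> EdgeProbabilityModel:
    """Truncated dot product: p = clamp(score, 0, 1); scores ≥ 1 are certain
    edges, negative scores are never edges."""
    return EdgeProbabilityModel(variant="TDP", emb=emb, params={})


def edge_probability(model: EdgeProbabilityModel, i: int, j: int) -> float:
    if i == j:
        raise IndexError("edge probability undefined on the diagonal")
    return model.prob(i, j)


def expected_degrees(model: EdgeProbabilityModel) -> tuple[np.ndarray, float]:
    """Per-vertex expected degrees E[D_i] = Σ_{j≠i} p(i,j) and the expected
    edge count ½·Σ_i E[D_i], computed blockwise."""
    exp_deg = np.zeros(model.n)
    for rows, p in model.iter_blocks():
        exp_deg[rows] = p.sum(axis=1)
    return exp_deg, 0.5 * float(exp_deg.sum())


def _expected_edge_count(model: EdgeProbabilityModel) -> float:
    return expected_degrees(model)[1]


def _sample_nonedges(
    graph: UndirectedGraph, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly sampled (with replacement) non-adjacent pairs i<j, as a
    (count, 2) array."""
    n = graph.n
    total_pairs = n * (n - 1) // 2
    if total_pairs - graph.m <= 0:
        raise ValueError("graph is complete; no non-edges to sample")
    out = np.empty((count, 2), dtype=np.int64)
    filled = 0
    while filled < count:
        cand = rng.integers(0, n, size=(2 * (count - filled) + 16, 2))
        for a, b in cand:
            if a == b:
                continue
            u, v = (a, b) if a < b else (b, a)
            if (u, v) in graph.edges:
                continue
            out[filled] = (u, v)
            filled += 1
            if filled == count:
                break
    return out


def _calibrate_ceiling(
    make_model, graph: UndirectedGraph, *, rel_tol: float, max_iter: int = 200
) -> tuple[EdgeProbabilityModel, float]:
    """Bisect the ceiling L ∈ (0,1] so expected edges match |E(G)|.

    The expected edge count is strictly increasing in L; if L=1 still
    undershoots, the decision boundary is shifted instead (second argument to
    ``make_model``), which raises every probability toward L.
    """
    m = graph.m
    if m == 0:
        return make_model(1e-12, 0.0), 0.0

    def resid(L: float, shift: float) -> float:
        return _expected_edge_count(make_model(L, shift)) - m

    shift = 0.0
    if resid(1.0, 0.0) < 0:
        # ceiling alone cannot reach m: push the boundary down until it can
        lo_s, hi_s = 0.0, 1.0
        while resid(1.0, hi_s) < 0 and hi_s < 1e6:
            lo_s, hi_s = hi_s, hi_s * 2
        if resid(1.0, hi_s) < 0:
            raise CalibrationError(
                "cannot match edge count even at maximal shift", abs(resid(1.0, hi_s)) / m
            )
        for _ in range(max_iter):
            mid = 0.5 * (lo_s + hi_s)
            if resid(1.0, mid) < 0:
                lo_s = mid
            else:
                hi_s = mid
            if abs(resid(1.0, hi_s)) / m <= rel_tol:
                break
        shift = hi_s
    lo, hi = 0.0, 1.0
    best = np.inf
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = resid(mid, shift)
        best = min(best, abs(r) / m)
        if abs(r) / m <= rel_tol / 4:
            return make_model(mid, shift), abs(r) / m
        if r < 0:
            lo = mid
        else:
            hi = mid
    r = resid(hi, shift)
    if abs(r) / m <= rel_tol:
        return make_model(hi, shift), abs(r) / m
    raise CalibrationError("ceiling bisection did not converge", best)


def fit_lrdp(
    emb: SignedEmbedding,
    graph: UndirectedGraph,
    *,
    rel_tol: float = 0.01,
    nonedge_ratio: float = 1.0,
    seed: int = 0,
    regularization_c: float = 1.0,
) -> EdgeProbabilityModel:
    """Fit the logistic-on-dot-product model L·sigmoid(k·(score − x0)).

    The slope and midpoint come from penalized logistic regression of edge
    scores (label 1) against ``nonedge_ratio``·m uniformly sampled non-edge
    scores (label 0); k is clamped to ≥ 0 so probability is nondecreasing in
    score.  L is then calibrated so Σ_{i<j} p matches the edge count within
    ``rel_tol``.
    """
    if emb.n != graph.n:
        raise ValueError(f"embedding n={emb.n} does not match graph n={graph.n}")
    rng = np.random.default_rng(seed)
    edges = np.array(sorted(graph.edges), dtype=np.int64)
    if len(edges) == 0:
        return EdgeProbabilityModel(
            variant="LRDP", emb=emb, params={"L": 1e-12, "k": 0.0, "x0": 0.0, "residual": 0.0}
        )
    nonedges = _sample_nonedges(graph, max(1, int(round(nonedge_ratio * len(edges)))), rng)
    s_edge = np.einsum(
        "ij,ij->i", emb.coords[edges[:, 0]] * emb.signature, emb.coords[edges[:, 1]]
    )
    s_non = np.einsum(
        "ij,ij->i", emb.coords[nonedges[:, 0]] * emb.signature, emb.coords[nonedges[:, 1]]
    )
    x = np.concatenate([s_edge, s_non])[:, None]
    y = np.concatenate([np.ones(len(s_edge)), np.zeros(len(s_non))])
    if np.ptp(x) < 1e-12:
        k, x0 = 0.0, 0.0  # constant scores: only the edge-count constraint binds
    else:
        clf = LogisticRegression(C=regularization_c, max_iter=1000)
        clf.fit(x, y)
        k = float(clf.coef_[0, 0])
        if k <= 0:
            k, x0 = 0.0, 0.0
        else:
            x0 = float(-clf.intercept_[0] / k)

    def make(L: float, shift: float) -> EdgeProbabilityModel:
        return EdgeProbabilityModel(
            variant="LRDP", emb=emb, params={"L": L, "k": k, "x0": x0 - shift}
        )

    model, residual = _calibrate_ceiling(make, graph, rel_tol=rel_tol)
    model.params["residual"] = residual
    model.params["seed"] = seed
    return model


def fit_lrhp(
    emb: SignedEmbedding,
    graph: UndirectedGraph,
    *,
    rel_tol: float = 0.01,
    nonedge_ratio: float = 1.0,
    seed: int = 0,
    regularization_c: float = 1.0,
) -> EdgeProbabilityModel:
    """Fit the logistic-on-Hadamard-product model L·sigmoid(w·f(i,j) + b),
    f(i,j)[r] = signature[r]·x_ir·x_jr; training and calibration mirror
    :func:`fit_lrdp` with a d-dimensional feature instead of the scalar score."""
    if emb.n != graph.n:
        raise ValueError(f"embedding n={emb.n} does not match graph n={graph.n}")
    rng = np.random.default_rng(seed)
    edges = np.array(sorted(graph.edges), dtype=np.int64)
    if len(edges) == 0:
        return EdgeProbabilityModel(
            variant="LRHP",
            emb=emb,
            params={"L": 1e-12, "w": np.zeros(emb.d), "b": 0.0, "residual": 0.0},
        )
    n_non = max(1, int(round(nonedge_ratio * len(edges))))
    total_nonedges = graph.n * (graph.n - 1) // 2 - graph.m
    if total_nonedges < 1:
        raise ValueError("graph has no non-edges to sample")
    nonedges = _sample_nonedges(graph, n_non, rng)
    f_edge = emb.coords[edges[:, 0]] * emb.coords[edges[:, 1]] * emb.signature
    f_non = emb.coords[nonedges[:, 0]] * emb.coords[nonedges[:, 1]] * emb.signature
    x = np.vstack([f_edge, f_non])
    y = np.concatenate([np.ones(len(f_edge)), np.zeros(len(f_non))])
    if np.ptp(x, axis=0).max() < 1e-12:
        w, b = np.zeros(emb.d), 0.0
    else:
        clf = LogisticRegression(C=regularization_c, max_iter=1000)
        clf.fit(x, y)
        w = clf.coef_[0].astype(float)
        b = float(clf.intercept_[0])

    def make(L: float, shift: float) -> EdgeProbabilityModel:
        return EdgeProbabilityModel(
            variant="LRHP", emb=emb, params={"L": L, "w": w, "b": b + shift}
        )

    model, residual = _calibrate_ceiling(make, graph, rel_tol=rel_tol)
    model.params["residual"] = residual
    model.params["seed"] = seed
    return model


def fit_softmax(emb: SignedEmbedding, graph: UndirectedGraph) -> EdgeProbabilityModel:
    """Degree-matched softmax: directed mass q(i→j) ∝ exp(score(i,j)) with the
    per-vertex constant set so Σ_{j≠i} q(i→j) = deg(i) exactly, then
    symmetrized by averaging and clamped to [0,1].  Exponentials use
    max-subtraction; an isolated vertex contributes an all-zero row.
    """
    if emb.n != graph.n:
        raise ValueError(f"embedding n={emb.n} does not match graph n={graph.n}")
    n = emb.n
    deg = graph.degrees().astype(float)
    shift = np.zeros(n)
    logz = np.zeros(n)
    for start in range(0, n, _BLOCK):
        rows = np.arange(start, min(start + _BLOCK, n))
        s = emb.score_block(rows)
        for r, i in enumerate(rows):
            s[r, i] = -np.inf  # exclude the self term from the normalizer
        shift[rows] = np.max(s, axis=1)
        logz[rows] = np.log(np.sum(np.exp(s - shift[rows, None]), axis=1))
    # isolated vertices contribute an all-zero row; an infinite normalizer
    # makes that exact and avoids overflow in their (unused) exponentials
    shift[deg == 0] = 0.0
    logz[deg == 0] = np.inf
    return EdgeProbabilityModel(
        variant="SOFTMAX",
        emb=emb,
        params={"degrees": deg, "shift": shift, "logz": logz},
    )
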