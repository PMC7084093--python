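"""Numeric certificates for the rank lower-bound apparatus.

Four checkable facts underlie the impossibility result for low-rank
dot-product models of triangle-rich sparse graphs:

* **Rank lemma** — for any square matrix M, (Σ_i M_ii)² ≤ rank(M)·Σ_ij M_ij².
  Applied to a Gram matrix VᵀV it lower-bounds the embedding dimension.
* **Dot-sum balance** — over all ordered pairs from a finite vector set, the
  total magnitude of negative dot products cannot exceed the positive total
  (expand ‖Σ_i w_i‖² ≥ 0).
* **Packing lemma** — any 4d unit vectors in R^d contain a pair with dot
  product ≥ 1/(4d): long vectors in low dimension must crowd, forcing
  high-probability edges and hence high degrees.
* **Explicit bounds** — a graph whose sampled triangles among degree-≤c
  vertices number Δ·n forces embedding rank ≥ min(1, α·Δ⁴/c⁹)·n/lg²n, with a
  cleaner Δ²/(c(Δ²+c⁴))·n bound when all vectors share one length.

Each routine recomputes its inequality from raw inputs and reports the pieces,
so a certificate can be serialized and audited independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Lemma-level default for the constant α ("sufficiently small"); the largest
#: value the explicit derivation supports.
DEFAULT_ALPHA = 1.0 / (128 * 3600 * 4**4)


@dataclass
class RankCertificate:
    """Rank lemma applied to one matrix: bound = (Σ diag)² / Σ entries²."""

    trace_sq: float
    entry_sq_sum: float
    bound: float
    numerical_rank: int

    @property
    def holds(self) -> bool:
        return self.bound <= self.numerical_rank + 1e-9

    def to_json_dict(self) -> dict:
        return {
            "trace_sq": self.trace_sq,
            "entry_sq_sum": self.entry_sq_sum,
            "bound": self.bound,
            "numerical_rank": self.numerical_rank,
            "holds": self.holds,
        }


@dataclass
class TheoremBound:
    """Explicit rank lower bound for a graph with a (c, Δ)-triangle foundation."""

    c: float
    delta: float
    n: int
    bound: float
    alpha: float | None = None
    min_common_length: float | None = None

    def to_json_dict(self) -> dict:
        return {
            "c": self.c,
            "delta": self.delta,
            "n": self.n,
            "alpha": self.alpha,
            "bound": self.bound,
            "min_common_length": self.min_common_length,
        }


def rank_lemma_certificate(
    m: np.ndarray, *, symmetry_tol: float = 1e-8
) -> RankCertificate:
    """Evaluate (Σ_i M_ii)² / Σ_ij |M_ij|² ≤ rank(M) on a symmetric matrix.

    The numerical rank counts singular values above the standard cutoff
    max(dim)·eps·σ_max.  Equality holds for the identity (bound = n = rank)
    and the all-ones matrix (bound = 1 = rank).
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    if m.size and np.max(np.abs(m - m.T)) > symmetry_tol:
        raise ValueError("matrix is not symmetric within tolerance")
    trace_sq = float(np.trace(m)) ** 2
    entry_sq = float(np.sum(m * m))
    bound = trace_sq / entry_sq if entry_sq > 0 else 0.0
    rank = int(np.linalg.matrix_rank(m)) if m.size else 0
    return RankCertificate(
        trace_sq=trace_sq, entry_sq_sum=entry_sq, bound=bound, numerical_rank=rank
    )


def dot_sum_balance(
    vectors: np.ndarray | list, *, tol: float = 1e-9
) -> tuple[float, float, bool]:
    """Split Σ over ordered pairs (i, j) ∈ [s]×[s] of w_i·w_j by sign.

    Returns (neg_sum, pos_sum, holds) where the sums are of |w_i·w_j| over
    pairs with negative and positive dot respectively, diagonal included.
    Since Σ_all w_i·w_j = ‖Σ w_i‖² ≥ 0, neg_sum ≤ pos_sum always.
    """
    w = np.atleast_2d(np.asarray(vectors, dtype=float))
    if w.shape[0] == 0:
        raise ValueError("vector set must be nonempty")
    gram = w @ w.T
    neg = float(-gram[gram < 0].sum())
    pos = float(gram[gram > 0].sum())
    return neg, pos, neg <= pos + tol


def packing_witness(
    vectors: np.ndarray | list, d: int, *, unit_tol: float = 1e-8
) -> tuple[int, int, float]:
    """Find the off-diagonal pair with maximal dot among ≥ 4d unit vectors in R^d.

    The packing lemma guarantees the maximum is ≥ 1/(4d); the maximizing pair
    is returned (not merely any witness) so a hypothetical failure would be as
    informative as possible.
    """
    u = np.atleast_2d(np.asarray(vectors, dtype=float))
    if u.shape[1] != d:
        raise ValueError(f"vectors have dimension {u.shape[1]}, expected {d}")
    if u.shape[0] < 4 * d:
        raise ValueError(f"need at least 4d={4 * d} vectors, got {u.shape[0]}")
    norms = np.linalg.norm(u, axis=1)
    if np.max(np.abs(norms - 1.0)) > unit_tol:
        bad = int(np.argmax(np.abs(norms - 1.0)))
        raise ValueError(f"vector {bad} is not unit norm (‖·‖ = {norms[bad]:.6g})")
    gram = u @ u.T
    np.fill_diagonal(gram, -np.inf)
    i, j = np.unravel_index(int(np.argmax(gram)), gram.shape)
    return int(i), int(j), float(gram[i, j])


def theorem1_rank_bound(
    c: float, delta: float, n: int, alpha: float | None = None
) -> TheoremBound:
    """General-position rank lower bound min(1, α·Δ⁴/c⁹)·n/lg²n.

    Hypotheses c > 4 and Δ > 0 are enforced; α defaults to the largest
    constant the derivation supports, 1/(128·3600·4⁴).
    """
    if c <= 4:
        raise ValueError(f"degree bound must satisfy c > 4 (got {c})")
    if delta <= 0:
        raise ValueError(f"triangle density must satisfy Δ > 0 (got {delta})")
    if n < 2:
        raise ValueError(f"need n >= 2 vertices (got {n})")
    if alpha is None:
        alpha = DEFAULT_ALPHA
    lg2 = np.log2(n) ** 2
    bound = min(1.0, alpha * delta**4 / c**9) * n / lg2
    return TheoremBound(c=c, delta=delta, n=n, alpha=alpha, bound=float(bound))


def equal_length_rank_bound(c: float, delta: float, n: int) -> TheoremBound:
    """Rank lower bound when all embedding vectors share a common length L:
    rank ≥ Δ²/(c·(Δ²+c⁴))·n, linear in n.

    Also reports the minimum common length the triangle count forces,
    L_min = √Δ/c (from Δ·n ≤ L²·c²·n).
    """
    if c <= 0:
        raise ValueError(f"degree bound must be positive (got {c})")
    if delta < 0:
        raise ValueError(f"triangle density must be >= 0 (got {delta})")
    if n < 1:
        raise ValueError(f"need n >= 1 (got {n})")
    bound = delta**2 / (c * (delta**2 + c**4)) * n
    l_min = float(np.sqrt(delta) / c)
    return TheoremBound(c=c, delta=delta, n=n, bound=float(bound), min_common_length=l_min)
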