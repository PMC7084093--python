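"""Spectral (eigendecomposition) embeddings of adjacency matrices and text-file ingestion.

The d-dimensional spectral embedding of a graph keeps the d largest-magnitude
eigenpairs of the symmetric adjacency matrix A = Ψ Λ Ψᵀ and reconstructs
A_d = Ψ_d Λ_d Ψ_dᵀ.  Because A is indefinite, some retained eigenvalues are
negative and A_d is not a Gram matrix of plain vectors; we therefore carry a
per-dimension sign signature alongside the coordinates, so that the signed dot
product

    score(i, j) = Σ_r signature[r] · x_ir · x_jr

reproduces (A_d)_ij exactly.  Embeddings trained externally (node2vec-style
text files) load with an all-positive signature, making the two sources
uniform downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph_core import UndirectedGraph


class EmbeddingFormatError(ValueError):
    pass


@dataclass
class SignedEmbedding:
    """Per-vertex coordinates plus a ±1 per-dimension signature.

    ``coords`` is n×d (row i = x_i); ``signature`` has entries in {+1, -1}.
    The pair score is the signature-weighted dot product, symmetric in (i, j),
    and the n×n score matrix has rank at most d.
    """

    coords: np.ndarray
    signature: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be a 2-D array")
        if self.signature is None:
            self.signature = np.ones(self.coords.shape[1])
        self.signature = np.asarray(self.signature, dtype=float)
        if self.signature.shape != (self.coords.shape[1],):
            raise ValueError("signature length must equal embedding dimension")
        if not np.all(np.isin(self.signature, (-1.0, 1.0))):
            raise ValueError("signature entries must be +1 or -1")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def score(self, i: int, j: int) -> float:
        if not (0 <= i < self.n and 0 <= j < self.n):
            raise IndexError(f"vertex index out of range: ({i},{j}) for n={self.n}")
        return float(np.dot(self.signature * self.coords[i], self.coords[j]))

    def score_block(self, rows: np.ndarray | list[int]) -> np.ndarray:
        """Score matrix restricted to the given rows (len(rows) × n)."""
        rows = np.asarray(rows)
        return (self.coords[rows] * self.signature) @ self.coords.T

    def score_matrix(self) -> np.ndarray:
        return self.score_block(np.arange(self.n))

    def features(self, i: int, rows: np.ndarray | None = None) -> np.ndarray:
        """Signed Hadamard features f(i, j)[r] = signature[r]·x_ir·x_jr for all j
        (or the given rows); summing coordinates recovers score(i, j)."""
        other = self.coords if rows is None else self.coords[rows]
        return (self.signature * self.coords[i]) * other


def spectral_embedding(graph: UndirectedGraph, d: int) -> SignedEmbedding:
    """Top-d (by |eigenvalue|) spectral embedding of the adjacency matrix.

    Coordinates are √|λ_r|·ψ_r entrywise and signature[r] = sign(λ_r), so the
    score matrix equals A_d = Ψ_d Λ_d Ψ_dᵀ.  Eigenpairs are ordered by
    decreasing |λ|, preferring the positive member of a ±λ tie; each
    eigenvector's sign is fixed so its largest-magnitude entry is positive.
    """
    n = graph.n
    if not (1 <= d <= n):
        raise ValueError(f"dimension d must satisfy 1 <= d <= n={n}, got {d}")
    use_dense = n <= 600 or d > n - 2 or graph.m == 0
    if use_dense:
        lam, psi = np.linalg.eigh(graph.adjacency_matrix())
    else:
        rows, cols = zip(*graph.edges)
        a = sp.coo_matrix(
            (np.ones(2 * len(rows)), (rows + cols, cols + rows)), shape=(n, n)
        ).tocsr()
        v0 = np.full(n, 1.0 / np.sqrt(n))  # fixed start vector for determinism
        try:
            lam, psi = spla.eigsh(a, k=d, which="LM", v0=v0)
        except spla.ArpackNoConvergence as exc:
            raise RuntimeError(f"eigensolver failed to converge: {exc}") from exc
    # order by |λ| descending; among ±λ ties prefer the positive eigenvalue
    order = np.lexsort((-lam, -np.abs(lam)))[:d]
    lam, psi = lam[order], psi[:, order]
    # deterministic eigenvector sign: largest-|entry| component positive
    for r in range(psi.shape[1]):
        k = int(np.argmax(np.abs(psi[:, r])))
        if psi[k, r] < 0:
            psi[:, r] = -psi[:, r]
    coords = psi * np.sqrt(np.abs(lam))
    signature = np.where(lam < 0, -1.0, 1.0)
    return SignedEmbedding(coords=coords, signature=signature)


def pair_score(emb: SignedEmbedding, i: int, j: int) -> float:
    """Signed dot product between the coordinates of vertices i and j."""
    return emb.score(i, j)


def load_embedding_text(
    path: str | Path,
    graph: UndirectedGraph | None = None,
) -> SignedEmbedding:
    """Load a word2vec/node2vec-style text embedding.

    Format: first line "n d", then n lines "id x1 ... xd".  The signature is
    all +1 (trained embeddings are plain vectors).  When ``graph`` is given,
    row ids are mapped through its label map so row i of the result is the
    graph's internal vertex i; otherwise ids must be 0..n-1.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingFormatError(f"{path}:1: header must be 'n d'")
        try:
            n, d = int(header[0]), int(header[1])
        except ValueError:
            raise EmbeddingFormatError(f"{path}:1: header must be two integers") from None
        coords = np.full((n, d), np.nan)
        seen: set[int] = set()
        count = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) != d + 1:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: expected {d + 1} tokens, got {len(tokens)}"
                )
            try:
                vid = int(tokens[0])
            except ValueError:
                raise EmbeddingFormatError(f"{path}:{lineno}: bad vertex id") from None
            if graph is not None and graph.labels is not None:
                if vid not in graph.labels:
                    raise EmbeddingFormatError(
                        f"{path}:{lineno}: id {vid} not in graph label map"
                    )
                row = graph.labels[vid]
            else:
                row = vid
            if not (0 <= row < n):
                raise EmbeddingFormatError(f"{path}:{lineno}: id {vid} out of range")
            if row in seen:
                raise EmbeddingFormatError(f"{path}:{lineno}: duplicate id {vid}")
            seen.add(row)
            coords[row] = [float(t) for t in tokens[1:]]
            count += 1
        if count != n:
            raise EmbeddingFormatError(f"{path}: header says {n} rows, found {count}")
    return SignedEmbedding(coords=coords, signature=np.ones(d))


def write_embedding_text(emb: SignedEmbedding, path: str | Path) -> None:
    """Write the word2vec-style text format (requires all-positive signature,
    since the format carries no sign information)."""
    if np.any(emb.signature < 0):
        raise ValueError("text format cannot represent a negative signature")
    with open(path, "w") as fh:
        fh.write(f"{emb.n} {emb.d}\n")
        for i in range(emb.n):
            coords = " ".join(f"{x:.17g}" for x in emb.coords[i])
            fh.write(f"{i} {coords}\n")
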