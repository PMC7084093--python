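# Methods

## The quantity being audited

For a simple undirected graph G on n vertices, let S_c be the set of vertices
whose degree in the *full* graph is at most c, and let T(c) be the number of
triangles in the subgraph induced by S_c. The triangle density at threshold c
is Δ(c) = T(c)/n — the denominator is always the total vertex count, so Δ is
comparable across graphs and thresholds. A graph has a (c, Δ)-triangle
foundation when T(c) ≥ Δ·n. Sparse real-world networks (social graphs, PPI
networks) combine low average degree with Δ(c) well above 1 for modest c;
graphs sampled from low-rank dot-product models of the same networks do not,
and the package's audit makes that gap measurable.

Two readings of the threshold are possible ("keep degree ≤ c" vs. "remove
degree ≥ x"); we standardize on the inclusive retain-form everywhere, with
S_c membership decided once from full-graph degrees, never recursively
recomputed after removal.

## Triangle counting

`count_triangles` ranks vertices by (degree, index), orients each edge toward
the higher rank, and intersects forward-neighbor sets, counting each triangle
once at its highest-ranked vertex — O(m^{3/2}) on sparse graphs.
`degree_triangle_curve` computes T at every distinct degree value in one pass:
vertices are inserted in nondecreasing (degree, index) order and each triangle
is charged to its last-inserted vertex, so S_c is always a prefix of the
insertion order and the cumulative count at the last vertex of degree c equals
the pointwise recomputation. Both routines are validated against exhaustive
O(n³) enumeration (and networkx) in the test suite.

## Spectral embeddings and the sign signature

The d-dimensional spectral embedding keeps the d largest-|λ| eigenpairs of the
adjacency matrix and reconstructs A_d = Ψ_d Λ_d Ψ_dᵀ. Adjacency matrices are
indefinite, so A_d is generally not a Gram matrix of plain vectors; we store
coordinates √|λ_r|·ψ_r together with a signature sign(λ_r) ∈ {±1} and define
score(i,j) = Σ_r sig_r·x_ir·x_jr, which reproduces A_d exactly. Externally
trained embeddings (node2vec-style text files, header `n d`) load with an
all-positive signature, so both sources feed the same downstream models; the
signed elementwise product sig_r·x_ir·x_jr likewise serves as the Hadamard
feature, keeping spectral and trained inputs uniform.

Numerical choices: dense `eigh` for n ≤ 600 or d near n (deterministic);
ARPACK `eigsh` with a fixed start vector otherwise. Eigenpairs are ordered by
decreasing |λ| with the positive member of a ±λ pair preferred, and each
eigenvector's sign is fixed by making its largest-magnitude entry positive.
Within an eigenspace of exact multiplicity the basis — and hence the
coordinates, though not A_d when the full eigenspace is retained — remains
solver-dependent; tests therefore compare score matrices, never eigenvectors.

## Edge-probability models

All four models are symmetric, zero-diagonal, and valued in [0,1]; all are
evaluated in row blocks so no dense n×n matrix is ever required.

**TDP** — p = max(0, min(score, 1)). Parameter-free; the reference model for
the rank lower bound.

**LRDP** — p = L·σ(k·(score − x0)). The single published constraint (expected
edge count = observed edge count) under-determines (L, k, x0), so we fit
(k, x0) by L2-penalized logistic regression of edge scores against an
equal-size uniform sample of non-edge scores (ratio and seed configurable),
clamp k ≥ 0 so probability is monotone in score, then calibrate L ∈ (0,1] by
bisection on the expected-edge-count equation (monotone in L). If L = 1 still
undershoots the edge count — possible when the regression's ceiling is too
low — x0 is shifted downward by a second bisection before L is calibrated;
this keeps calibration convergent whenever a solution exists. Default
calibration tolerance: 1% relative; the bisection itself targets 0.25% so the
contract holds with margin.

**LRHP** — p = L·σ(w·f(i,j) + b) on the d-dimensional signed Hadamard
feature. Same training and ceiling calibration as LRDP (the bias plays x0's
role). With tied weights w = k·1, b = −k·x0 it reproduces LRDP exactly, which
the tests use as an equivalence oracle.

**Softmax** — directed mass q(i→j) = deg(i)·exp(score(i,j))/Σ_{k≠i}
exp(score(i,k)), so each row sums to the true degree exactly (isolated
vertices get an all-zero row); the undirected probability is the clamped
average (q(i→j)+q(j→i))/2. Exponentials use per-row max-subtraction. The
clamp is applied after symmetrization. Note the softmax is defined with
exponentiated scores; the self-term is excluded from the normalizer so no
probability mass is spent on self-loops.

## Sampling and the replicate audit

`sample_graph` performs one independent Bernoulli trial per unordered pair,
drawing uniforms row by row in vertex order so the result is a deterministic
function of (model, seed). Replicate r of `replicate_audit` uses a
counter-based seed (SeedSequence with spawn_key r), so replicates are
reproducible independently of how many run. Per-replicate Δ(c) curves are
merged on the union of their thresholds by step-function extension (Δ = 0
below a curve's smallest threshold, total-triangle density above its
largest), and the audit reports the pointwise *maximum* — a deliberately
generous summary for the model under audit.

The audit defaults mirror the standard experiment: a 100-dimensional
embedding, 100 Bernoulli samples, max-Δ reported; summary ratios default to
c ∈ {5, 10, 25, 50}. Tests and the acceptance script scale the replicate
count to 20 on the n = 300 witness, which already separates the regimes by an
order of magnitude.

## Certificates

* **Rank lemma** — for square M, (Σ_i M_ii)² ≤ rank(M)·Σ_ij M_ij². The
  certificate reports numerator, denominator, their ratio, and the numerical
  rank (singular values above max(dim)·eps·σ_max, the standard cutoff).
* **Dot-sum balance** — over ordered pairs (diagonal included) the negative
  dot-product mass never exceeds the positive mass, since their difference is
  ‖Σ w_i‖² ≥ 0.
* **Packing** — among ≥ 4d unit vectors in R^d some pair has dot ≥ 1/(4d).
  The routine returns the *maximizing* pair, so a hypothetical counterexample
  would be maximally informative.
* **Explicit bounds** — `theorem1_rank_bound` evaluates
  min(1, α·Δ⁴/c⁹)·n/lg²n under the hypotheses c > 4, Δ > 0, with α defaulting
  to 1/(128·3600·4⁴), the largest constant the derivation supports (α is only
  required to be "sufficiently small"; fixing it makes bound values
  reproducible, and it is an argument for sensitivity analysis).
  `equal_length_rank_bound` evaluates the equal-length-vector case
  Δ²/(c·(Δ²+c⁴))·n and reports the forced minimum common length
  L_min = √Δ/c. The radical follows from the defining inequality
  Δ·n ≤ L²·c²·n; source texts sometimes drop it in typesetting, and we
  implement the derivation-consistent form.

## Synthetic fixtures

`disjoint_cliques(m, k)` is the extremal deterministic witness: n = m·k,
every degree k−1, m·C(k,3) triangles, Δ(k−1) = C(k,3)/k. With k = 3 it
realizes Δ(2) = 1/3 — maximal triangle density at minimal degree — and its
adjacency spectrum ({2} with multiplicity m, {−1} with multiplicity 2m) makes
the d-sweep behavior analyzable: a rank-d truncation with d ≤ m reconstructs
roughly d of the m triangle blocks at edge probability 2/3 each, so the
expected retained density grows essentially linearly in d and reaches 1/3
only at full rank. `planted_triangle_graph` unions a seeded G(n, p) with
vertex-disjoint planted triangles (exact lower bound on the triangle count,
+2 degree impact per planted vertex). `rdpg_vectors` draws latent vectors
with all pair scores in [0,1] — nonnegative unit vectors ("spherical") or
near-orthogonal cluster centroids with within-cluster dot ≈ 0.9
("clustered", a stochastic block model in latent-position form).

What these fixtures do not emulate: heavy-tailed degree distributions,
degree-triangle correlation, and the scale of real networks. Passing tests
show the pipeline's operations are correct and that the rank phenomenon
appears exactly where the theory predicts on controlled inputs; they do not
by themselves quantify the loss on any real network — the CLI exists to run
the same audit on downloaded edge lists.

## Problem sizes

Test-suite and acceptance-script sizes were chosen so each check is decisive
at desk scale: exhaustive-enumeration cross-checks up to n = 60 (200 graphs),
exact-reconstruction checks up to n = 100, 500 random matrices for the rank
lemma, 10⁴ unit-vector sets for packing, 500 sampler replicates for the
second-moment inequality, and a 20-replicate d-sweep on the n = 300
disjoint-triangle witness.

## Known limitations

* LRDP/LRHP training details (non-edge sampling scheme, regularization) are
  genuinely open choices; ours are config-exposed (ratio, seed, C) and the
  defaults (1:1, C = 1) are recorded with every fitted model.
* Calibration matches the expected *edge count* only, as specified — not the
  degree sequence (that is softmax's job) nor any higher moment.
* The LRDP fallback cannot rescue a degenerate fit with k = 0 on a graph
  denser than 1/2 (the constant model's ceiling is L/2); calibration then
  fails with a diagnostic carrying the best residual.
* Weighted and directed graphs, Laplacian/normalized-adjacency embeddings,
  and distance-based (non-dot-product) latent space models are out of scope;
  the last of these is known to be a potential escape from the rank bound.
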