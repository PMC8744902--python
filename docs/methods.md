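# Methods

This note documents the models, numerical choices and limitations behind the
package, in the spirit of a methods appendix.

## Google matrix and ranking

The adjacency of the simple network is binary: `A[i, j] = 1` when node j
points to node i, regardless of link sign or repeated interactions ("directed
and nonweighted").  Columns are normalized to give the transition matrix S;
dangling columns (zero out-degree) are replaced by the uniform column 1/N.
The Google matrix `G = αS + (1 − α)/N` is never materialized: it is applied
matrix-free as `G v = α S_sparse v + 1 (c·v)` with
`c_j = (α·[j dangling] + 1 − α)/N`, so the memory cost stays O(links).

* **Damping** α = 0.85 (the conventional value; rankings are stable for
  α ∈ (0.5, 0.95), and a soft diagnostic in the test suite logs the top-10
  rank displacement between α = 0.85 and 0.75).
* **PageRank** by power iteration from the uniform vector, L1 convergence
  tolerance 1e-14 by default (chosen so that the doubled-network identity
  below can be verified at the 1e-13 level), hard cap 100 000 iterations, with
  an explicit error carrying the final residual on non-convergence.
* **Rank indices** are 1-based, descending probability, ties broken by
  ascending node index (the tie rule is a package convention; the construction
  itself does not define one).
* **CheiRank** is the PageRank of the link-inverted network.  The dangling
  sets of the two constructions generally differ.
* **Rank-plane density**: the (ln K, ln K*) plane is divided into `bins²`
  logarithmically equidistant cells over [0, ln N]; a cell's value is the node
  count divided by its capacity — the number of integer (K, K*) pairs whose
  logarithms fall inside (half-open cells, last cell closed) — and the grid is
  renormalized to total 1.  Zero-capacity cells are excluded before
  renormalization.  A single-node input has an empty log range and is
  rejected.

## Reduced Google matrix

Two routes compute the stochastic complement
`GR = Grr + Grs (1 − Gss)⁻¹ Gsr` and agree to ≤ 1e-10 elementwise on every
test network (this cross-validation is part of the acceptance suite):

* **dense_solve** — sparse LU factorization of `1 − α Sss`, with the rank-1
  teleportation-plus-dangling term `1 c_sᵀ` folded in by the Sherman–Morrison
  identity (one extra solve against the all-ones vector).  One factorization
  serves all Nr right-hand-side columns.
* **spectral_series** — the leading right/left eigenvectors ψR, ψL of Gss are
  computed by power iteration (tolerance 1e-14), biorthonormalized to
  ψLᵀψR = 1 with ψR entrywise nonnegative and L1-normalized.  Then
  `Gpr = Grs ψR ψLᵀ Gsr / (1 − λc)` and
  `Gqr = Grs Σ_{l≥0} Ḡss^l Qc Gsr` with `Qc = 1 − ψR ψLᵀ`,
  `Ḡss = Qc Gss Qc`.  The series truncates when a term's max-norm drops below
  1e-12 (re-projecting each term for numerical stability), hard cap 10 000
  terms with a diagnostic error on failure.

Gss is *not* column-renormalized: the escape probability from the scattering
block into the subset is exactly what makes λc < 1 and the series convergent.
In the dense route Gpr comes from the same eigenvector pair and
`Gqr = GR − Grr − Gpr`.

Matrix orientation everywhere: element (i, j) is the transition j → i, i.e.
row = target, column = source; all matrix TSV output follows this convention.

Degenerate contract: when the subset is the whole network, GR equals G,
Gpr = Gqr = 0 and λc is reported as 0.

`Pr` is the global PageRank restricted to the subset and renormalized; the
PageRank of GR reproduces it (checked to 1e-8 in L1 over random subsets).
Negative entries occur only in Gqr; their count is exposed as a diagnostic
(`ReducedSet.n_negative_qr`), since reductions of real PPI networks show
roughly a tenth of entries mildly negative.

## Bifunctional Ising doubling

Each node splits into (+) and (−) copies, interleaved as
((1,+),(1,−),(2,+),(2,−),…) — the ordering is a package convention chosen to
keep base-node locality; it is stated in all outputs.  Each signed edge
contributes its σ-block (σ⁺ = [[1,1],[0,0]], σ⁻ = [[0,0],[1,1]],
σ⁰ = ½[[1,1],[1,1]]); repeated interactions sum their blocks, making the
doubled adjacency weighted.  The Google matrix of the doubled network
normalizes columns by their weighted sums; all-zero columns get the uniform
column 1/(2N).

The split identity `P(j) = P⁺(j) + P⁻(j)` (P from the simple network) is
exact **only when every (source, target) pair carries a single interaction**:
σ-block summation makes the collapsed doubled chain weighted while the simple
network is binary, so duplicate pairs break the identity at the 1e-4 level
rather than 1e-13.  The emulated database's printed link counts satisfy the
doubled sparsity identity `NI,ℓ = 2(Nℓ⁺ + Nℓ⁻) + 4 Nℓⁿ` exactly, which pins
duplicate pairs as absent there; the synthetic generator therefore defaults
to unique pairs (`multi_edge_prob = 0`), and the approximate regime remains
available by raising that parameter.

Reduced matrices on the doubled node set inherit two structural properties
that the tests verify: the (b,+) and (b,−) columns of GR are identical, and
collapsing target-label pairs reproduces the simple-network GR of the same
subset.

## Sensitivity derivative

The perturbation multiplies one element GR(a, b) by (1 + ε) and renormalizes
column b by 1/(1 + ε GR(a, b)).  Differentiating at ε = 0 gives the column-b
matrix `E` with `E(a,b) = GR(a,b)(1 − GR(a,b))` and
`E(c,b) = −GR(c,b) GR(a,b)` for c ≠ a, whose column sum is zero.  The
PageRank derivative solves `(1 − GR) P′ = E Pr` on the zero-sum subspace; the
unit eigenvalue is deflated by adding `ones·onesᵀ/Nr`, which leaves the
zero-sum solution unchanged and makes the system nonsingular.  The derivative
is exact — the central-finite-difference quotient at ε = 1e-6 agrees to
1e-6 relative over random stochastic matrices (an acceptance property) — and
`Σ_j D(b→a)(j) Pr(j) = 0` holds to 1e-12 because perturbed PageRanks stay
normalized.

For the all-pairs matrix the solve is vectorized: with `A` the deflated
system matrix, `D[a,b] = GR(a,b) Pr(b) (A⁻¹[a,a] − (A⁻¹GR)[a,b]) / Pr(a)`,
needing one matrix inverse per reduced set.  On an exactly rank-1 GR (all
columns equal to Pr) the closed form `D[a,b] = (1 − Pr(a)) Pr(b)` holds to
1e-10; on realistic reductions D[a,b] correlates strongly with Pr(b) because
the rank-1 background dominates — both are tested, the latter as a logged
diagnostic only.  Diagonal entries D[a,a] are computed (the formula is well
defined) but excluded from all rankings, which pair up/down rows with
TGF-β/X columns only.

## External-influencer (X-protein) selection

Candidates are all nodes outside the internal group with at least one direct
edge — of any sign, since the ranking network is unsigned — into the top
`n_top_up` up- or `n_top_down` down-responders (defaults 5/5; `n_select`
defaults to 10).  The reduced matrix is computed over the internals
(annotation order) followed by the candidates ordered by global PageRank
index (ties by node id), its sensitivity matrix evaluated, and each candidate
b scored by `Ds(5+5)(b) = Σ_{a ∈ top responders} D[a,b]`.  The winners are
appended to the annotation table as new x-rows ordered by local PageRank.
An empty candidate set is an explicit error, not an empty result.

## Synthetic generator

The generator emulates the published summary statistics of a MetaCore-scale
PPI network: mean out-degree 7.3 (Poisson, truncated to [1, N−1]), sign mix
65157 : 49321 : 177713 (exact count ratios as defaults), no self-loops.
Targets are drawn with probability ∝ (in-degree + 1)^γ with γ = 1 by default
(linear preferential attachment), which produces the heavy-tailed in-degree
and PageRank distributions that make the selection and reduction stages
behave realistically.  One private RNG stream per call; identical spec and
seed give byte-identical edge lists.

What the generator does **not** emulate: the true degree law (unpublished),
community structure, biological motif statistics, or any correlation between
link sign and topology (signs are i.i.d.).  Passing tests on synthetic
networks therefore validate the algorithms and their numerical contracts,
not any biological claim about real interaction databases.

Planted-influencer instances wire a few outside nodes with `boost` direct
activation links into the top-responder set plus `boost` incoming links
(raising their PageRank); the selection procedure recovers at least 2 of 3
planted nodes in its top 3 in at least 8 of 10 seeds at N = 600, boost = 10 —
in practice recovery is 10/10 at these settings.

## Fits and report tables

The summed-sensitivity law is fitted two ways: one-parameter least squares
through the origin (η = Σxy/Σx², standard error from the residual variance
with n − 1 degrees of freedom) and ordinary least squares of ln y on ln x
(κ = slope, η̃ = exp(intercept), with the prefactor error by the delta
method).  Both are validated in the tests against independent
normal-equation and grid-search oracles, and on the packaged reference table
they land inside the published uncertainty intervals.  The fitting method
behind the published intervals is not documented at the source; unweighted
least squares is the package's interpretation, and the packaged-table test
uses the printed intervals as tolerances, not as definitions.

Report tables (ranked pair list, summed-sensitivity table, TGF-β influence
ranking) are TSV with explicit headers, floats at 6 decimals.

## Diagrams

Friend/follower expansion uses the modulus of matrix elements for strength
(negative elements participate; the signed value is kept as an edge
attribute), branch 4 and two levels by default, ties by ascending group
index, and skips links internal to the combined TGF-β + X group.  Colors
always come from Grr + Gqr(nd) regardless of the diagram's source matrix;
the U1/U2 (D1/D2) comparison uses strict `>`, so an exact tie falls to the
second color — the tie rule is a documented package convention.  Export is
DOT (hand-written, attribute-carrying) or GraphML (networkx); geometric
layout is left to the renderer.

## Problem sizes

The test and acceptance workloads run on synthetic networks of N = 100–1000
nodes with subsets of 10–54 nodes — sizes at which the dense reduced-matrix
algebra is exact and fast while exercising every code path; the sparse
matrix-free design itself scales to much larger networks (the spectral-series
route exists precisely for the regime where (1 − Gss) cannot be factorized).

## Known limitations

* The generator is a declared stand-in; quantities that depend on the
  commercial database's actual topology (specific weights, candidate counts,
  named-protein ranks) are shipped only as reference fixtures, not
  recomputed.
* Sensitivity positivity (all Dab > 0) is typical but not guaranteed on
  arbitrary synthetic reductions; the fraction of negative entries is logged,
  not asserted.
* The Ising friend/follower diagrams are out of scope; the doubled reduced
  matrices are computed and validated, their diagram rendering is not.
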