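# Methods

## Scope and model

`dxlink` computes exact polynomial invariants of the oriented links that
model double-crossover DNA polyhedra built on cubic (3-regular) plane
graphs. The link L(G) associated with a cubic graph G is obtained by
truncating G (subdivide every edge twice, then replace every original
degree-3 vertex star by a triangle), covering each original-edge image
with the double-crossover 2-tangle T1 and each triangle edge with the
vertical 2-tangle T2, and orienting the two backbone strands
antiparallel, which makes every crossing left-handed ("negative"). With
four helical turns per edge the diagram has 16 crossings per original
edge: 192 for the cube, 96 for K4, 48 for the theta graph.

The computation never touches the diagram. It runs entirely at the graph
level:

    cubic multigraph G
      → chain polynomial Ch(G)                   (deletion–contraction)
      → two-label chain polynomial Ch(G′)        (truncation substitution)
      → Homfly polynomial P_L(v,z)               (rational substitution,
                                                  exact cancellation)
      → Conway ∇(z), Jones V(t), braid bounds.

## Chain polynomial

For a graph with edges labeled by commuting symbols, Ch(G) is the sum
over edge subsets Y of F_Y(1 − ω) · π_{E−Y}, where F is the flow
polynomial and π the product of the labels outside Y. Ch is multilinear
in the labels; its label-free term is F_G(1 − ω).

Implementation: deletion–contraction with the pivot fixed as the
lexicographically smallest non-loop label (deterministic recursion
tree), base cases "edgeless → 1" and "loop labeled a → factor (a − ω)",
with two accelerations that change nothing mathematically:

- **Component/block factorization.** Ch is multiplicative over
  components and over subgraphs meeting in at most one vertex. We split
  into connected components at every level. Disconnected graphs are not
  covered explicitly by the one-cut-vertex product rule; we extend Ch
  multiplicatively over components, which is forced by the subset-sum
  definition (the flow polynomial is multiplicative over components).
- **Memoization** keyed on the exact sorted labeled edge list — never on
  isomorphism classes. Correctness over speed; the largest graph that
  ever goes through deletion–contraction here is the 18-edge truncated
  K4 used as an oracle (~0.5 s).

The literal subset-sum route (`chain_polynomial_subset_sum`) is kept as
an independent implementation for ≤ 16 edges and is compared against the
recursion in the tests. The flow polynomial itself is cross-checked in
the tests against a third route, networkx's Tutte polynomial, via
F(t) = (−1)^(m−n+c) · T(0, 1 − t).

Sign convention: everything is evaluated at t = 1 − ω, so a cycle
contributes −ω per independent loop (single loop → −ω, theta → ω² + ω).

## Truncation by substitution

For cubic loop-free G with n vertices and m edges, each term of Ch(G)
with support U and coefficient F contributes

    F · a^|U| · (b³−ω)^p · (b²+b−ω−1)^q · (3b−ω−2)^(n−p−q),

p = #vertices with all three incident edges in U, q = #vertices with
exactly one. Incidence is counted per edge *instance* on the original
graph G (parallel edges each count; this is what makes the theta graph
work). A vertex meeting exactly two support edges is impossible — the
vertex star is a cut-set and such terms vanish — and the code *asserts*
this instead of assuming it, so an invalid input polynomial raises
`ConsistencyError` rather than producing garbage.

The result is stored twice: factored (per-term powers of the three ω–b
factors) and expanded ({(a-exp, b-exp) → ω-polynomial}); `self_check()`
re-expands the factored form and compares. A stepwise variant exposes
the intermediate polynomials (per-vertex subdivision labels, then the
x/y-collapsed form) built via the chain-replacement and Y−Δ
substitution rules; tests confirm it agrees with the direct bookkeeping
and with a from-scratch deletion–contraction on the structurally
truncated graph.

Design choices:

- **Loops are rejected** by the substitution engine even though cubic
  multigraphs may contain them: the edge-replacement step presumes two
  distinct end-vertices, and no published convention covers a loop.
  `structural_truncate` (the graph-level operation) does handle loops
  via half-edge bookkeeping, so the restriction is purely about the
  polynomial shortcut.
- The per-edge labels of a structural truncation keep their identity
  (`a_k'`, `b<vertex>_1..3`) so that the oracle comparison can collapse
  them onto the two generic labels a, b after the fact.

## Homfly conversion

With δ = (v⁻¹ − v)/z, substitute into Ch(G′):

    ω = 1 − δ²,   b = v⁴,
    a = (v⁻² − 1 − z²(1+v²+v⁴+v⁶)) / (v⁻² − 1 − 2z²(v²+1)),

then multiply by δ⁻¹ · [(v⁻³ − v⁻¹ − 2z²(v+v⁻¹)) / (v¹³ − v¹⁵)]^m.
The result is the Homfly polynomial of the negative link; the positive
(all right-handed) mirror follows by v → −v⁻¹, implemented as that
variable change and not as an independent formula.

Numerically everything is fraction-free: each factor is homogenized
over the common denominator (v²z²)^D · A_d^m, where A_d is the
denominator of the a-substitution cleared of negative powers and D is
the maximal ω-weight over terms. A structural identity makes the
bookkeeping collapse: v³ · (v⁻³ − v⁻¹ − 2z²(v + v⁻¹)) equals A_d
exactly, so the edge-weight numerators cancel the a-denominators and
the entire expression reduces to

    P = N / (1 − v²)^(m+1) · v^(1−16m−2D) z^(1−2D)

for one big integer Laurent polynomial N. The division by
(1 − v²)^(m+1) is performed as *exact* division (per-z-slice univariate
reduction; a generic lex-order reduction covers genuinely bivariate
divisors) and raises `ConsistencyError` on any nonzero remainder — a
substitution bug cannot produce a silently wrong polynomial.
Coefficients reach ~10²³ for the cube link; Python integers make this
exact without extra dependencies, and the full cube pipeline runs in
about 0.2 s.

## Specializations and braid index

- Conway: ∇(z) = P(1, z). Negative z-powers must cancel at v = 1;
  leftovers raise. For the three named links ∇ is a single term whose
  lowest degree is (number of components − 1), consistent with 8-, 14-
  and 26-component links; the component counts are not asserted
  independently.
- Jones: V(t) = P(t, t^½ − t^-½), represented exactly in s = t^½ with
  integer exponents (even-component links have half-integer t-powers,
  e.g. the cube link's leading t^(−409/2)). Negative z-powers are
  handled by clearing z^k and dividing exactly by (s − s⁻¹)^k.
- Braid index: MFW lower bound span_v(P)/2 + 1 and Ohyama's upper bound
  1 + c/2 with c = 16m crossings. For the theta, K4 and cube links the
  bounds coincide (25, 49, 97), pinning the braid index exactly. The
  16-per-edge crossing count is the 4-turn convention; other turn
  numbers are out of scope.
- Tangle invariants: the closure values Nu/De of T1 and T2 and the
  derived basis coefficients μ, w are provided as closed-form sympy
  expressions; μ and w are *recomputed* from the closures through their
  defining identities and verified against the closed forms at
  construction time.

## Synthetic fixtures

`random_cubic_multigraph(n, seed)` pairs 3n half-edges uniformly with a
seeded Mersenne Twister. It deliberately produces loops and parallel
edges — the chain-polynomial machinery must handle both — and the
property suites use n ∈ {2, 4, 6} (up to 9 edges), 50 seeds. What the
generator emulates is combinatorial shape only: it knows nothing of
planarity or embeddings, so a green property suite establishes the
algebraic identities (subset-sum equivalence, deletion–contraction
identities, cut-set vanishing, exact Theorem-level cancellation) on
arbitrary cubic multigraphs, not any statement about realizable DNA
polyhedra. Graphs with loops are skipped by the truncation/Homfly
property checks, matching the engine's documented precondition.

## Numerical choices, degenerate inputs, limitations

- All arithmetic is exact (integers, integer Laurent coefficients);
  floating point appears nowhere.
- Deterministic everything: pivot choice, edge order, JSON key order;
  identical inputs give byte-identical CLI reports.
- Degenerate inputs: edgeless graphs have Ch = 1; non-cubic graphs are
  rejected by the truncation/Homfly layer with the violating vertex
  named; the zero polynomial has no v-span and is rejected by the
  braid-bound calculator; an odd v-span (impossible for links from this
  pipeline) raises.
- The deletion–contraction engine is meant for graphs up to ~20 edges;
  the substitution pipeline itself scales to larger cubic graphs
  (its cost is driven by the number of chain-polynomial terms, i.e. by
  the cycle structure of G, not by the size of the truncated graph).
- Only 3-regular graphs and 4-turn (16 crossings/edge) diagrams are
  supported; n-regular generalizations and protein polyhedra are out of
  scope. The linking-matrix/cofactor cross-check of the Conway leading
  coefficient needs per-component linking numbers that are not modelled
  here; the tests assert only that the leading coefficient is a single
  nonzero integer.
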