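"""Flow and chain polynomials: published examples, defining identities,
and the independent oracles (subset-sum definition, Tutte specialization)."""

import networkx as nx
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from dxlink import (
    ChainPolynomial,
    ConsistencyError,
    LabeledMultigraph,
    OmegaPolynomial,
    chain_polynomial,
    chain_polynomial_subset_sum,
    chain_replace,
    flow_polynomial,
    random_cubic_multigraph,
    y_delta,
)

w = sympy.Symbol("omega")

TRIANGLE = LabeledMultigraph((0, 1, 2), ((0, 1, "x"), (1, 2, "y"), (2, 0, "z")))
STAR_K13 = LabeledMultigraph(
    (0, 1, 2, 3), ((0, 1, "x"), (0, 2, "y"), (0, 3, "z"))
)
SINGLE_LOOP = LabeledMultigraph((0,), ((0, 0, "a"),))


def flow_via_tutte(g: LabeledMultigraph):
    """Independent flow-polynomial oracle: F(t) = (-1)^(m-n+c) T(0, 1-t),
    evaluated at t = 1 - ω, with T from networkx."""
    G = g.to_networkx()
    x, y = sympy.symbols("x y")
    T = nx.tutte_polynomial(G)
    c = nx.number_connected_components(G)
    sign = (-1) ** (g.n_edges - g.n_vertices + c)
    return sympy.expand(sign * T.subs({x: 0, y: w}, simultaneous=True))


class TestFlowPolynomial:
    def test_theta(self, theta):
        assert flow_polynomial(theta) == OmegaPolynomial({1: 1, 2: 1})

    def test_bridges_kill_the_flow(self):
        path = LabeledMultigraph((0, 1, 2), ((0, 1, "a"), (1, 2, "b")))
        assert flow_polynomial(path).is_zero()

    def test_single_loop(self):
        assert flow_polynomial(SINGLE_LOOP) == OmegaPolynomial({1: -1})

    def test_cube(self, cube):
        # constant term of the published truncated-cube chain polynomial
        assert flow_polynomial(cube) == OmegaPolynomial(
            {1: -11, 2: -25, 3: -20, 4: -7, 5: -1}
        )

    def test_loop_count_interpolation(self):
        """A loop has k-1 nowhere-zero Z_k flows, so F(t) = t - 1; at
        t = 1 - ω that is -ω per loop, multiplicatively."""
        two_loops = LabeledMultigraph((0,), ((0, 0, "a"), (0, 0, "b")))
        assert flow_polynomial(two_loops) == OmegaPolynomial({2: 1})

    @given(st.integers(0, 10**6), st.sampled_from([2, 4, 6]))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_tutte_specialization(self, seed, n):
        g = random_cubic_multigraph(n, seed)
        assert sympy.expand(flow_polynomial(g).to_sympy(w) - flow_via_tutte(g)) == 0


class TestChainPolynomial:
    def test_theta_published_form(self, theta):
        a1, a2, a3 = sympy.symbols("a1 a2 a3")
        expected = a1 * a2 * a3 - w * (a1 + a2 + a3) + w**2 + w
        assert sympy.expand(chain_polynomial(theta).to_sympy(w) - expected) == 0

    def test_tetrahedron_published_form(self, tetrahedron):
        a = sympy.symbols("a1:7")
        expected = (
            a[0] * a[1] * a[2] * a[3] * a[4] * a[5]
            - (
                a[0] * a[1] * a[2]
                + a[0] * a[4] * a[5]
                + a[1] * a[3] * a[5]
                + a[2] * a[3] * a[4]
                + a[0] * a[3]
                + a[1] * a[4]
                + a[2] * a[5]
            )
            * w
            + sum(a) * w * (w + 1)
            - w * (w + 1) * (w + 2)
        )
        assert sympy.expand(chain_polynomial(tetrahedron).to_sympy(w) - expected) == 0

    def test_single_loop_is_a_minus_omega(self):
        ch = chain_polynomial(SINGLE_LOOP)
        assert ch.coefficient(["a"]) == OmegaPolynomial.one()
        assert ch.constant_term == OmegaPolynomial({1: -1})
        assert len(ch.terms()) == 2

    def test_triangle(self):
        # xyz - ω: every proper nonempty edge subset has a bridge
        ch = chain_polynomial(TRIANGLE)
        x, y, z = sympy.symbols("x y z")
        assert sympy.expand(ch.to_sympy(w) - (x * y * z - w)) == 0

    def test_star_all_bridges(self):
        # K_{1,3}: only the full label product survives
        ch = chain_polynomial(STAR_K13)
        assert ch.terms() == {
            (("x", 1), ("y", 1), ("z", 1)): OmegaPolynomial.one()
        }

    @given(st.integers(0, 10**6), st.sampled_from([2, 4, 6]))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_subset_sum_oracle(self, seed, n):
        """Deletion-contraction equals the literal definition (sum over
        edge subsets of flow(<Y>) times outside-label product)."""
        g = random_cubic_multigraph(n, seed)
        assert chain_polynomial(g) == chain_polynomial_subset_sum(g)

    @given(st.integers(0, 10**6), st.sampled_from([2, 4, 6]))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_constant_term_is_flow_and_multilinear(self, seed, n):
        g = random_cubic_multigraph(n, seed)
        ch = chain_polynomial(g)
        assert ch.constant_term == flow_polynomial(g)
        assert ch.is_multilinear()

    @given(st.integers(0, 10**6), st.sampled_from([4, 6]))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_deletion_contraction_identities(self, seed, n):
        """For a non-loop edge a: the coefficient of a in Ch(G) is
        Ch(G - a), and setting a = 1 yields Ch(G / a)."""
        g = random_cubic_multigraph(n, seed)
        nonloops = [e for e in g.edges if e[0] != e[1]]
        if not nonloops:
            return
        u, v, lab = nonloops[seed % len(nonloops)]
        ch = chain_polynomial(g)
        deleted = LabeledMultigraph(
            g.vertices, tuple(e for e in g.edges if e[2] != lab)
        )
        keep, drop = min(u, v), max(u, v)
        contracted = LabeledMultigraph(
            tuple(x for x in g.vertices if x != drop),
            tuple(
                (keep if a == drop else a, keep if b == drop else b, l)
                for a, b, l in g.edges
                if l != lab
            ),
        )
        ch_del = chain_polynomial(deleted)
        ch_con = chain_polynomial(contracted)
        # Ch(G) = (a - 1) Ch(G-a) + Ch(G/a)
        a_poly = ChainPolynomial.label(lab)
        assert ch == (a_poly - ChainPolynomial.one()) * ch_del + ch_con
        # coefficient extraction: terms containing the pivot label
        coeff_of_a = ChainPolynomial(
            {
                tuple(p for p in mono if p[0] != lab): c
                for mono, c in ch.terms().items()
                if (lab, 1) in mono
            }
        )
        assert coeff_of_a == ch_del
        assert ch.set_label_to_one(lab) == ch_con

    @given(st.integers(0, 10**6), st.sampled_from([4, 6]))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_vertex_star_cutset_terms_vanish(self, seed, n):
        """A term holding all but one edge of a vertex star (a cut-set)
        has zero coefficient.  Loops are excluded: a loop never crosses
        a cut, so the cut-set at v is its non-loop incident edges."""
        g = random_cubic_multigraph(n, seed)
        ch = chain_polynomial(g)
        stars = {
            v: frozenset(
                lab for u2, v2, lab in g.edges if u2 != v2 and v in (u2, v2)
            )
            for v in g.vertices
        }
        for mono, coeff in ch.terms().items():
            support = {lab for lab, _ in mono}
            for star in stars.values():
                if star and len(star & support) == len(star) - 1:
                    # cut-set minus exactly one edge: must not happen
                    raise AssertionError(
                        f"term {mono} holds all but one of cut-set {sorted(star)}"
                    )

    def test_disconnected_graph_is_product_of_components(self, theta):
        pair = LabeledMultigraph(
            (0, 1, 2, 3),
            (
                (0, 1, "a1"),
                (0, 1, "a2"),
                (0, 1, "a3"),
                (2, 3, "c1"),
                (2, 3, "c2"),
                (2, 3, "c3"),
            ),
        )
        theta2 = chain_polynomial(
            LabeledMultigraph((2, 3), ((2, 3, "c1"), (2, 3, "c2"), (2, 3, "c3")))
        )
        assert chain_polynomial(pair) == chain_polynomial(theta) * theta2


class TestChainReplace:
    def test_theta_step1_merged_substitution(self, theta):
        """Subdividing all three parallel edges into b1-a-b2 chains (with
        the two subdivision labels shared per end-vertex) gives the
        published a³b1³b2³ - 3ωab1b2 + ω² + ω."""
        ch = chain_polynomial(theta)
        rep = ChainPolynomial(
            {(("a", 1), ("b1", 1), ("b2", 1)): OmegaPolynomial.one()}
        )
        star = ch.substitute("a1", rep).substitute("a2", rep).substitute("a3", rep)
        a, b1, b2 = sympy.symbols("a b1 b2")
        expected = a**3 * b1**3 * b2**3 - 3 * w * a * b1 * b2 + w**2 + w
        assert sympy.expand(star.to_sympy(w) - expected) == 0

    def test_identity_replacement(self, tetrahedron):
        ch = chain_polynomial(tetrahedron)
        assert chain_replace(ch, "a1", ["a1"]) == ch

    def test_collapse_expand_round_trip(self, tetrahedron):
        ch = chain_polynomial(tetrahedron)
        expanded = chain_replace(ch, "a1", ["p", "q", "r"])
        # converse: collapse the chain product p·q·r back into one edge
        restored = (
            expanded.substitute("p", ChainPolynomial.label("a1"))
            .substitute("q", ChainPolynomial.one())
            .substitute("r", ChainPolynomial.one())
        )
        assert restored == ch

    def test_chain_replace_matches_subdivided_graph(self):
        """Replacing an edge label by a length-2 chain gives the chain
        polynomial of the graph with that edge subdivided."""
        ch = chain_polynomial(TRIANGLE)
        replaced = chain_replace(ch, "x", ["x1", "x2"])
        subdivided = LabeledMultigraph(
            (0, 1, 2, 3),
            ((0, 3, "x1"), (3, 1, "x2"), (1, 2, "y"), (2, 0, "z")),
        )
        assert replaced == chain_polynomial(subdivided)

    def test_colliding_chain_label_rejected(self, theta):
        ch = chain_polynomial(theta)
        with pytest.raises(Exception, match="collides"):
            chain_replace(ch, "a1", ["a2", "fresh"])


class TestYDelta:
    def test_star_becomes_triangle(self):
        ch_star = chain_polynomial(STAR_K13)
        assert y_delta(ch_star, "x", "y", "z") == chain_polynomial(TRIANGLE)

    def test_theta_star_double_transform_published(self, theta):
        """Both degree-3 vertices of the subdivided theta transformed in
        turn give the published a³(b³-ω)² - 3ωa(b²+b-ω-1)² + (ω²+ω)(3b-ω-2)²,
        after merging per-vertex triangle labels."""
        # subdivided theta with distinct labels per new edge
        ch = chain_polynomial(theta)
        for k in ("1", "2", "3"):
            rep = ChainPolynomial(
                {
                    ((f"a", 1), (f"p{k}", 1), (f"q{k}", 1)): OmegaPolynomial.one()
                }
            )
            ch = ch.substitute(f"a{k}", rep)
        ch = y_delta(ch, "p1", "p2", "p3")
        ch = y_delta(ch, "q1", "q2", "q3")
        collapsed = ch.rename_labels(
            {lab: "b" for lab in ("p1", "p2", "p3", "q1", "q2", "q3")}
        )
        a, b = sympy.symbols("a b")
        expected = (
            a**3 * (b**3 - w) ** 2
            - 3 * w * a * (b**2 + b - w - 1) ** 2
            + (w**2 + w) * (3 * b - w - 2) ** 2
        )
        assert sympy.expand(collapsed.to_sympy(w) - expected) == 0

    def test_constant_only_polynomial(self):
        c = OmegaPolynomial({0: 5, 2: -1})
        out = y_delta(ChainPolynomial.from_omega(c), "x", "y", "z")
        x, y, z = sympy.symbols("x y z")
        expected = c.to_sympy(w) * (x + y + z - w - 2)
        assert sympy.expand(out.to_sympy(w) - expected) == 0

    def test_cross_term_rejected(self):
        bad = ChainPolynomial(
            {(("x", 1), ("y", 1)): OmegaPolynomial.one()}
        )
        with pytest.raises(ConsistencyError, match="two of"):
            y_delta(bad, "x", "y", "z")

    def test_matches_structural_transform(self):
        """Y-Δ on the chain polynomial equals the chain polynomial of the
        structurally transformed graph (K4 with one vertex opened to a Y)."""
        # K4 minus vertex 0's star, plus a Y at new vertex 9
        g_y = LabeledMultigraph(
            (1, 2, 3, 9),
            (
                (9, 2, "x"),
                (9, 3, "y"),
                (9, 1, "z"),
                (1, 3, "a4"),
                (1, 2, "a5"),
                (2, 3, "a6"),
            ),
        )
        # triangle edge x joins the former neighbours of y and z, etc.
        g_delta = LabeledMultigraph(
            (1, 2, 3),
            (
                (1, 3, "x"),
                (1, 2, "y"),
                (2, 3, "z"),
                (1, 3, "a4"),
                (1, 2, "a5"),
                (2, 3, "a6"),
            ),
        )
        transformed = y_delta(chain_polynomial(g_y), "x", "y", "z")
        assert transformed == chain_polynomial(g_delta)
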