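"""Two-label chain polynomial of a truncated cubic graph by substitution.

Truncating a cubic graph G (subdivide every edge twice, then Y-Δ every
original vertex) produces a graph G' with 2m vertices and 3m edges.  If
the original edges of G are all given the label a and the new triangle
edges the label b, the chain polynomial of G' follows from the chain
polynomial of G by pure bookkeeping: a term of Ch(G) whose label
support is the edge subset U, with ω-coefficient F, contributes

    F · a^|U| · (b³-ω)^p · (b²+b-ω-1)^q · (3b-ω-2)^(n-p-q)

where p (resp. q) counts the vertices of G with all three (resp.
exactly one) of their incident edges in U.  No vertex can meet exactly
two support edges: the star of a vertex is a cut-set, so such terms
have zero coefficient — the code asserts this rather than assuming it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import sympy

from .chain import ChainPolynomial, chain_replace, chain_polynomial
from .errors import ConsistencyError, PreconditionError
from .graphs import LabeledMultigraph
from .omega import OmegaPolynomial

# The three ω-b factors produced by the substitution, expanded in b.
#   (b³ - ω), (b² + b - ω - 1), (3b - ω - 2)
_F_TRIANGLE = {3: OmegaPolynomial.one(), 0: -OmegaPolynomial.omega()}
_F_SINGLE = {
    2: OmegaPolynomial.one(),
    1: OmegaPolynomial.one(),
    0: -OmegaPolynomial.omega() - OmegaPolynomial.one(),
}
_F_EMPTY = {
    1: OmegaPolynomial.const(3),
    0: -OmegaPolynomial.omega() - OmegaPolynomial.const(2),
}


def _bpoly_mul(p: dict[int, OmegaPolynomial], q: dict[int, OmegaPolynomial]):
    out: dict[int, OmegaPolynomial] = {}
    for e1, c1 in p.items():
        for e2, c2 in q.items():
            e = e1 + e2
            nv = out.get(e, OmegaPolynomial.zero()) + c1 * c2
            if nv:
                out[e] = nv
            elif e in out:
                del out[e]
    return out


def _bpoly_pow(p: dict[int, OmegaPolynomial], n: int):
    out = {0: OmegaPolynomial.one()}
    base = p
    while n:
        if n & 1:
            out = _bpoly_mul(out, base)
        base = _bpoly_mul(base, base)
        n >>= 1
    return out


@dataclass
class TwoLabelChainPolynomial:
    """Chain polynomial of a truncated cubic graph in the labels a, b.

    Stored both factored — a list of ``(F, a_exp, p, q, r)`` entries
    meaning ``F · a^a_exp · (b³-ω)^p · (b²+b-ω-1)^q · (3b-ω-2)^r`` — and
    expanded as ``{(a_exp, b_exp): OmegaPolynomial}``.  Equality of the
    two forms is a structural self-check.
    """

    factored: list[tuple[OmegaPolynomial, int, int, int, int]]
    expanded: dict[tuple[int, int], OmegaPolynomial]
    n: int
    m: int
    source: str | None = field(default=None, compare=False)

    def expand_factored(self) -> dict[tuple[int, int], OmegaPolynomial]:
        out: dict[tuple[int, int], OmegaPolynomial] = {}
        for coef, a_exp, p, q, r in self.factored:
            bpoly = _bpoly_mul(
                _bpoly_mul(_bpoly_pow(_F_TRIANGLE, p), _bpoly_pow(_F_SINGLE, q)),
                _bpoly_pow(_F_EMPTY, r),
            )
            for b_exp, c in bpoly.items():
                key = (a_exp, b_exp)
                nv = out.get(key, OmegaPolynomial.zero()) + coef * c
                if nv:
                    out[key] = nv
                elif key in out:
                    del out[key]
        return out

    def self_check(self) -> None:
        if self.expand_factored() != self.expanded:
            raise ConsistencyError("factored and expanded two-label forms disagree")

    def coefficient(self, a_exp: int, b_exp: int) -> OmegaPolynomial:
        return self.expanded.get((a_exp, b_exp), OmegaPolynomial.zero())

    def as_chain_polynomial(self) -> ChainPolynomial:
        """The expanded form as a generic polynomial in the labels a, b."""
        terms = {}
        for (a_exp, b_exp), coef in self.expanded.items():
            mono = tuple(
                (lab, e) for lab, e in (("a", a_exp), ("b", b_exp)) if e
            )
            terms[mono] = coef
        return ChainPolynomial(terms)

    def evaluate(self, a_val: int, b_val: int, w_val) -> object:
        """Exact evaluation of the expanded form (ints / sympy exprs)."""
        total = 0
        for (a_exp, b_exp), coef in self.expanded.items():
            total = total + coef(w_val) * a_val**a_exp * b_val**b_exp
        return total

    def to_sympy(self, a=None, b=None, w=None):
        a = sympy.Symbol("a") if a is None else a
        b = sympy.Symbol("b") if b is None else b
        w = sympy.Symbol("omega") if w is None else w
        return sympy.expand(
            sympy.Add(
                *(
                    coef.to_sympy(w) * a**ae * b**be
                    for (ae, be), coef in self.expanded.items()
                )
            )
        )

    def to_json_dict(self) -> dict:
        return {
            "n": self.n,
            "m": self.m,
            "factored": [
                {
                    "omega_coeff": {str(e): v for e, v in sorted(F.coeffs().items())},
                    "a_exp": a_exp,
                    "triangle_exp": p,
                    "single_exp": q,
                    "empty_exp": r,
                }
                for F, a_exp, p, q, r in self.factored
            ],
        }


def _check_truncatable(graph: LabeledMultigraph) -> None:
    if graph.has_loops():
        loop = next(lab for u, v, lab in graph.edges if u == v)
        raise PreconditionError(
            f"truncation substitution is undefined for loops (edge {loop!r})"
        )
    if not graph.is_cubic():
        v, d = next((v, d) for v, d in graph.degrees().items() if d != 3)
        raise PreconditionError(
            f"truncation substitution needs a cubic graph; vertex {v} has degree {d}"
        )


def _vertex_support_counts(
    graph: LabeledMultigraph, support: frozenset[str]
) -> tuple[int, int]:
    """(p, q): vertices with 3 resp. exactly 1 incident edge in support.

    Raises if any vertex meets exactly 2 support edges: the vertex star
    is a cut-set, so a valid chain polynomial has no such term.
    """
    p = q = 0
    for v in graph.vertices:
        k = sum(1 for lab in graph.incident_labels(v) if lab in support)
        if k == 3:
            p += 1
        elif k == 1:
            q += 1
        elif k == 2:
            raise ConsistencyError(
                f"term with support {sorted(support)} meets exactly 2 edges at "
                f"vertex {v}; input polynomial is not a chain polynomial of this graph"
            )
    return p, q


def truncate_chain(
    graph: LabeledMultigraph, poly: ChainPolynomial | None = None
) -> TwoLabelChainPolynomial:
    """Two-label chain polynomial of the truncation of a cubic graph.

    ``poly`` defaults to ``chain_polynomial(graph)``; passing it in
    explicitly allows reuse when several transforms share one graph.
    """
    _check_truncatable(graph)
    if poly is None:
        poly = chain_polynomial(graph)
    n = graph.n_vertices
    factored_map: dict[tuple[int, int, int, int], OmegaPolynomial] = {}
    for mono, coef in poly.terms().items():
        support = frozenset(lab for lab, _ in mono)
        p, q = _vertex_support_counts(graph, support)
        key = (len(support), p, q, n - p - q)
        nv = factored_map.get(key, OmegaPolynomial.zero()) + coef
        if nv:
            factored_map[key] = nv
        elif key in factored_map:
            del factored_map[key]
    factored = [
        (coef, a_exp, p, q, r)
        for (a_exp, p, q, r), coef in sorted(factored_map.items(), reverse=True)
    ]
    result = TwoLabelChainPolynomial(
        factored=factored,
        expanded={},
        n=n,
        m=graph.n_edges,
        source=graph.name,
    )
    result.expanded = result.expand_factored()
    return result


def truncate_chain_stepwise(
    graph: LabeledMultigraph, poly: ChainPolynomial | None = None
) -> tuple[ChainPolynomial, ChainPolynomial, TwoLabelChainPolynomial]:
    """The same computation exposed step by step.

    Step 1: replace each original edge label a_k (with end-vertices v_i,
    v_j) by the length-3 chain b_i · a · b_j, giving Ch(G*).  Step 2:
    collapse b_k³ -> x and b_k -> y, giving a polynomial in a, x, y, ω;
    any b_k² would flag an invalid input.  Step 3 (folded into the
    returned two-label polynomial): x -> b³-ω, y -> b²+b-ω-1, and each
    term is topped up by (3b-ω-2) to total vertex weight n.
    """
    _check_truncatable(graph)
    if poly is None:
        poly = chain_polynomial(graph)
    # Step 1 via chain replacement, one edge at a time.  The same b_i is
    # reused by all edges at vertex v_i, so substitute directly (the
    # fresh-label collision check does not apply to this merged form).
    star = poly
    for u, v, lab in graph.edges:
        replacement = ChainPolynomial(
            {
                tuple(sorted(((f"b{u}", 1), ("a", 1), (f"b{v}", 1)))): OmegaPolynomial.one()
            }
        )
        star = star.substitute(lab, replacement)
    # Step 2: per-vertex exponent bookkeeping.
    star2 = ChainPolynomial.zero()
    for mono, coef in star.terms().items():
        a_exp = 0
        x_exp = y_exp = 0
        for lab, e in mono:
            if lab == "a":
                a_exp = e
            elif e == 3:
                x_exp += 1
            elif e == 1:
                y_exp += 1
            else:
                raise ConsistencyError(
                    f"vertex label {lab!r} has exponent {e}; for nonzero terms "
                    "the per-vertex exponent cannot be 2"
                )
        mono2 = tuple(
            (lab, e)
            for lab, e in (("a", a_exp), ("x", x_exp), ("y", y_exp))
            if e
        )
        star2 = star2 + ChainPolynomial({mono2: coef})
    # Step 3: assemble the factored two-label form from Ch(G**).
    n = graph.n_vertices
    factored = []
    for mono, coef in sorted(star2.terms().items(), reverse=True):
        a_exp = x_exp = y_exp = 0
        for lab, e in mono:
            if lab == "a":
                a_exp = e
            elif lab == "x":
                x_exp = e
            elif lab == "y":
                y_exp = e
        factored.append((coef, a_exp, x_exp, y_exp, n - x_exp - y_exp))
    result = TwoLabelChainPolynomial(
        factored=factored, expanded={}, n=n, m=graph.n_edges, source=graph.name
    )
    result.expanded = result.expand_factored()
    return star, star2, result
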