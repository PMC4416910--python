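"""Chain and flow polynomials of labeled multigraphs.

The chain polynomial of a labeled graph G is the sum, over all subsets
Y of the edge set, of the flow polynomial (evaluated at t = 1 - ω) of
the spanning subgraph <Y> times the product of the labels of the edges
NOT in Y.  It is multilinear in the edge labels and its label-free term
is the flow polynomial of G itself.

Two independent routes are provided: a deletion-contraction recursion
(the workhorse) and the literal subset sum (a brute-force cross-check
for small graphs).  Chain-replacement (a path of degree-2 vertices is
interchangeable with a single edge carrying the product of its labels)
and the Y-Δ transform of a degree-3 vertex are implemented as symbolic
substitutions on chain polynomials.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import sympy

from .errors import ConsistencyError, PreconditionError
from .graphs import Edge, LabeledMultigraph
from .omega import OmegaPolynomial

# A monomial in edge labels: sorted tuple of (label, exponent), exponents >= 1.
Monomial = tuple[tuple[str, int], ...]

_ONE: Monomial = ()


def _monomial(labels: Iterable[tuple[str, int]]) -> Monomial:
    merged: dict[str, int] = {}
    for lab, e in labels:
        if e:
            merged[lab] = merged.get(lab, 0) + e
    return tuple(sorted(merged.items()))


class ChainPolynomial:
    """Polynomial in edge labels with OmegaPolynomial coefficients.

    For an actual graph the polynomial is multilinear (exponent <= 1 per
    label); chain replacement can introduce higher powers, so general
    exponents are supported.
    """

    __slots__ = ("_terms",)

    def __init__(self, terms: Mapping[Monomial, OmegaPolynomial] | None = None):
        t: dict[Monomial, OmegaPolynomial] = {}
        if terms:
            for mono, coef in terms.items():
                if coef:
                    t[mono] = coef
        self._terms = t

    # -- constructors -------------------------------------------------
    @classmethod
    def zero(cls) -> "ChainPolynomial":
        return cls()

    @classmethod
    def one(cls) -> "ChainPolynomial":
        return cls({_ONE: OmegaPolynomial.one()})

    @classmethod
    def from_omega(cls, coef: OmegaPolynomial) -> "ChainPolynomial":
        return cls({_ONE: coef})

    @classmethod
    def label(cls, lab: str, exp: int = 1) -> "ChainPolynomial":
        return cls({_monomial([(lab, exp)]): OmegaPolynomial.one()})

    # -- queries ------------------------------------------------------
    def terms(self) -> dict[Monomial, OmegaPolynomial]:
        return dict(self._terms)

    def coefficient(self, labels: Iterable[str] | Monomial) -> OmegaPolynomial:
        """Coefficient of the given monomial (bare labels mean exponent 1)."""
        key = _monomial(
            (lab, 1) if isinstance(lab, str) else lab for lab in labels
        )
        return self._terms.get(key, OmegaPolynomial.zero())

    @property
    def constant_term(self) -> OmegaPolynomial:
        """The label-free coefficient; for Ch(G) this is the flow polynomial."""
        return self._terms.get(_ONE, OmegaPolynomial.zero())

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(lab for mono in self._terms for lab, _ in mono)

    def is_multilinear(self) -> bool:
        return all(e <= 1 for mono in self._terms for _, e in mono)

    def __bool__(self) -> bool:
        return bool(self._terms)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChainPolynomial):
            return NotImplemented
        return self._terms == other._terms

    def __hash__(self):
        return hash(frozenset(self._terms.items()))

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other: "ChainPolynomial") -> "ChainPolynomial":
        t = dict(self._terms)
        for mono, coef in other._terms.items():
            nv = t.get(mono, OmegaPolynomial.zero()) + coef
            if nv:
                t[mono] = nv
            elif mono in t:
                del t[mono]
        out = ChainPolynomial.__new__(ChainPolynomial)
        out._terms = t
        return out

    def __neg__(self) -> "ChainPolynomial":
        out = ChainPolynomial.__new__(ChainPolynomial)
        out._terms = {mono: -coef for mono, coef in self._terms.items()}
        return out

    def __sub__(self, other: "ChainPolynomial") -> "ChainPolynomial":
        return self + (-other)

    def __mul__(self, other) -> "ChainPolynomial":
        if isinstance(other, (int, OmegaPolynomial)):
            coef = (
                OmegaPolynomial.const(other) if isinstance(other, int) else other
            )
            out = ChainPolynomial.__new__(ChainPolynomial)
            out._terms = {}
            for mono, c in self._terms.items():
                nv = c * coef
                if nv:
                    out._terms[mono] = nv
            return out
        if not isinstance(other, ChainPolynomial):
            return NotImplemented
        t: dict[Monomial, OmegaPolynomial] = {}
        for m1, c1 in self._terms.items():
            for m2, c2 in other._terms.items():
                mono = _monomial(list(m1) + list(m2))
                nv = t.get(mono, OmegaPolynomial.zero()) + c1 * c2
                if nv:
                    t[mono] = nv
                elif mono in t:
                    del t[mono]
        out = ChainPolynomial.__new__(ChainPolynomial)
        out._terms = t
        return out

    __rmul__ = __mul__

    # -- substitutions ------------------------------------------------
    def substitute(self, target: str, replacement: "ChainPolynomial") -> "ChainPolynomial":
        """Replace every power ``target**e`` by ``replacement**e``."""
        out = ChainPolynomial.zero()
        for mono, coef in self._terms.items():
            rest = [(lab, e) for lab, e in mono if lab != target]
            exp = next((e for lab, e in mono if lab == target), 0)
            term = ChainPolynomial({_monomial(rest): coef})
            if exp:
                rep = ChainPolynomial.one()
                for _ in range(exp):
                    rep = rep * replacement
                term = term * rep
            out = out + term
        return out

    def rename_labels(self, mapping: Mapping[str, str]) -> "ChainPolynomial":
        """Relabel (and possibly merge) labels; exponents of merged labels add."""
        out_terms: dict[Monomial, OmegaPolynomial] = {}
        for mono, coef in self._terms.items():
            new = _monomial((mapping.get(lab, lab), e) for lab, e in mono)
            nv = out_terms.get(new, OmegaPolynomial.zero()) + coef
            if nv:
                out_terms[new] = nv
            elif new in out_terms:
                del out_terms[new]
        return ChainPolynomial(out_terms)

    def set_label_to_one(self, target: str) -> "ChainPolynomial":
        return self.substitute(target, ChainPolynomial.one())

    # -- conversion ---------------------------------------------------
    def to_sympy(self, w=None):
        w = sympy.Symbol("omega") if w is None else w
        total = sympy.Integer(0)
        for mono, coef in self._terms.items():
            prod = coef.to_sympy(w)
            for lab, e in mono:
                prod *= sympy.Symbol(lab) ** e
            total += prod
        return sympy.expand(total)

    def to_json_dict(self) -> dict:
        out = {}
        for mono, coef in sorted(self._terms.items()):
            key = "*".join(f"{lab}^{e}" if e > 1 else lab for lab, e in mono) or "1"
            out[key] = {str(e): v for e, v in sorted(coef.coeffs().items())}
        return out

    def __repr__(self) -> str:
        if not self._terms:
            return "0"
        parts = []
        for mono, coef in sorted(self._terms.items()):
            m = "*".join(f"{lab}^{e}" if e > 1 else lab for lab, e in mono)
            parts.append(f"({coef!r})*{m}" if m else f"({coef!r})")
        return " + ".join(parts)


# ---------------------------------------------------------------------
# Flow polynomial
# ---------------------------------------------------------------------

def _canonical(edges: Sequence[Edge]) -> tuple:
    return tuple(sorted((min(u, v), max(u, v), lab) for u, v, lab in edges))


def _components(edges: Sequence[Edge]) -> list[list[Edge]]:
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v, _ in edges:
        parent.setdefault(u, u)
        parent.setdefault(v, v)
    for u, v, _ in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups: dict[int, list[Edge]] = {}
    for e in edges:
        groups.setdefault(find(e[0]), []).append(e)
    return list(groups.values())


def _contract(edges: Sequence[Edge], u: int, v: int) -> list[Edge]:
    """Merge vertex v into u (u kept), preserving labels; may create loops."""
    out = []
    for a, b, lab in edges:
        a2 = u if a == v else a
        b2 = u if b == v else b
        out.append((a2, b2, lab))
    return out


def _flow_rec(edges: tuple[Edge, ...], memo: dict) -> OmegaPolynomial:
    if not edges:
        return OmegaPolynomial.one()
    key = _canonical(edges)
    if key in memo:
        return memo[key]
    comps = _components(edges)
    if len(comps) > 1:
        result = OmegaPolynomial.one()
        for comp in comps:
            result = result * _flow_rec(tuple(comp), memo)
        memo[key] = result
        return result
    # Loops multiply the flow polynomial by (t - 1) = -ω.
    loops = [e for e in edges if e[0] == e[1]]
    if loops:
        rest = tuple(e for e in edges if e[0] != e[1])
        result = (-OmegaPolynomial.omega()) ** len(loops) * _flow_rec(rest, memo)
        memo[key] = result
        return result
    # Deletion-contraction on the smallest-labeled edge: F = F(G/e) - F(G-e).
    u, v, lab = min(edges, key=lambda e: e[2])
    others = [e for e in edges if e[2] != lab]
    contracted = tuple(_contract(others, min(u, v), max(u, v)))
    deleted = tuple(others)
    result = _flow_rec(contracted, memo) - _flow_rec(deleted, memo)
    memo[key] = result
    return result


def flow_polynomial(graph: LabeledMultigraph) -> OmegaPolynomial:
    """Flow polynomial of the graph, evaluated at t = 1 - ω.

    Zero whenever the graph has a bridge; a single loop gives -ω; the
    theta graph gives ω² + ω.  Multiplicative over components and blocks.
    """
    return _flow_rec(tuple(graph.edges), {})


def flow_polynomial_of_edges(edges: Sequence[Edge]) -> OmegaPolynomial:
    return _flow_rec(tuple(edges), {})


# ---------------------------------------------------------------------
# Chain polynomial by deletion-contraction
# ---------------------------------------------------------------------

def _chain_rec(edges: tuple[Edge, ...], memo: dict) -> ChainPolynomial:
    if not edges:
        return ChainPolynomial.one()
    key = _canonical(edges)
    if key in memo:
        return memo[key]
    comps = _components(edges)
    if len(comps) > 1:
        result = ChainPolynomial.one()
        for comp in comps:
            result = result * _chain_rec(tuple(comp), memo)
        memo[key] = result
        return result
    loops = [e for e in edges if e[0] == e[1]]
    if loops:
        # A loop with label a contributes a factor (a - ω).
        rest = tuple(e for e in edges if e[0] != e[1])
        result = _chain_rec(rest, memo)
        for _, _, lab in loops:
            factor = ChainPolynomial.label(lab) + ChainPolynomial.from_omega(
                -OmegaPolynomial.omega()
            )
            result = result * factor
        memo[key] = result
        return result
    # Pivot on the lexicographically smallest non-loop label:
    # Ch(G) = (a - 1) Ch(G - a) + Ch(G / a).
    u, v, lab = min(edges, key=lambda e: e[2])
    others = [e for e in edges if e[2] != lab]
    deleted = _chain_rec(tuple(others), memo)
    contracted = _chain_rec(tuple(_contract(others, min(u, v), max(u, v))), memo)
    a_minus_1 = ChainPolynomial.label(lab) - ChainPolynomial.one()
    result = a_minus_1 * deleted + contracted
    memo[key] = result
    return result


def chain_polynomial(graph: LabeledMultigraph) -> ChainPolynomial:
    """Chain polynomial of a labeled multigraph by deletion-contraction.

    Base cases: the edgeless graph is 1, a loop labeled a is (a - ω),
    and the polynomial is multiplicative over components.  The result is
    multilinear in the edge labels and its constant term is the flow
    polynomial of the graph.
    """
    result = _chain_rec(tuple(graph.edges), {})
    if not result.is_multilinear():
        raise ConsistencyError("chain polynomial of a graph must be multilinear")
    return result


def chain_polynomial_subset_sum(graph: LabeledMultigraph) -> ChainPolynomial:
    """Literal definition of the chain polynomial: sum over all edge
    subsets Y of flow(<Y>) times the product of labels outside Y.

    Exponential in the edge count; intended as an independent
    cross-check for graphs with at most ~12 edges.
    """
    if graph.n_edges > 16:
        raise PreconditionError("subset-sum route is limited to 16 edges")
    edges = graph.edges
    total = ChainPolynomial.zero()
    for r in range(len(edges) + 1):
        for ys in combinations(range(len(edges)), r):
            yset = set(ys)
            flow = flow_polynomial_of_edges([edges[i] for i in yset])
            if not flow:
                continue
            mono = _monomial(
                (edges[i][2], 1) for i in range(len(edges)) if i not in yset
            )
            total = total + ChainPolynomial({mono: flow})
    return total


# ---------------------------------------------------------------------
# Symbolic graph moves on chain polynomials
# ---------------------------------------------------------------------

def chain_replace(
    poly: ChainPolynomial, target: str, chain: Sequence[str]
) -> ChainPolynomial:
    """Replace the label ``target`` by the product of ``chain`` labels.

    This mirrors subdividing the target edge into a path whose edges
    carry the chain labels (or, run with a single fresh label, the
    converse collapse of a path to one edge).
    """
    if target not in poly.labels:
        raise PreconditionError(f"label {target!r} does not occur in the polynomial")
    for lab in chain:
        if lab != target and lab in poly.labels:
            raise PreconditionError(f"chain label {lab!r} collides with an existing label")
    replacement = ChainPolynomial({_monomial((lab, 1) for lab in chain): OmegaPolynomial.one()})
    return poly.substitute(target, replacement)


def y_delta(poly: ChainPolynomial, x: str, y: str, z: str) -> ChainPolynomial:
    """Y-Δ transform on the chain polynomial of a graph with a degree-3
    vertex whose incident edges carry labels x, y, z.

    The polynomial must decompose as P·xyz + A·x + B·y + C·z + V (terms
    holding exactly two of the three labels are forbidden: {x, y, z} is
    a cut-set, so such terms vanish).  The image is
    P(xyz-ω) + A(yz+x-ω-1) + B(xz+y-ω-1) + C(xy+z-ω-1) + V(x+y+z-ω-2).
    """
    trip = (x, y, z)
    parts: dict[frozenset, dict] = {
        frozenset(trip): {},
        frozenset([x]): {},
        frozenset([y]): {},
        frozenset([z]): {},
        frozenset(): {},
    }
    for mono, coef in poly.terms().items():
        present = frozenset(lab for lab, _ in mono if lab in trip)
        for lab, e in mono:
            if lab in trip and e > 1:
                raise ConsistencyError(
                    f"label {lab!r} appears with exponent {e}; not a valid Y-vertex polynomial"
                )
        if len(present) == 2:
            raise ConsistencyError(
                f"term with exactly two of {trip} has nonzero coefficient; "
                "{x,y,z} cannot be the star of a degree-3 vertex"
            )
        rest = _monomial((lab, e) for lab, e in mono if lab not in trip)
        parts[present][rest] = coef
    P = ChainPolynomial(parts[frozenset(trip)])
    A = ChainPolynomial(parts[frozenset([x])])
    B = ChainPolynomial(parts[frozenset([y])])
    C = ChainPolynomial(parts[frozenset([z])])
    V = ChainPolynomial(parts[frozenset()])

    one = ChainPolynomial.one()
    w = ChainPolynomial.from_omega(OmegaPolynomial.omega())
    lx, ly, lz = (ChainPolynomial.label(l) for l in trip)
    return (
        P * (lx * ly * lz - w)
        + A * (ly * lz + lx - w - one)
        + B * (lx * lz + ly - w - one)
        + C * (lx * ly + lz - w - one)
        + V * (lx + ly + lz - w - one - one)
    )
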