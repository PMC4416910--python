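"""Homfly, Conway and Jones polynomials of double-crossover 3-regular links.

A double-crossover 4-turn link is built on a plane cubic graph by
covering every original edge with the double-crossover 2-tangle T1 and
every edge created by truncation with the vertical 2-tangle T2 (16
crossings per original edge in total).  With all crossings left-handed
("negative", the antiparallel dsDNA orientation), the Homfly polynomial
of the link is obtained from the two-label chain polynomial of the
truncated graph by the substitutions

    ω = 1 - δ²,      δ = (v⁻¹ - v)/z,
    a = (v⁻² - 1 - z²(1 + v² + v⁴ + v⁶)) / (v⁻² - 1 - 2z²(v² + 1)),
    b = v⁴,

followed by multiplication with δ⁻¹·[(v⁻³ - v⁻¹ - 2z²(v + v⁻¹))/(v¹³ - v¹⁵)]^x
where x is the number of original edges.  Every intermediate here is a
rational function, but the result is a genuine Laurent polynomial in
(v, z); the implementation clears all denominators first and performs a
single exact division at the end, so a substitution bug surfaces as a
loud non-divisibility error instead of a wrong polynomial.

Specializations: the Conway polynomial is P(1, z) and the Jones
polynomial is P(t, t^½ - t^-½), kept exact in s = t^½.  The positive
(all right-handed) link's polynomial follows by v -> -v⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy

from .errors import ConsistencyError, PreconditionError
from .graphs import LabeledMultigraph
from .laurent import LaurentPolynomial1, LaurentPolynomial2
from .truncation import TwoLabelChainPolynomial, truncate_chain

# ---------------------------------------------------------------------
# Building blocks of the substitution, all denominators pre-cleared.
#   ω = Wn / Wd          Wn = v²z² - (1-v²)²,     Wd = v²z²
#   a = An / Ad          An = 1 - v² - z²(v²+v⁴+v⁶+v⁸)
#                        Ad = 1 - v² - 2z²(v²+v⁴)
# Note v³·(v⁻³ - v⁻¹ - 2z²(v+v⁻¹)) = Ad: the edge-weight numerator and
# the denominator of a are the same polynomial, which is what makes the
# final division collapse to (1-v²)^(x+1) alone.
# ---------------------------------------------------------------------

_WD = LaurentPolynomial2({(2, 2): 1})
_WN = _WD - (LaurentPolynomial2({(0, 0): 1, (2, 0): -1}) ** 2)
_AN = LaurentPolynomial2(
    {(0, 0): 1, (2, 0): -1, (2, 2): -1, (4, 2): -1, (6, 2): -1, (8, 2): -1}
)
_AD = LaurentPolynomial2({(0, 0): 1, (2, 0): -1, (2, 2): -2, (4, 2): -2})
_ONE_MINUS_V2 = LaurentPolynomial2({(0, 0): 1, (2, 0): -1})

# Numerators of the three ω-b factors over the common denominator Wd,
# with b = v⁴ already substituted:
#   b³ - ω        -> v¹²·Wd - Wn
#   b² + b - ω -1 -> (v⁸ + v⁴ - 1)·Wd - Wn
#   3b - ω - 2    -> (3v⁴ - 2)·Wd - Wn
_N_TRIANGLE = _WD.shift(12, 0) - _WN
_N_SINGLE = (
    _WD.shift(8, 0) + _WD.shift(4, 0) - _WD - _WN
)
_N_EMPTY = 3 * _WD.shift(4, 0) - 2 * _WD - _WN


def homfly_double_crossover(
    graph: LabeledMultigraph,
    orientation: str = "negative",
    truncated: TwoLabelChainPolynomial | None = None,
) -> LaurentPolynomial2:
    """Homfly polynomial of the double-crossover 4-turn link on a cubic graph.

    ``orientation`` is "negative" (all left-handed crossings, the DNA
    default) or "positive" (the mirror, via v -> -v⁻¹).  ``truncated``
    may pass in a precomputed two-label chain polynomial of the
    truncation to avoid recomputation.
    """
    if orientation not in ("negative", "positive"):
        raise PreconditionError(f"unknown orientation {orientation!r}")
    if truncated is None:
        truncated = truncate_chain(graph)
    m = truncated.m

    # Homogenize all terms over the common denominator Wd^D · Ad^m.
    degs = [F.degree + p + q + r for F, _, p, q, r in truncated.factored]
    D = max(degs) if degs else 0
    wn_pow = {e: _WN**e for e in range(D + 1)}
    wd_pow = {e: _WD**e for e in range(D + 1)}
    num = LaurentPolynomial2.zero()
    for F, a_exp, p, q, r in truncated.factored:
        body = (_N_TRIANGLE**p) * (_N_SINGLE**q) * (_N_EMPTY**r)
        body = body * (_AN**a_exp) * (_AD ** (m - a_exp))
        # F(ω) with ω = Wn/Wd, topped up to total Wd-weight D - (p+q+r).
        fpart = LaurentPolynomial2.zero()
        top = D - (p + q + r)
        for e, c in F.coeffs().items():
            fpart = fpart + c * wn_pow[e] * wd_pow[top - e]
        num = num + fpart * body
    # P = num · v·z / ((1-v²)^(m+1) · v^(16m + 2D) · z^(2D)):
    # the factor Ad^m of the edge weights cancels the denominator of a^…,
    # and δ⁻¹ = v·z/(1-v²), (v¹³-v¹⁵)^m = v^13m·(1-v²)^m, Wd^D = (v·z)^(2D).
    quotient = num.exquo(_ONE_MINUS_V2 ** (m + 1))
    result = quotient.shift(1 - 16 * m - 2 * D, 1 - 2 * D)
    if orientation == "positive":
        result = result.subs_v_neg_inv()
    return result


def mirror(poly: LaurentPolynomial2) -> LaurentPolynomial2:
    """Homfly polynomial of the mirror image: v -> -v⁻¹."""
    return poly.subs_v_neg_inv()


def conway(poly: LaurentPolynomial2) -> LaurentPolynomial1:
    """Conway polynomial: the Homfly polynomial evaluated at v = 1.

    Negative powers of z must cancel at v = 1; leftovers mean the input
    was not a Homfly polynomial of a link.
    """
    out = poly.eval_v_one()
    if out and out.min_degree < 0:
        raise ConsistencyError(
            "negative z-powers survive at v=1; input is not a Homfly polynomial"
        )
    return out


def jones(poly: LaurentPolynomial2) -> "HalfIntegerLaurent":
    """Jones polynomial via v = t, z = t^½ - t^-½, exact in s = t^½.

    Negative powers of z are handled by clearing z^k first and dividing
    the substituted polynomial exactly by (s - s⁻¹)^k.
    """
    if not poly:
        return HalfIntegerLaurent({})
    k0 = max(0, -poly.min_z_degree)
    shifted = poly.shift(0, k0)  # multiply by z^k0: all z-exponents >= 0
    s_minus_sinv = LaurentPolynomial1({1: 1, -1: -1})
    acc = LaurentPolynomial1.zero()
    zpow: dict[int, LaurentPolynomial1] = {}
    for (ev, ez), cv in shifted.coeffs().items():
        if ez not in zpow:
            zpow[ez] = s_minus_sinv**ez
        acc = acc + cv * LaurentPolynomial1({2 * ev: 1}) * zpow[ez]
    if k0:
        acc = acc.exquo(s_minus_sinv**k0)
    return HalfIntegerLaurent(acc.coeffs())


class HalfIntegerLaurent(LaurentPolynomial1):
    """Laurent polynomial in s = t^½; a one-variable Laurent polynomial
    whose exponents are halved when printed in t."""

    def coefficient_t(self, numerator: int, denominator: int = 1) -> int:
        """Coefficient of t^(numerator/denominator); denominator 1 or 2."""
        if denominator == 1:
            return self.coefficient(2 * numerator)
        if denominator == 2:
            return self.coefficient(numerator)
        raise ValueError("t-exponents are integers or half-integers")

    def to_t_string(self) -> str:
        if not self._c:
            return "0"
        parts = []
        for e in sorted(self._c, reverse=True):
            cv = self._c[e]
            if e == 0:
                body = ""
            elif e % 2 == 0:
                body = f"t^{e // 2}" if e != 2 else "t"
            else:
                body = f"t^({e}/2)"
            if not body:
                parts.append(f"{cv}")
            elif cv in (1, -1):
                parts.append(f"-{body}" if cv == -1 else body)
            else:
                parts.append(f"{cv}*{body}")
        return " + ".join(parts).replace("+ -", "- ")


# ---------------------------------------------------------------------
# Tangle invariants
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class TangleInvariants:
    """Closed forms for the two covering tangles, as sympy expressions.

    T1 is the double-crossover tangle placed on original edges, T2 the
    vertical 2-crossing tangle on truncation edges.  Nu/De are the
    numerator and denominator closures; μ and w are the basis
    coefficients obtained from them via δ = (v⁻¹ - v)/z:

        μ(T) = (δ·Nu(T) - De(T)) / (δ² - 1)
        w(T) = (δ·De(T) - Nu(T)) / (δ·Nu(T) - De(T))
    """

    nu_t1: sympy.Expr
    de_t1: sympy.Expr
    nu_t2: sympy.Expr
    de_t2: sympy.Expr
    mu_t1: sympy.Expr
    mu_t2: sympy.Expr
    w_t1: sympy.Expr
    w_t2: sympy.Expr
    delta: sympy.Expr
    v: sympy.Symbol
    z: sympy.Symbol


def tangle_invariants() -> TangleInvariants:
    """Closure values and basis coefficients of the covering tangles.

    μ and w are *recomputed* from the closures through the defining
    identities and verified against their closed forms; a mismatch
    raises rather than returning inconsistent data.
    """
    v, z = sympy.symbols("v z", positive=True)
    delta = (1 / v - v) / z
    nu_t1 = delta ** -1 * (1 - v**-4) ** 2 + delta**-1 * 2 * v**-4 * (1 - v**-4) + delta * v**-8
    de_t1 = delta ** -2 * (1 - v**-4) ** 2 + 2 * v**-4 * (1 - v**-4) + delta**2 * v**-8
    nu_t2 = sympy.Integer(1)
    de_t2 = delta ** -1 * (1 - v**-4) + delta * v**-4

    def mu_of(nu, de):
        return sympy.cancel((delta * nu - de) / (delta**2 - 1))

    def w_of(nu, de):
        return sympy.cancel((delta * de - nu) / (delta * nu - de))

    mu_t1 = mu_of(nu_t1, de_t1)
    mu_t2 = mu_of(nu_t2, de_t2)
    w_t1 = w_of(nu_t1, de_t1)
    w_t2 = w_of(nu_t2, de_t2)

    closed = {
        "mu_t1": z**2 * (v**-1 + v**-3) ** 2,
        "mu_t2": -z * (v**-1 + v**-3),
        "w_t1": (v**-3 - v**-1 - 2 * z**2 * (v + v**-1)) / (z**3 * (1 + v**2) ** 2),
        "w_t2": -(z**-1) * (v + v**3) ** -1,
    }
    computed = {"mu_t1": mu_t1, "mu_t2": mu_t2, "w_t1": w_t1, "w_t2": w_t2}
    for key, expr in closed.items():
        if sympy.simplify(computed[key] - expr) != 0:
            raise ConsistencyError(f"tangle invariant {key} does not match its closed form")
    return TangleInvariants(
        nu_t1=nu_t1,
        de_t1=de_t1,
        nu_t2=nu_t2,
        de_t2=de_t2,
        mu_t1=mu_t1,
        mu_t2=mu_t2,
        w_t1=w_t1,
        w_t2=w_t2,
        delta=delta,
        v=v,
        z=z,
    )


# ---------------------------------------------------------------------
# Braid index bounds
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class BraidIndexBounds:
    span_v: int
    mfw_lower: int
    crossing_number: int
    ohyama_upper: int
    exact: int | None

    def to_json_dict(self) -> dict:
        return {
            "span_v": self.span_v,
            "mfw_lower": self.mfw_lower,
            "crossing_number": self.crossing_number,
            "ohyama_upper": self.ohyama_upper,
            "exact": self.exact,
        }


def diagram_crossing_number(graph: LabeledMultigraph) -> int:
    """Crossing count of the standard 4-turn diagram: 16 per original edge
    (the double-crossover tangle and its two flanking vertical tangles)."""
    if not graph.is_cubic():
        raise PreconditionError("crossing-number formula applies to cubic graphs")
    return 16 * graph.n_edges


def braid_index_bounds(
    poly: LaurentPolynomial2, crossing_number: int
) -> BraidIndexBounds:
    """MFW lower bound span_v/2 + 1 and Ohyama upper bound 1 + c/2.

    ``exact`` is filled when the two bounds coincide, which pins the
    braid index of the (non-splittable) link.
    """
    if not poly:
        raise PreconditionError("zero polynomial has no v-span")
    if crossing_number % 2:
        raise PreconditionError("crossing number of these diagrams is even")
    span = poly.span_v
    if span % 2:
        raise ConsistencyError(
            f"odd v-span {span}: not the Homfly polynomial of a link diagram "
            "from this pipeline"
        )
    lower = span // 2 + 1
    upper = 1 + crossing_number // 2
    return BraidIndexBounds(
        span_v=span,
        mfw_lower=lower,
        crossing_number=crossing_number,
        ohyama_upper=upper,
        exact=lower if lower == upper else None,
    )
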