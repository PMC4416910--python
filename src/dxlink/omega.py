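"""Exact univariate polynomials in the chain-polynomial variable ω.

Flow polynomials appear throughout this package evaluated at t = 1 - ω,
so every scalar coefficient of a chain polynomial is an integer
polynomial in ω.  Arithmetic is exact (Python integers); no zero
coefficients are ever stored.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import sympy


class OmegaPolynomial:
    """Integer polynomial in ω, stored sparsely as {exponent: coefficient}."""

    __slots__ = ("_c",)

    def __init__(self, coeffs: Mapping[int, int] | None = None):
        c = {}
        if coeffs:
            for e, v in coeffs.items():
                if v:
                    if e < 0:
                        raise ValueError("negative ω exponent")
                    c[int(e)] = int(v)
        self._c = c

    # -- constructors -------------------------------------------------
    @classmethod
    def zero(cls) -> "OmegaPolynomial":
        return cls()

    @classmethod
    def one(cls) -> "OmegaPolynomial":
        return cls({0: 1})

    @classmethod
    def const(cls, n: int) -> "OmegaPolynomial":
        return cls({0: n})

    @classmethod
    def omega(cls, exp: int = 1) -> "OmegaPolynomial":
        return cls({exp: 1})

    # -- queries ------------------------------------------------------
    def coeffs(self) -> dict[int, int]:
        return dict(self._c)

    def coefficient(self, exp: int) -> int:
        return self._c.get(exp, 0)

    @property
    def degree(self) -> int:
        """Degree in ω; -1 for the zero polynomial."""
        return max(self._c) if self._c else -1

    def is_zero(self) -> bool:
        return not self._c

    def __bool__(self) -> bool:
        return bool(self._c)

    # -- arithmetic ---------------------------------------------------
    @staticmethod
    def _coerce(other) -> "OmegaPolynomial":
        if isinstance(other, OmegaPolynomial):
            return other
        if isinstance(other, int):
            return OmegaPolynomial({0: other})
        return NotImplemented  # type: ignore[return-value]

    def __add__(self, other) -> "OmegaPolynomial":
        other = self._coerce(other)
        if other is NotImplemented:
            return NotImplemented
        c = dict(self._c)
        for e, v in other._c.items():
            nv = c.get(e, 0) + v
            if nv:
                c[e] = nv
            elif e in c:
                del c[e]
        out = OmegaPolynomial.__new__(OmegaPolynomial)
        out._c = c
        return out

    __radd__ = __add__

    def __neg__(self) -> "OmegaPolynomial":
        out = OmegaPolynomial.__new__(OmegaPolynomial)
        out._c = {e: -v for e, v in self._c.items()}
        return out

    def __sub__(self, other) -> "OmegaPolynomial":
        other = self._coerce(other)
        if other is NotImplemented:
            return NotImplemented
        return self + (-other)

    def __rsub__(self, other) -> "OmegaPolynomial":
        return (-self) + other

    def __mul__(self, other) -> "OmegaPolynomial":
        other = self._coerce(other)
        if other is NotImplemented:
            return NotImplemented
        c: dict[int, int] = {}
        for e1, v1 in self._c.items():
            for e2, v2 in other._c.items():
                e = e1 + e2
                nv = c.get(e, 0) + v1 * v2
                if nv:
                    c[e] = nv
                elif e in c:
                    del c[e]
        out = OmegaPolynomial.__new__(OmegaPolynomial)
        out._c = c
        return out

    __rmul__ = __mul__

    def __pow__(self, n: int) -> "OmegaPolynomial":
        if n < 0:
            raise ValueError("negative power")
        result = OmegaPolynomial.one()
        base = self
        while n:
            if n & 1:
                result = result * base
            base = base * base
            n >>= 1
        return result

    def __eq__(self, other) -> bool:
        other = self._coerce(other)
        if other is NotImplemented:
            return NotImplemented
        return self._c == other._c

    def __hash__(self) -> int:
        return hash(frozenset(self._c.items()))

    # -- conversion ---------------------------------------------------
    def __call__(self, value):
        """Evaluate at an arbitrary (exact) value: int, Fraction, sympy expr."""
        total = 0
        for e, v in self._c.items():
            total = total + v * value**e
        return total

    def to_sympy(self, w=None):
        w = sympy.Symbol("omega") if w is None else w
        return sympy.Add(*(v * w**e for e, v in self._c.items()))

    @classmethod
    def from_sympy(cls, expr, w) -> "OmegaPolynomial":
        poly = sympy.Poly(sympy.expand(expr), w)
        return cls({int(mono[0]): int(coef) for mono, coef in poly.terms()})

    def __repr__(self) -> str:
        if not self._c:
            return "0"
        parts = []
        for e in sorted(self._c):
            v = self._c[e]
            if e == 0:
                parts.append(f"{v}")
            elif e == 1:
                parts.append(f"{v}*w" if v != 1 else "w")
            else:
                parts.append(f"{v}*w^{e}" if v != 1 else f"w^{e}")
        return " + ".join(parts).replace("+ -", "- ")


def omega_sum(items: Iterable[OmegaPolynomial]) -> OmegaPolynomial:
    total = OmegaPolynomial.zero()
    for item in items:
        total = total + item
    return total
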