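"""Sparse exact-integer Laurent polynomials in one and two variables.

Coefficients in this pipeline reach ~10²³, so everything is Python-int
exact; floating point is never used.  Division is *exact* division
(``exquo``): it either returns the precise quotient or raises, which is
how the pipeline asserts that every rational intermediate collapses to
a genuine Laurent polynomial.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .errors import ConsistencyError


class LaurentPolynomial2:
    """Laurent polynomial in (v, z) over the integers.

    Stored as ``{(v_exp, z_exp): coeff}`` with no zero entries.
    """

    __slots__ = ("_c",)

    def __init__(self, coeffs: Mapping[tuple[int, int], int] | None = None):
        self._c = {
            (int(ev), int(ez)): int(cv)
            for (ev, ez), cv in (coeffs or {}).items()
            if cv
        }

    @classmethod
    def zero(cls) -> "LaurentPolynomial2":
        return cls()

    @classmethod
    def one(cls) -> "LaurentPolynomial2":
        return cls({(0, 0): 1})

    @classmethod
    def term(cls, coeff: int, v_exp: int, z_exp: int) -> "LaurentPolynomial2":
        return cls({(v_exp, z_exp): coeff})

    # -- queries ------------------------------------------------------
    def coeffs(self) -> dict[tuple[int, int], int]:
        return dict(self._c)

    def coefficient(self, v_exp: int, z_exp: int) -> int:
        return self._c.get((v_exp, z_exp), 0)

    def __bool__(self) -> bool:
        return bool(self._c)

    def __len__(self) -> int:
        return len(self._c)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LaurentPolynomial2):
            return NotImplemented
        return self._c == other._c

    def __hash__(self):
        return hash(frozenset(self._c.items()))

    @property
    def max_v_degree(self) -> int:
        if not self._c:
            raise ValueError("zero polynomial has no degree")
        return max(ev for ev, _ in self._c)

    @property
    def min_v_degree(self) -> int:
        if not self._c:
            raise ValueError("zero polynomial has no degree")
        return min(ev for ev, _ in self._c)

    @property
    def span_v(self) -> int:
        return self.max_v_degree - self.min_v_degree

    @property
    def min_z_degree(self) -> int:
        if not self._c:
            raise ValueError("zero polynomial has no degree")
        return min(ez for _, ez in self._c)

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other: "LaurentPolynomial2") -> "LaurentPolynomial2":
        c = dict(self._c)
        for key, cv in other._c.items():
            nv = c.get(key, 0) + cv
            if nv:
                c[key] = nv
            elif key in c:
                del c[key]
        out = LaurentPolynomial2.__new__(LaurentPolynomial2)
        out._c = c
        return out

    def __neg__(self) -> "LaurentPolynomial2":
        out = LaurentPolynomial2.__new__(LaurentPolynomial2)
        out._c = {k: -cv for k, cv in self._c.items()}
        return out

    def __sub__(self, other: "LaurentPolynomial2") -> "LaurentPolynomial2":
        return self + (-other)

    def __mul__(self, other) -> "LaurentPolynomial2":
        if isinstance(other, int):
            out = LaurentPolynomial2.__new__(LaurentPolynomial2)
            out._c = {k: cv * other for k, cv in self._c.items()} if other else {}
            return out
        if not isinstance(other, LaurentPolynomial2):
            return NotImplemented
        c: dict[tuple[int, int], int] = {}
        for (e1, f1), c1 in self._c.items():
            for (e2, f2), c2 in other._c.items():
                key = (e1 + e2, f1 + f2)
                nv = c.get(key, 0) + c1 * c2
                if nv:
                    c[key] = nv
                elif key in c:
                    del c[key]
        out = LaurentPolynomial2.__new__(LaurentPolynomial2)
        out._c = c
        return out

    __rmul__ = __mul__

    def __pow__(self, n: int) -> "LaurentPolynomial2":
        if n < 0:
            raise ValueError("negative power of a polynomial")
        result = LaurentPolynomial2.one()
        base = self
        while n:
            if n & 1:
                result = result * base
            base = base * base
            n >>= 1
        return result

    def shift(self, dv: int, dz: int) -> "LaurentPolynomial2":
        """Multiply by the monomial v^dv · z^dz."""
        out = LaurentPolynomial2.__new__(LaurentPolynomial2)
        out._c = {(ev + dv, ez + dz): cv for (ev, ez), cv in self._c.items()}
        return out

    def exquo(self, divisor: "LaurentPolynomial2") -> "LaurentPolynomial2":
        """Exact division; raises ConsistencyError if not exact.

        Single-divisor reduction under lex order on (v_exp, z_exp); in
        a Laurent ring monomials are units, so only integer coefficient
        divisibility can fail.
        """
        if not divisor:
            raise ZeroDivisionError("division by zero polynomial")
        if not self:
            return LaurentPolynomial2.zero()
        divisor_z_exps = {ez for _, ez in divisor._c}
        if len(divisor_z_exps) == 1:
            # Divisor involves v only (up to a z-monomial): z-slices are
            # independent, and per-slice univariate division is fast.
            ez0 = divisor_z_exps.pop()
            div1 = LaurentPolynomial1({ev: cv for (ev, _), cv in divisor._c.items()})
            slices: dict[int, dict[int, int]] = {}
            for (ev, ez), cv in self._c.items():
                slices.setdefault(ez, {})[ev] = cv
            out: dict[tuple[int, int], int] = {}
            for ez, sl in slices.items():
                q = LaurentPolynomial1(sl).exquo(div1)
                for ev, cv in q.coeffs().items():
                    out[(ev, ez - ez0)] = cv
            return LaurentPolynomial2(out)
        lead = max(divisor._c)
        lead_c = divisor._c[lead]
        rem = dict(self._c)
        quo: dict[tuple[int, int], int] = {}
        # The quotient has at most len(self) * len(divisor) terms when the
        # division is exact; use a generous cap to detect non-exactness.
        cap = 4 * (len(self._c) + 1) * (len(divisor._c) + 1) + 1000
        for _ in range(cap):
            if not rem:
                return LaurentPolynomial2(quo)
            rkey = max(rem)
            rc = rem[rkey]
            q, r = divmod(rc, lead_c)
            if r:
                raise ConsistencyError("non-exact Laurent division (coefficient)")
            qkey = (rkey[0] - lead[0], rkey[1] - lead[1])
            quo[qkey] = quo.get(qkey, 0) + q
            for dkey, dc in divisor._c.items():
                key = (qkey[0] + dkey[0], qkey[1] + dkey[1])
                nv = rem.get(key, 0) - q * dc
                if nv:
                    rem[key] = nv
                elif key in rem:
                    del rem[key]
        raise ConsistencyError("non-exact Laurent division (non-terminating)")

    # -- substitutions ------------------------------------------------
    def subs_v_neg_inv(self) -> "LaurentPolynomial2":
        """The variable change v -> -v⁻¹ (mirror / orientation flip)."""
        out = LaurentPolynomial2.__new__(LaurentPolynomial2)
        out._c = {
            (-ev, ez): (cv if ev % 2 == 0 else -cv) for (ev, ez), cv in self._c.items()
        }
        return out

    def eval_v_one(self) -> "LaurentPolynomial1":
        """Evaluate at v = 1, leaving a Laurent polynomial in z."""
        c: dict[int, int] = {}
        for (_, ez), cv in self._c.items():
            nv = c.get(ez, 0) + cv
            if nv:
                c[ez] = nv
            elif ez in c:
                del c[ez]
        return LaurentPolynomial1(c)

    # -- presentation -------------------------------------------------
    def sorted_terms(self) -> list[tuple[int, int, int]]:
        """(z_exp, v_exp, coeff), descending z then descending v."""
        return [
            (ez, ev, self._c[(ev, ez)])
            for ev, ez in sorted(self._c, key=lambda k: (-k[1], -k[0]))
        ]

    def to_json_dict(self) -> dict[str, int]:
        return {
            f"{ev}:{ez}": self._c[(ev, ez)]
            for ev, ez in sorted(self._c, key=lambda k: (-k[1], -k[0]))
        }

    def __repr__(self) -> str:
        if not self._c:
            return "0"
        parts = []
        for ez, ev, cv in self.sorted_terms():
            body = "".join(
                (
                    f"v^{ev}" if ev not in (0, 1) else ("v" if ev == 1 else ""),
                    f"z^{ez}" if ez not in (0, 1) else ("z" if ez == 1 else ""),
                )
            )
            if not body:
                parts.append(f"{cv}")
            elif cv == 1:
                parts.append(body)
            elif cv == -1:
                parts.append(f"-{body}")
            else:
                parts.append(f"{cv}*{body}")
        return " + ".join(parts).replace("+ -", "- ")


class LaurentPolynomial1:
    """Laurent polynomial in one variable over the integers."""

    __slots__ = ("_c",)

    def __init__(self, coeffs: Mapping[int, int] | None = None):
        self._c = {int(e): int(cv) for e, cv in (coeffs or {}).items() if cv}

    @classmethod
    def zero(cls) -> "LaurentPolynomial1":
        return cls()

    @classmethod
    def one(cls) -> "LaurentPolynomial1":
        return cls({0: 1})

    @classmethod
    def term(cls, coeff: int, exp: int) -> "LaurentPolynomial1":
        return cls({exp: coeff})

    def coeffs(self) -> dict[int, int]:
        return dict(self._c)

    def coefficient(self, exp: int) -> int:
        return self._c.get(exp, 0)

    def __bool__(self) -> bool:
        return bool(self._c)

    def __len__(self) -> int:
        return len(self._c)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LaurentPolynomial1):
            return NotImplemented
        return self._c == other._c

    def __hash__(self):
        return hash(frozenset(self._c.items()))

    @property
    def min_degree(self) -> int:
        if not self._c:
            raise ValueError("zero polynomial has no degree")
        return min(self._c)

    @property
    def max_degree(self) -> int:
        if not self._c:
            raise ValueError("zero polynomial has no degree")
        return max(self._c)

    def __add__(self, other: "LaurentPolynomial1") -> "LaurentPolynomial1":
        c = dict(self._c)
        for e, cv in other._c.items():
            nv = c.get(e, 0) + cv
            if nv:
                c[e] = nv
            elif e in c:
                del c[e]
        out = LaurentPolynomial1.__new__(LaurentPolynomial1)
        out._c = c
        return out

    def __neg__(self) -> "LaurentPolynomial1":
        out = LaurentPolynomial1.__new__(LaurentPolynomial1)
        out._c = {e: -cv for e, cv in self._c.items()}
        return out

    def __sub__(self, other: "LaurentPolynomial1") -> "LaurentPolynomial1":
        return self + (-other)

    def __mul__(self, other) -> "LaurentPolynomial1":
        if isinstance(other, int):
            out = LaurentPolynomial1.__new__(LaurentPolynomial1)
            out._c = {e: cv * other for e, cv in self._c.items()} if other else {}
            return out
        if not isinstance(other, LaurentPolynomial1):
            return NotImplemented
        c: dict[int, int] = {}
        for e1, c1 in self._c.items():
            for e2, c2 in other._c.items():
                e = e1 + e2
                nv = c.get(e, 0) + c1 * c2
                if nv:
                    c[e] = nv
                elif e in c:
                    del c[e]
        out = LaurentPolynomial1.__new__(LaurentPolynomial1)
        out._c = c
        return out

    __rmul__ = __mul__

    def __pow__(self, n: int) -> "LaurentPolynomial1":
        if n < 0:
            raise ValueError("negative power of a polynomial")
        result = LaurentPolynomial1.one()
        base = self
        while n:
            if n & 1:
                result = result * base
            base = base * base
            n >>= 1
        return result

    def exquo(self, divisor: "LaurentPolynomial1") -> "LaurentPolynomial1":
        """Exact division; raises ConsistencyError if not exact."""
        if not divisor:
            raise ZeroDivisionError("division by zero polynomial")
        if not self:
            return LaurentPolynomial1.zero()
        lead = max(divisor._c)
        lead_c = divisor._c[lead]
        rem = dict(self._c)
        quo: dict[int, int] = {}
        cap = 4 * (len(self._c) + 1) * (len(divisor._c) + 1) + 1000
        for _ in range(cap):
            if not rem:
                return LaurentPolynomial1(quo)
            rkey = max(rem)
            q, r = divmod(rem[rkey], lead_c)
            if r:
                raise ConsistencyError("non-exact Laurent division (coefficient)")
            qkey = rkey - lead
            quo[qkey] = quo.get(qkey, 0) + q
            for dkey, dc in divisor._c.items():
                key = qkey + dkey
                nv = rem.get(key, 0) - q * dc
                if nv:
                    rem[key] = nv
                elif key in rem:
                    del rem[key]
        raise ConsistencyError("non-exact Laurent division (non-terminating)")

    def to_json_dict(self) -> dict[str, int]:
        return {str(e): self._c[e] for e in sorted(self._c, reverse=True)}

    def __repr__(self) -> str:
        if not self._c:
            return "0"
        parts = []
        for e in sorted(self._c, reverse=True):
            cv = self._c[e]
            body = f"x^{e}" if e not in (0, 1) else ("x" if e == 1 else "")
            if not body:
                parts.append(f"{cv}")
            elif cv in (1, -1):
                parts.append(f"-{body}" if cv == -1 else body)
            else:
                parts.append(f"{cv}*{body}")
        return " + ".join(parts).replace("+ -", "- ")
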