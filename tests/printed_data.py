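"""Published reference values frozen into the test suite.

The theta-graph link invariants are published in full; the tetrahedron
(K4) and cube links only as leading/trailing/selected terms.  Brackets
are stored in the published factored convention

    P_L = -v^{v_pref} z^{z_pref} * (bracket in non-negative powers)

and parsed here into coefficient maps.  The theta bracket was checked
for internal consistency before freezing: every z-column sums to zero
at v = 1 except z^14, whose coefficients sum to 37632, matching the
published single-term Conway polynomial.
"""

import re

_TERM = re.compile(r"([+-]?)(\d*)(?:v(\d+))?(?:z(\d+))?")


def parse_bracket(text: str) -> dict[tuple[int, int], int]:
    """Parse 'v48z14+7v46z14-...-1' into {(v_exp, z_exp): coeff}."""
    out: dict[tuple[int, int], int] = {}
    for chunk in re.findall(r"[+-]?[^+-]+", text.replace(" ", "").replace("\n", "")):
        m = _TERM.fullmatch(chunk)
        if not m:
            raise ValueError(f"bad bracket term {chunk!r}")
        sign, coeff, vexp, zexp = m.groups()
        c = int(coeff) if coeff else 1
        if sign == "-":
            c = -c
        key = (int(vexp or 0), int(zexp or 0))
        if key in out:
            raise ValueError(f"duplicate bracket term {chunk!r}")
        out[key] = c
    return out


def homfly_from_bracket(
    bracket: dict[tuple[int, int], int], v_pref: int, z_pref: int
) -> dict[tuple[int, int], int]:
    """Expand -v^v_pref z^z_pref * bracket into a plain coefficient map."""
    return {(ev + v_pref, ez + z_pref): -c for (ev, ez), c in bracket.items()}


# ---------------------------------------------------------------------
# Theta-graph link: fully published.
#   P_L(Θ) = -v^-55 z^-7 * (bracket)
# ---------------------------------------------------------------------
THETA_HOMFLY_BRACKET = parse_bracket(
    "v48z14+7v46z14+28v44z14+84v42z14+3v42z12+207v40z14+15v40z12+441v38z14"
    "+47v38z12+838v36z14+115v36z12+1450v34z14+3v36z10+246v34z12+2308v32z14"
    "+9v34z10+478v32z12+3388v30z14+36v32z10+836v30z12+4570v28z14+84v30z10"
    "+1332v28z12+5590v26z14+4v30z8+196v28z10+1834v26z12+6069v24z14+4v28z8"
    "+372v26z10+2066v24z12+5619v22z14+52v26z8+528v24z10+1554v22z12+4116v20z14"
    "+52v24z8+664v22z10-374v20z12+2140v18z14+9v24z6+238v22z8-285v20z10"
    "-2815v18z12+679v16z14-9v22z6+238v20z8-2319v18z10-3291v16z12+97v14z14"
    "+184v20z6-1066v18z8-1996v16z10-1705v14z12-184v18z6-1066v16z8+684v14z10"
    "-341v12z12+66v18z4-606v16z6+1190v14z8+1518v12z10-198v16z4+606v14z6"
    "+1190v12z8+506v10z10+12v16z2+66v14z4+624v12z6-418v10z8-60v14z2+330v12z4"
    "-624v10z6-418v8z8+v14+108v12z2-330v10z4-211v8z6-7v12-60v10z2-66v8z4"
    "+211v6z6+21v10-60v8z2+198v6z4-35v8+108v6z2-66v4z4+35v6-60v4z2-21v4"
    "+12v2z2+7v2-1"
)
THETA_HOMFLY = homfly_from_bracket(THETA_HOMFLY_BRACKET, -55, -7)

# V_L(Θ) = -t^(-103/2) * (sum of JONES coefficients, t^48 down to t^0)
THETA_JONES_BRACKET = [
    1, -7, 28, -84, 210, -462, 924, -1713, 2985, -4939, 7819, -11912,
    17544, -25072, 34875, -47326, 62766, -81462, 103570, -129055, 157634,
    -188690, 221242, -253870, 284755, -311685, 332298, -344228, 345601,
    -335293, 313457, -281464, 242045, -198659, 155160, -114883, 80386,
    -52914, 32652, -18771, 10012, -4907, 2200, -885, 320, -98, 27, -5, 1,
]
# s-exponent -> coefficient of the Jones polynomial in s = t^(1/2)
THETA_JONES = {
    -103 + 2 * (48 - k): -c for k, c in enumerate(THETA_JONES_BRACKET)
}

# ---------------------------------------------------------------------
# Tetrahedron (K4) link: published terms of the v^-109 z^-13 bracket.
# ---------------------------------------------------------------------
TET_HOMFLY_BRACKET_TERMS = parse_bracket(
    "v96z26+13v94z26+91v92z26+455v90z26+6v90z24+1814v88z26+66v88z24"
    "+6110v86z26+400v86z24+18014v84z26+15v84z22+6240v82z24"
    "+76044v44z16-568318v42z18-9151952v40z20-35714154v38z22"
    "-3982176v26z14+2351088v24z16+3395394v22z18-464792v20z20"
    "+24v2z2+13v2-1"
)
TET_HOMFLY_PREFIX = (-109, -13)

# V_L(T) = -t^(-205/2)*(...); published terms as {t_exp: coeff}.
TET_JONES_BRACKET_TERMS = {
    96: 1, 95: -13, 94: 91, 93: -455, 92: 1820, 91: -6188, 90: 18564,
    89: -50382, 88: 125898,
    42: 405708071163, 41: -422901756090, 40: 434762332438, 39: -440420890844,
    2: 90, 1: -11, 0: 1,
}
TET_JONES_S_PREFIX = -205

# ---------------------------------------------------------------------
# Cube link: published terms of the v^-217 z^-25 bracket.
# ---------------------------------------------------------------------
CUBE_HOMFLY_BRACKET_TERMS = parse_bracket(
    "v192z50+25v190z50+325v188z50+2925v186z50+12v186z48+20463v184z50"
    "+276v184z48+118455v182z50+3320v182z48+589867v180z50+27784v180z48"
    "+2594275v178z50"
    "+117286813536v146z44+24631386348v118z36-4342184782394v82z34"
    "+604406814588216v62z36-316550564v42z6+6981260760v24z10"
    "+48v2z2+25v2-1"
)
CUBE_HOMFLY_PREFIX = (-217, -25)

# V_L(H) = -t^(-409/2)*(...); published terms as {t_exp: coeff}.
CUBE_JONES_BRACKET_TERMS = {
    192: 1, 191: -25, 190: 325, 189: -2925, 188: 20475, 187: -118755,
    186: 593775,
    136: 64833446416942962011,
    89: -451043083493105466629441,
    39: -388424807064142369273,
    10: 1083862665,
    2: 324, 1: -23, 0: 1,
}
CUBE_JONES_S_PREFIX = -409

# Published single-term Conway polynomials {z_exp: coeff}.
CONWAY = {
    "theta": {7: -37632},
    "tetrahedron": {13: -1078984704},
    "cube": {25: -748419423085264896},
}

# Published braid indices (MFW lower = Ohyama upper).
BRAID_INDEX = {"theta": 25, "tetrahedron": 49, "cube": 97}
CROSSINGS = {"theta": 48, "tetrahedron": 96, "cube": 192}
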