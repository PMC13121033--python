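"""Shared monoisotopic mass table and formula arithmetic.

Every mass used anywhere in the package (tracer shift, adduct and
isotopologue deltas, base metabolites, formula enumeration, conjugate
arithmetic) is derived from the NIST atomic mass table shipped with
:mod:`pyteomics`, so there is a single source of truth.
"""

from __future__ import annotations

import re

from pyteomics import mass as _pmass

_NIST = _pmass.nist_mass

#: Monoisotopic masses of the elements handled by the formula tools (Da).
ELEMENT_MASS: dict[str, float] = {
    "C": _NIST["C"][12][0],
    "H": _NIST["H"][1][0],
    "N": _NIST["N"][14][0],
    "O": _NIST["O"][16][0],
    "P": _NIST["P"][31][0],
    "S": _NIST["S"][32][0],
    "Na": _NIST["Na"][23][0],
    "K": _NIST["K"][39][0],
    "Cl": _NIST["Cl"][35][0],
}

#: Heavy-minus-light isotope mass differences (Da).
DELTA_13C: float = _NIST["C"][13][0] - _NIST["C"][12][0]
DELTA_15N: float = _NIST["N"][15][0] - _NIST["N"][14][0]
DELTA_34S: float = _NIST["S"][34][0] - _NIST["S"][32][0]
DELTA_18O: float = _NIST["O"][18][0] - _NIST["O"][16][0]

#: Mass of a proton (for m/z <-> neutral mass conversion of singly
#: charged ions).
PROTON_MASS: float = _NIST["H"][1][0] - _NIST["e*"][0][0]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula such as ``"C3H7NO2S"`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        if not match.group(0):
            break
        element, digits = match.groups()
        if element not in ELEMENT_MASS:
            raise ValueError(f"unsupported element {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def formula_mass(formula: str | dict[str, int]) -> float:
    """Neutral monoisotopic mass (Da) of a formula string or count map."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(ELEMENT_MASS[el] * n for el, n in counts.items())


def format_formula(counts: dict[str, int]) -> str:
    """Element counts -> Hill-order formula string (C, H, then alphabetical)."""
    order = ["C", "H"] + sorted(k for k in counts if k not in ("C", "H"))
    parts = []
    for el in order:
        n = counts.get(el, 0)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    return "".join(parts)


def ppm_diff(observed: float, reference: float) -> float:
    """Signed difference of ``observed`` from ``reference`` in parts per million."""
    return (observed - reference) / reference * 1e6


# Frequently used neutral monoisotopic masses (Da).
MASS_H2O: float = formula_mass("H2O")
MASS_H3PO4: float = formula_mass("H3PO4")
MASS_CYS: float = formula_mass("C3H7NO2S")
MASS_GSH: float = formula_mass("C10H17N3O6S")
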