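"""Monoisotopic mass arithmetic for formulas, ions and isotope deltas.

Atomic masses are embedded literals (IUPAC/AME monoisotopic values, >=6
decimal places); nothing is looked up at run time.  The module backs the
synthetic fixtures and the documentation examples: the diagnostic phosphate
fragment H4O4P+ (m/z 98.9842), the iron-binding adduct delta 52.91 Da
(56Fe replacing three protons) and the 13C isotope spacing 1.0034 Da all
derive from this table.
"""

from __future__ import annotations

import re
from typing import Dict, Mapping

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ISOTOPE_MASSES",
    "MONOISOTOPIC",
    "Formula",
    "parse_formula",
    "monoisotopic_mass",
    "formula_ion_mz",
    "ion_mz",
    "species_mass",
    "mass_delta",
]

ELECTRON_MASS = 0.00054857990907  # Da
PROTON_MASS = 1.00727646688  # Da (bare proton; H atom minus electron)

#: (element symbol, nucleon number) -> atomic mass in Da.
ISOTOPE_MASSES: Dict[tuple, float] = {
    ("H", 1): 1.00782503207,
    ("H", 2): 2.01410177785,
    ("C", 12): 12.0,
    ("C", 13): 13.00335483778,
    ("N", 14): 14.00307400478,
    ("N", 15): 15.00010889823,
    ("O", 16): 15.99491461956,
    ("O", 18): 17.99916104,
    ("F", 19): 18.99840322,
    ("Na", 23): 22.98976928087,
    ("Mg", 24): 23.9850417,
    ("Si", 28): 27.97692653246,
    ("P", 31): 30.97376163,
    ("S", 32): 31.97207100,
    ("S", 34): 33.96786690,
    ("Cl", 35): 34.96885268,
    ("Cl", 37): 36.96590259,
    ("K", 39): 38.96370668,
    ("Ca", 40): 39.96259098,
    ("Fe", 54): 53.93961050,
    ("Fe", 56): 55.93493750,
    ("Cu", 63): 62.92959750,
    ("Zn", 64): 63.92914220,
    ("Se", 80): 79.91652130,
    ("Br", 79): 78.91833710,
    ("Br", 81): 80.91629060,
    ("I", 127): 126.90447300,
}

#: element symbol -> most abundant isotope's mass (the default when no
#: nucleon number is given).
_MOST_ABUNDANT = {
    "H": 1, "C": 12, "N": 14, "O": 16, "F": 19, "Na": 23, "Mg": 24,
    "Si": 28, "P": 31, "S": 32, "Cl": 35, "K": 39, "Ca": 40, "Fe": 56,
    "Cu": 63, "Zn": 64, "Se": 80, "Br": 79, "I": 127,
}
MONOISOTOPIC: Dict[str, float] = {
    el: ISOTOPE_MASSES[(el, a)] for el, a in _MOST_ABUNDANT.items()
}

Formula = Mapping[str, int]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(ValueError):
    """Raised for element symbols or isotope labels not in the table."""


def parse_formula(text: str) -> Dict[str, int]:
    """Parse a Hill-like formula string ("C6H12O6", "H4O4P") to counts.

    No charge signs, parentheses or isotope labels are allowed inside a
    formula; counts default to 1.
    """
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"invalid formula syntax at position {pos}: {text!r}")
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC:
            raise UnknownElementError(f"unknown element {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return counts


def monoisotopic_mass(formula: Formula | str) -> float:
    """Monoisotopic mass of a neutral formula in Da.

    The sum runs in a fixed (alphabetical) element order so the float
    result is reproducible independent of input dict ordering.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    total = 0.0
    for el in sorted(formula):
        count = formula[el]
        if count < 0:
            raise ValueError(f"negative count for element {el!r}")
        if el not in MONOISOTOPIC:
            raise UnknownElementError(f"unknown element {el!r}")
        total += count * MONOISOTOPIC[el]
    return total


def ion_mz(neutral_mass: float, z: int = 1, mode: str = "protonated") -> float:
    """m/z of the [M + zH]z+ or [M - zH]z- ion of a neutral mass.

    Uses the bare-proton mass, so the electron is already accounted for.
    """
    if z == 0:
        raise ValueError("charge z must be nonzero")
    z = abs(int(z))
    if mode == "protonated":
        return (neutral_mass + z * PROTON_MASS) / z
    if mode == "deprotonated":
        return (neutral_mass - z * PROTON_MASS) / z
    raise ValueError(f"unknown ionization mode {mode!r}")


def formula_ion_mz(formula: Formula | str, z: int = 1) -> float:
    """m/z of a cation whose *formula already includes* the ionizing protons.

    E.g. formula_ion_mz("H4O4P", 1) is the phosphate fragment ion:
    the formula-ion mass minus z electrons, divided by z.  Must agree with
    ion_mz(monoisotopic_mass(neutral), z, "protonated") to <1e-6 Da.
    """
    if z == 0:
        raise ValueError("charge z must be nonzero")
    z = abs(int(z))
    return (monoisotopic_mass(formula) - z * ELECTRON_MASS) / z


_SPECIES_TERM = re.compile(r"(\d*)([A-Z][a-z]?)")


def species_mass(label: str) -> float:
    """Mass in Da of an isotope-or-species label.

    Labels are composites of signed terms, e.g. "56Fe", "13C",
    "56Fe-3H".  A leading integer on a term is interpreted as a nucleon
    number when (element, number) names a known isotope, otherwise as a
    multiplier of the element's default monoisotopic mass (so "3H" is
    three hydrogen atoms).  "0" is the empty species.
    """
    text = label.replace("−", "-").replace(" ", "")
    if text in ("0", ""):
        return 0.0
    total = 0.0
    sign = 1
    pos = 0
    if text[0] in "+-":
        sign = -1 if text[0] == "-" else 1
        pos = 1
    while pos < len(text):
        m = _SPECIES_TERM.match(text, pos)
        if m is None or m.start() != pos or not m.group(2):
            raise ValueError(f"invalid species label at position {pos}: {label!r}")
        num, el = m.group(1), m.group(2)
        if el not in MONOISOTOPIC:
            raise UnknownElementError(f"unknown element {el!r} in {label!r}")
        if num and (el, int(num)) in ISOTOPE_MASSES:
            total += sign * ISOTOPE_MASSES[(el, int(num))]
        elif num:
            total += sign * int(num) * MONOISOTOPIC[el]
        else:
            total += sign * MONOISOTOPIC[el]
        pos = m.end()
        if pos < len(text):
            if text[pos] not in "+-":
                raise ValueError(f"invalid species label at position {pos}: {label!r}")
            sign = -1 if text[pos] == "-" else 1
            pos += 1
    return total


def mass_delta(a: str, b: str) -> float:
    """Signed mass difference species_mass(a) - species_mass(b) in Da.

    mass_delta("13C", "12C") is the carbon isotope spacing 1.003355;
    mass_delta("56Fe-3H", "0") is the iron-binding adduct delta 52.911462.
    """
    return species_mass(a) - species_mass(b)
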