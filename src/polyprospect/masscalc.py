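"""Molecular-formula parsing and monoisotopic adduct m/z arithmetic.

The computational half of a negative-mode HR-ESI-MS identification: parse a
neutral molecular formula, compute its monoisotopic mass, and derive the
m/z of named ionisation adducts such as [M-H]-, [M-2H+Na]- or the in-source
decarboxylation ion [M-CO2-H]-.  The electron mass is accounted for per
unit charge (added for anions, subtracted for cations); rounding happens
only at presentation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ElementCounts",
    "Adduct",
    "parse_formula",
    "parse_adduct",
    "monoisotopic_mass",
    "adduct_mz",
    "NAMED_ADDUCTS",
]

#: monoisotopic atomic masses (u), 12C-scale
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
    "S": 31.97207100,
    "P": 30.97376163,
    "Cl": 34.96885268,
    "K": 38.96370668,
}

ELECTRON_MASS = 0.00054857990

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementCounts:
    """Element -> count map with an overall charge (0 for a neutral)."""

    counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self):
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el!r}")

    def __add__(self, other: "ElementCounts") -> "ElementCounts":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementCounts(merged, self.charge + other.charge)


def parse_formula(text: str) -> ElementCounts:
    """Parse a Hill-notation-like formula, e.g. ``"C18H18O2"``."""
    if not text:
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula at {text[pos:]!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {el!r} in formula {text!r}")
        n = int(num) if num else 1
        if n == 0:
            raise ValueError(f"zero count for element {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + n
    if pos != len(text):
        raise ValueError(f"cannot parse formula at {text[pos:]!r}")
    return ElementCounts(counts)


def monoisotopic_mass(counts: ElementCounts) -> float:
    """Monoisotopic mass of a neutral composition, in Da."""
    if counts.charge != 0:
        raise ValueError("charged composition: use adduct_mz for ions")
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.counts.items())


@dataclass(frozen=True)
class Adduct:
    """A named ion type: element deltas applied to M plus a charge."""

    name: str
    delta: dict[str, int]
    charge: int

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError(f"adduct {self.name!r}: an ion needs |charge| >= 1")


_ADDUCT_BODY = re.compile(r"([+-])(\d*)([A-Za-z0-9]+)")
_CHARGE_TAIL = re.compile(r"(\d*)([+-])$")


def parse_adduct(name: str) -> Adduct:
    """Parse adduct notation like ``[M-H]-``, ``[M-2H+Na]-``, ``[M-CO2-H]-``.

    Parentheses and spaces are ignored, so the sodium-loss reading
    ``[(M-2H)-Na]-`` parses literally as removing 2 H and 1 Na.
    """
    compact = re.sub(r"[()\s]", "", name)
    if not (compact.startswith("[") and "]" in compact):
        raise ValueError(f"cannot parse adduct {name!r}")
    body, tail = compact[1:].split("]", 1)
    m = _CHARGE_TAIL.fullmatch(tail)
    if m is None:
        raise ValueError(f"adduct {name!r}: missing charge")
    mult = int(m.group(1)) if m.group(1) else 1
    charge = mult if m.group(2) == "+" else -mult
    if not body.startswith("M"):
        raise ValueError(f"adduct {name!r}: expected [M...]")
    delta: dict[str, int] = {}
    pos = 1
    for tok in _ADDUCT_BODY.finditer(body, 1):
        if tok.start() != pos:
            raise ValueError(f"cannot parse adduct {name!r} at {body[pos:]!r}")
        pos = tok.end()
        sign = 1 if tok.group(1) == "+" else -1
        count = int(tok.group(2)) if tok.group(2) else 1
        group = parse_formula(tok.group(3))
        for el, n in group.counts.items():
            delta[el] = delta.get(el, 0) + sign * count * n
    if pos != len(body):
        raise ValueError(f"cannot parse adduct {name!r} at {body[pos:]!r}")
    return Adduct(name, delta, charge)


#: the ion types reported for protegencin, plus the common positive modes.
#: "[(M-2H)-Na]-" is the literal sodium-loss reading; "[M-2H+Na]-" is the
#: sodium-exchange reading usually meant by that notation.
NAMED_ADDUCTS = {
    n: parse_adduct(n)
    for n in ("[M-H]-", "[M+H]+", "[M+Na]+", "[M-2H+Na]-", "[(M-2H)-Na]-",
              "[M-CO2-H]-")
}


def adduct_mz(counts: ElementCounts, adduct: Adduct | str) -> float:
    """m/z of the ion formed by applying *adduct* to the neutral *counts*."""
    if isinstance(adduct, str):
        adduct = NAMED_ADDUCTS.get(adduct) or parse_adduct(adduct)
    adjusted = dict(counts.counts)
    deficient = []
    for el, n in adduct.delta.items():
        adjusted[el] = adjusted.get(el, 0) + n
        if adjusted[el] < 0:
            deficient.append(el)
    if deficient:
        raise ValueError(
            f"adduct {adduct.name!r} not applicable: composition lacks "
            + ", ".join(sorted(deficient)))
    adjusted = {el: n for el, n in adjusted.items() if n > 0}
    mass = monoisotopic_mass(ElementCounts(adjusted))
    mass += -adduct.charge * ELECTRON_MASS  # +m_e per negative charge
    return mass / abs(adduct.charge)
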