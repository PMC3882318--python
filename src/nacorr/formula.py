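"""Molecular formula parsing.

A formula string such as ``"C17H27N3O17P2"`` is a run of element symbols,
each optionally followed by a decimal atom count (an absent count means 1).
The per-element atom counts bound the isotopologue label dimensions: a
molecule with 17 carbons can carry at most 17 heavy carbon labels.

Parenthesized groups, hydrates, adducts and charge states are not
supported and raise :class:`FormulaError`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["MolecularFormula", "FormulaError", "parse_formula"]

# Standard periodic-table symbols (elements 1-118).
_ELEMENTS = frozenset(
    """
    H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb
    Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re
    Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es
    Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og
    """.split()
)

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a formula string cannot be parsed."""


@dataclass(frozen=True)
class MolecularFormula:
    """An element → atom-count mapping.

    Counts are strictly positive; an element absent from the mapping has
    an implicit count of zero.
    """

    elements: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym, count in self.elements.items():
            if sym not in _ELEMENTS:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if not isinstance(count, int) or count < 1:
                raise FormulaError(f"invalid atom count for {sym}: {count!r}")

    def count(self, element: str) -> int:
        """Atom count of *element*, zero when absent."""
        return self.elements.get(element, 0)

    def __str__(self) -> str:
        # Hill order: C first, then H, then alphabetical.
        syms = sorted(
            self.elements,
            key=lambda s: (s != "C", s != "H" if "C" in self.elements else False, s),
        )
        parts = []
        for s in syms:
            n = self.elements[s]
            parts.append(s if n == 1 else f"{s}{n}")
        return "".join(parts)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a molecular formula string.

    >>> parse_formula("C17H27N3O17P2").elements
    {'C': 17, 'H': 27, 'N': 3, 'O': 17, 'P': 2}

    Repeated symbols accumulate (``"CHOOH"`` gives two oxygens).  Unknown
    symbols, explicit zero counts and any non-formula characters raise
    :class:`FormulaError` naming the offending token.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    elements: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"unparseable token at position {pos} in {text!r}: {text[pos:]!r}"
            )
        sym, digits = m.group(1), m.group(2)
        if sym not in _ELEMENTS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaError(f"zero atom count for {sym!r} in {text!r}")
        elements[sym] = elements.get(sym, 0) + count
        pos = m.end()
    return MolecularFormula(elements)


def max_label_count(formula: MolecularFormula, isotope) -> int:
    """Maximum number of tracer labels *isotope* can place on *formula*.

    This is simply the atom count of the isotope's element: a ¹³C tracer
    on C17H27N3O17P2 admits label counts 0..17.
    """
    return formula.count(isotope.element)
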