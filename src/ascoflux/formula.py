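"""Elemental formulas and degree-of-reduction accounting.

The degree of reduction :math:`\\gamma` of a compound is the number of
available electron moles per carbon mole, taken relative to the reference
(fully oxidized) states CO2, H2O, NH3, H2SO4 and H3PO4.  Under that
convention each element contributes a fixed electron weight (C +4, H +1,
O -2, N -3, S +6, P +5), so for a compound :math:`C_n H_h O_o N_m S_s P_p`

.. math::

   \\gamma = (4n + h - 2o - 3m + 6s + 5p) / n .

Carbohydrates sit at 4 (glucose), ethanol at 6; fermentation-product
electron bookkeeping throughout the package rests on this single function.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction

ELEMENTS = ("C", "H", "O", "N", "S", "P")

#: electron-mole weight of each element relative to CO2/H2O/NH3/H2SO4/H3PO4
ELECTRON_WEIGHTS = {"C": 4, "H": 1, "O": -2, "N": -3, "S": 6, "P": 5}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unusable elemental formulas."""


@dataclass(frozen=True)
class Formula:
    """Neutral-species elemental composition over C, H, O, N, S, P."""

    C: int = 0
    H: int = 0
    O: int = 0
    N: int = 0
    S: int = 0
    P: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            v = getattr(self, el)
            if not isinstance(v, int) or v < 0:
                raise FormulaError(f"element count {el}={v!r} must be a nonnegative integer")
        if all(getattr(self, el) == 0 for el in ELEMENTS):
            raise FormulaError("formula must contain at least one atom")

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string such as ``C6H12O6``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _TOKEN.finditer(text.strip()):
            if m.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r}")
            el, num = m.group(1), m.group(2)
            if el not in ELEMENTS:
                raise FormulaError(f"unsupported element {el!r} in {text!r}")
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(text.strip()) or not counts:
            raise FormulaError(f"cannot parse formula {text!r}")
        return cls(**counts)

    def counts(self) -> dict[str, int]:
        return {el: getattr(self, el) for el in ELEMENTS}

    def electrons(self) -> int:
        """Total available electron moles per mole of compound."""
        return sum(ELECTRON_WEIGHTS[el] * getattr(self, el) for el in ELEMENTS)

    def __str__(self) -> str:
        out = []
        for el in ELEMENTS:
            n = getattr(self, el)
            if n == 1:
                out.append(el)
            elif n > 1:
                out.append(f"{el}{n}")
        return "".join(out)


def degree_of_reduction(formula: Formula) -> Fraction:
    """Available electron moles per Cmol of ``formula``.

    Raises :class:`FormulaError` for carbon-free compounds, for which a
    per-Cmol quantity is undefined.
    """
    if formula.C < 1:
        raise FormulaError(f"degree of reduction undefined for carbon-free formula {formula}")
    return Fraction(formula.electrons(), formula.C)
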