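"""Elemental-composition arithmetic for derivative mass calculations.

Compositions are plain ``{element: count}`` dictionaries over the small
element set relevant to carboxylic-acid derivatization chemistry
(C, H, D, N, O, S, P).  Deuterium is treated as its own symbol ``D`` so
that isotopologue reagents (2PA-d6) and pre-deuterated internal standards
(propanoic acid-d5, butyric acid-d7) can be expressed directly.
"""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

from .errors import FormulaError

# Monoisotopic atomic masses in Da (CODATA/IUPAC 2021 values).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "D": 2.0141017778,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

PROTON_MASS = 1.00727646688  # Da
ELECTRON_MASS = 5.48579909e-4  # Da
#: mass of a bare deuteron (D nucleus), for [M+D]+ adducts
DEUTERON_MASS = MONOISOTOPIC_MASS["D"] - ELECTRON_MASS
#: per-site mass increment of an H -> D substitution
H_TO_D_SHIFT = MONOISOTOPIC_MASS["D"] - MONOISOTOPIC_MASS["H"]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

Composition = dict[str, int]


def parse_formula(formula_text: str) -> Composition:
    """Parse a molecular formula string into an element -> count map.

    Accepts symbols from the supported element set with optional positive
    integer counts, e.g. ``"C3H6O2"`` or ``"C3HD5O2"``.  Repeated symbols
    are summed.  Raises :class:`FormulaError` on unknown symbols,
    explicit zero counts, or any unparseable residue.
    """
    if not isinstance(formula_text, str) or not formula_text.strip():
        raise FormulaError("empty formula")
    text = formula_text.strip()
    composition: Composition = {}
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(
                f"unparseable token at {text[pos:]!r} in formula {formula_text!r}"
            )
        symbol, digits = match.groups()
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(
                f"unknown element symbol {symbol!r} in formula {formula_text!r}"
            )
        count = int(digits) if digits else 1
        if count <= 0:
            raise FormulaError(
                f"non-positive count for {symbol!r} in formula {formula_text!r}"
            )
        composition[symbol] = composition.get(symbol, 0) + count
        pos = match.end()
    return composition


def hill_formula(composition: Composition) -> str:
    """Canonical Hill-order string: C, H, D, then remaining elements
    alphabetically.  ``parse_formula(hill_formula(c)) == c`` for valid
    compositions."""
    _validate(composition)
    ordered: list[str] = []
    for symbol in ("C", "H", "D"):
        if composition.get(symbol, 0):
            ordered.append(symbol)
    ordered.extend(
        sorted(s for s, n in composition.items() if n and s not in ("C", "H", "D"))
    )
    parts = []
    for symbol in ordered:
        n = composition[symbol]
        parts.append(symbol if n == 1 else f"{symbol}{n}")
    return "".join(parts)


def monoisotopic_mass(composition: Composition) -> float:
    """Monoisotopic mass in Da: sum of count x atomic monoisotopic mass.

    The empty composition has mass 0.0.
    """
    _validate(composition)
    return sum(MONOISOTOPIC_MASS[s] * n for s, n in composition.items())


def formula_add(a: Composition, b: Composition) -> Composition:
    """Element-wise sum of two compositions."""
    _validate(a)
    _validate(b)
    out = dict(a)
    for symbol, n in b.items():
        out[symbol] = out.get(symbol, 0) + n
    return out


def formula_subtract(a: Composition, b: Composition) -> Composition:
    """Element-wise difference ``a - b``; negative counts are an error."""
    _validate(a)
    _validate(b)
    out = dict(a)
    for symbol, n in b.items():
        remaining = out.get(symbol, 0) - n
        if remaining < 0:
            raise FormulaError(
                f"cannot remove {n} x {symbol} from {hill_formula(a)}"
            )
        if remaining == 0:
            out.pop(symbol, None)
        else:
            out[symbol] = remaining
    return out


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed m/z tables),
    unlike banker's rounding used by built-in :func:`round`."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def _validate(composition: Composition) -> None:
    for symbol, n in composition.items():
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {symbol!r}")
        if not isinstance(n, int) or n < 0:
            raise FormulaError(f"invalid count {n!r} for element {symbol!r}")


WATER: Composition = {"H": 2, "O": 1}
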