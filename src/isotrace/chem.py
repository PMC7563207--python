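"""Chemical-formula arithmetic for isotope tracing.

Monoisotopic masses, adduct ion m/z and the ¹³C isotopomer spacing
(1.0033548378 Da per label, divided by charge) that underpins the
theoretical-m/z expansion of a reference list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Mapping

__all__ = [
    "DELTA_13C",
    "ChemicalFormula",
    "Adduct",
    "FormulaError",
    "BUILTIN_ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "isotopomer_mz",
]

#: Mass difference between ¹³C and ¹²C in Da; divided by |z| it is the
#: m/z spacing between successive mass isotopomers of a ¹³C-labeled ion.
DELTA_13C = 1.0033548378

# Monoisotopic masses of the most-abundant isotope (IUPAC, 7 decimals).
# Hard-coded: no external lookup happens at run time.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.0078250,
    "B": 11.0093054,
    "C": 12.0000000,
    "N": 14.0030740,
    "O": 15.9949146,
    "F": 18.9984032,
    "Na": 22.9897693,
    "Mg": 23.9850417,
    "Al": 26.9815386,
    "Si": 27.9769265,
    "P": 30.9737616,
    "S": 31.9720707,
    "Cl": 34.9688527,
    "K": 38.9637065,
    "Ca": 39.9625909,
    "Mn": 54.9380451,
    "Fe": 55.9349375,
    "Co": 58.9331950,
    "Ni": 57.9353429,
    "Cu": 62.9295975,
    "Zn": 63.9291422,
    "As": 74.9215965,
    "Se": 79.9165213,
    "Br": 78.9183371,
    "I": 126.9044719,
    "Li": 7.0160034,
}


class FormulaError(ValueError):
    """Raised for malformed or chemically unknown formula strings."""


@dataclass(frozen=True)
class ChemicalFormula:
    """An elemental composition, e.g. ``C40H80NO8P``.

    Stored elements always have count >= 1; ``carbon_count`` is 0 when
    the molecule contains no carbon.
    """

    element_counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for elem, count in self.element_counts.items():
            if elem not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element {elem!r}")
            if count < 1:
                raise FormulaError(f"non-positive count for element {elem!r}")

    @property
    def carbon_count(self) -> int:
        return self.element_counts.get("C", 0)

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        counts = dict(self.element_counts)
        parts = []
        for elem in ["C", "H"] + sorted(e for e in counts if e not in ("C", "H")):
            if elem in counts:
                n = counts[elem]
                parts.append(elem + (str(n) if n > 1 else ""))
        return "".join(parts)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-style formula string (``"C40H80NO8P"``) case-sensitively.

    Whitespace is stripped (LipidSearch exports occasionally pad formulas);
    parentheses and isotope prefixes are not part of the dialect.

    Raises
    ------
    FormulaError
        If the string is empty, contains an unknown element symbol, or has
        characters that are not element-count tokens.
    """
    cleaned = re.sub(r"\s+", "", text or "")
    if not cleaned:
        raise FormulaError("empty formula")
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula token at {cleaned[pos:]!r}")
        elem, digits = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {elem!r} in formula {cleaned!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {elem!r}")
        counts[elem] = counts.get(elem, 0) + n
        pos = m.end()
    return ChemicalFormula(counts)


def monoisotopic_mass(formula: ChemicalFormula | str) -> float:
    """Neutral monoisotopic mass in Da (sum of most-abundant-isotope masses)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if not formula.element_counts:
        raise FormulaError("empty formula has no mass")
    return sum(
        count * MONOISOTOPIC_MASS[elem]
        for elem, count in formula.element_counts.items()
    )


@dataclass(frozen=True)
class Adduct:
    """An ESI adduct: name, neutral-fragment mass delta, charge and polarity.

    Mass deltas are atomic-mass sums of the gained/lost fragment; the
    electron mass is ignored (< 0.001 Th error at z = 1, below the 2-decimal
    precision at which ion m/z values are reported).
    """

    name: str
    mass_delta: float
    z: int
    polarity: str

    def __post_init__(self) -> None:
        if self.z == 0:
            raise ValueError("adduct charge z must be nonzero")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"invalid polarity {self.polarity!r}")
        if (self.z > 0) != (self.polarity == "positive"):
            raise ValueError(
                f"adduct {self.name!r}: sign of z={self.z} inconsistent "
                f"with polarity {self.polarity!r}"
            )


def _frag(formula: str) -> float:
    return monoisotopic_mass(parse_formula(formula))


#: Built-in adduct table; extensible at run time via the configuration.
BUILTIN_ADDUCTS: Dict[str, Adduct] = {
    a.name: a
    for a in [
        Adduct("+H", _frag("H"), +1, "positive"),
        Adduct("+Na", _frag("Na"), +1, "positive"),
        Adduct("+NH4", _frag("NH4"), +1, "positive"),
        Adduct("-H", -_frag("H"), -1, "negative"),
        Adduct("+HCOO", _frag("CHO2"), -1, "negative"),
        Adduct("-H2O-H", -_frag("H3O"), -1, "negative"),
    ]
}


def get_adduct(name: str, extra: Mapping[str, Adduct] | None = None) -> Adduct:
    """Look up an adduct by token, consulting ``extra`` before the built-ins."""
    if extra and name in extra:
        return extra[name]
    try:
        return BUILTIN_ADDUCTS[name]
    except KeyError:
        raise KeyError(
            f"unknown adduct {name!r}; known: {sorted(BUILTIN_ADDUCTS)}"
        ) from None


def ion_mz(neutral_mass: float, adduct: Adduct) -> float:
    """m/z of the adduct ion of a neutral molecule.

    ``(M + mass_delta) / |z|`` — e.g. the formate adduct of dipalmitoyl-PC
    (C40H80NO8P, M = 733.5622) gives m/z 778.56 in negative mode.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return (neutral_mass + adduct.mass_delta) / abs(adduct.z)


def isotopomer_mz(base_mz: float, n: int, z: int = 1) -> float:
    """Theoretical m/z of the M+n mass isotopomer of an ion at ``base_mz``.

    Adds n × 1.0033548378 / z, the ¹³C–¹²C mass difference per label
    divided by the charge magnitude.
    """
    if n < 0:
        raise ValueError("label count n must be >= 0")
    if z < 1:
        raise ValueError("charge magnitude z must be >= 1")
    return base_mz + n * DELTA_13C / z
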