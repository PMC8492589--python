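"""Elemental-composition arithmetic and exact monoisotopic ion masses.

Every identification step in the package reduces to integer element
bookkeeping plus a handful of physical constants: metabolite candidates are
net elemental deltas applied to a parent composition, fragment shifts are
deltas applied to fragment compositions, and observed m/z values are compared
against theoretical ion masses.  This module owns that arithmetic.

Masses are in unified atomic mass units (u); m/z is unitless by convention.
Only singly charged positive ions are supported (protonated molecules
[M+H]+ and even-electron fragment cations), which covers positive-mode
LC-HRMS/MS of small molecules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Tuple

__all__ = [
    "ElementalFormula",
    "IonSpecies",
    "MassDelta",
    "FormulaError",
    "InfeasibleDeltaError",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "apply_delta",
    "ppm_error",
    "PROTON_MASS",
    "ELECTRON_MASS",
]

# IUPAC monoisotopic atomic masses, 6+ decimals.  The printed literature
# values round to 4 decimals; they only round-trip when atoms carry at least
# 5 decimals, hence full-precision constants here.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.007825032,
    "C": 12.0,
    "N": 14.003074005,
    "O": 15.994914620,
    "F": 18.998403163,
    "P": 30.973761998,
    "S": 31.972071174,
    "Cl": 34.968852682,
    "Br": 78.918337600,
    "I": 126.904471900,
    "Na": 22.989769282,
    "K": 38.963706486,
}

PROTON_MASS = 1.007276467
ELECTRON_MASS = 0.000548580

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string or unknown element symbol."""


class InfeasibleDeltaError(ValueError):
    """Applying a delta would drive an element count negative."""


def _parse_counts(text: str) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    pos = 0
    for match in _TOKEN_RE.finditer(text):
        if match.start() != pos:
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token "
                f"{text[pos:match.start()]!r} at position {pos}"
            )
        pos = match.end()
        symbol, digits = match.groups()
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
    if pos != len(text):
        raise FormulaError(
            f"malformed formula {text!r}: unexpected token {text[pos:]!r} "
            f"at position {pos}"
        )
    return counts


def _hill_order(counts: Mapping[str, int]) -> Iterator[Tuple[str, int]]:
    # Hill convention: C first, then H, then the rest alphabetically.
    for sym in ("C", "H"):
        if counts.get(sym, 0):
            yield sym, counts[sym]
    for sym in sorted(counts):
        if sym in ("C", "H"):
            continue
        if counts[sym]:
            yield sym, counts[sym]


@dataclass(frozen=True)
class ElementalFormula:
    """Non-negative integer element counts; the unit of all mass arithmetic.

    Addition and subtraction are element-wise; subtraction raises
    :class:`InfeasibleDeltaError` rather than ever producing a negative
    count.  The empty formula is the additive identity with mass 0.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for sym, n in self.counts.items():
            if sym not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {sym!r}")
            if int(n) != n or n < 0:
                raise FormulaError(f"count for {sym!r} must be a non-negative integer")
            if n:
                clean[sym] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_string(cls, text: str) -> "ElementalFormula":
        return cls(_parse_counts(text))

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass in u."""
        return sum(MONOISOTOPIC_MASS[s] * n for s, n in self.counts.items())

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            left = merged.get(sym, 0) - n
            if left < 0:
                raise InfeasibleDeltaError(
                    f"cannot remove {other} from {self}: {sym} would go negative"
                )
            merged[sym] = left
        return ElementalFormula(merged)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __str__(self) -> str:
        return "".join(
            f"{sym}{n if n > 1 else ''}" for sym, n in _hill_order(self.counts)
        )

    def key(self) -> Tuple[Tuple[str, int], ...]:
        """Hashable canonical representation (Hill order)."""
        return tuple(_hill_order(self.counts))


@dataclass(frozen=True)
class MassDelta:
    """A named, signed net elemental change (a biotransformation or a shift).

    ``delta`` maps element symbols to signed integers, e.g. oxidative
    defluorination is ``{"F": -1, "O": +1, "H": +1}``.  ``mass`` is derived
    from the atomic mass table, so a delta's label can never disagree with
    its arithmetic.
    """

    label: str
    delta: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for sym, n in self.delta.items():
            if sym not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {sym!r}")
            if n:
                clean[sym] = int(n)
        object.__setattr__(self, "delta", clean)

    @classmethod
    def from_terms(cls, label: str, terms: str) -> "MassDelta":
        """Parse signed terms such as ``"+O -H2"`` or ``"-C4H6O"``."""
        delta: Dict[str, int] = {}
        stripped = terms.strip()
        if stripped:
            for term in stripped.split():
                if term[0] not in "+-":
                    raise FormulaError(
                        f"delta term {term!r} must start with '+' or '-'"
                    )
                sign = 1 if term[0] == "+" else -1
                for sym, n in _parse_counts(term[1:]).items():
                    delta[sym] = delta.get(sym, 0) + sign * n
        return cls(label, delta)

    @property
    def mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[s] * n for s, n in self.delta.items())

    def __neg__(self) -> "MassDelta":
        return MassDelta(
            f"-({self.label})", {s: -n for s, n in self.delta.items()}
        )

    def __add__(self, other: "MassDelta") -> "MassDelta":
        merged = dict(self.delta)
        for sym, n in other.delta.items():
            merged[sym] = merged.get(sym, 0) + n
        return MassDelta(f"{self.label}+{other.label}", merged)

    def __bool__(self) -> bool:
        return bool(self.delta)

    def key(self) -> Tuple[Tuple[str, int], ...]:
        return tuple(sorted((s, n) for s, n in self.delta.items() if n))

    def __str__(self) -> str:
        sign = "+" if self.mass >= 0 else "-"
        return f"{self.label} ({sign}{abs(self.mass):.4f})"


PROTONATED_MOLECULE = "protonated_molecule"
EVEN_ELECTRON_CATION = "even_electron_cation"


@dataclass(frozen=True)
class IonSpecies:
    """A singly charged positive ion of a given elemental composition.

    ``protonated_molecule`` treats the formula as the neutral molecule and
    adds a proton; ``even_electron_cation`` treats the formula as the ion's
    own composition and subtracts the electron mass.
    """

    formula: ElementalFormula
    ion_type: str = PROTONATED_MOLECULE
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ValueError("only singly charged positive ions are supported")
        if self.ion_type not in (PROTONATED_MOLECULE, EVEN_ELECTRON_CATION):
            raise ValueError(f"unsupported ion_type {self.ion_type!r}")

    @property
    def mz(self) -> float:
        if self.ion_type == PROTONATED_MOLECULE:
            return self.formula.mass + PROTON_MASS
        return self.formula.mass - ELECTRON_MASS


# -- functional surface -------------------------------------------------------

def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string (e.g. ``"C25H24N2O2"``)."""
    return ElementalFormula.from_string(text)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Neutral monoisotopic mass of a formula, in u."""
    return f.mass


def ion_mz(ion: IonSpecies) -> float:
    """m/z of a singly charged ion."""
    return ion.mz


def protonated_mz(f: ElementalFormula) -> float:
    """[M+H]+ m/z of the neutral formula ``f``."""
    return f.mass + PROTON_MASS


def cation_mz(f: ElementalFormula) -> float:
    """m/z of an even-electron cation whose own composition is ``f``."""
    return f.mass - ELECTRON_MASS


def apply_delta(f: ElementalFormula, d: MassDelta) -> ElementalFormula:
    """Apply a signed elemental delta; raises if any count would go negative."""
    gained = {s: n for s, n in d.delta.items() if n > 0}
    lost = {s: -n for s, n in d.delta.items() if n < 0}
    try:
        return (f + ElementalFormula(gained)) - ElementalFormula(lost)
    except InfeasibleDeltaError as exc:
        raise InfeasibleDeltaError(
            f"delta {d.label!r} cannot apply to {f}: {exc}"
        ) from None


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def mda_error(observed: float, theoretical: float) -> float:
    """Signed absolute mass error in milli-Dalton (mDa)."""
    return 1e3 * (observed - theoretical)
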