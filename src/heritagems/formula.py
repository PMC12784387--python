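"""Elemental-formula arithmetic and exact monoisotopic mass calculation.

This is the numeric core of the package.  Every printed assignment in an
ultra-high-resolution APCI spectrum is an elemental formula, and reproducing
the sub-ppm mass errors of FT-ICR data requires two things done carefully:

* a *pinned* table of monoisotopic atomic masses (shipped as
  ``data/isotope_masses.tsv`` and versioned via :data:`CONSTANTS_VERSION`), and
* subtraction of the electron mass when converting a cation's atom inventory
  to m/z.  At m/z 300 one electron is about 1.8 ppm -- comparable to or larger
  than the calibration error of the instrument, so it cannot be ignored.

All ions handled here are singly charged even-electron cations ([M+H]+ and
its in-source fragments), the species an atmospheric-pressure chemical
ionization source produces in positive mode.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import Iterator, Mapping

__all__ = [
    "CONSTANTS_VERSION",
    "ATOMIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "Formula",
    "FormulaError",
    "parse_formula",
    "parse_ion",
    "monoisotopic_mass",
    "cation_mz",
    "ppm_error",
    "format_ppm",
    "WATER",
    "CO",
    "OXYGEN",
    "H2",
    "PROTON",
]

#: Version tag of the pinned constants table.  Reports record it so that a
#: theoretical m/z can always be traced to the constants that produced it.
CONSTANTS_VERSION = "2020.1"


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid formula arithmetic."""


def _load_atomic_masses() -> dict[str, float]:
    text = (
        resources.files("heritagems.data").joinpath("isotope_masses.tsv").read_text()
    )
    masses: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("element"):
            continue
        symbol, value = line.split("\t")
        masses[symbol] = float(value)
    return masses


#: Monoisotopic atomic mass per supported element, Da.
ATOMIC_MASS: Mapping[str, float] = _load_atomic_masses()

#: Electron rest mass, Da (CODATA-2018).
ELECTRON_MASS = 0.00054857990907

#: Proton mass, Da, defined as m(H atom) - m(e-).  This is the constant that
#: converts a neutral monoisotopic mass into an [M+H]+ m/z in one step.
PROTON_MASS = ATOMIC_MASS["H"] - ELECTRON_MASS

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping[str, int]):
    """An immutable multiset of atoms: non-negative integer count per element.

    Supports element-wise ``+``, ``-`` (never producing a negative count) and
    ``*`` by a non-negative integer.  Equality is count equality; instances
    are hashable and usable as dict keys.  ``str()`` renders Hill notation
    (C first, H second, remaining elements alphabetical).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None) -> None:
        clean: dict[str, int] = {}
        for element, n in (counts or {}).items():
            if element not in ATOMIC_MASS:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if not isinstance(n, int) or isinstance(n, bool):
                raise FormulaError(f"count for {element} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for {element}: {n}")
            if n > 0:
                clean[element] = n
        object.__setattr__(self, "_counts", dict(sorted(clean.items())))

    def __setattr__(self, name: str, value: object) -> None:  # pragma: no cover
        raise AttributeError("Formula is immutable")

    # Mapping interface -----------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element: object) -> bool:
        return element in self._counts

    # Arithmetic ------------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        if not isinstance(other, Formula):
            return NotImplemented
        merged = dict(self._counts)
        for element, n in other._counts.items():
            merged[element] = merged.get(element, 0) + n
        return Formula(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        if not isinstance(other, Formula):
            return NotImplemented
        merged = dict(self._counts)
        for element, n in other._counts.items():
            remaining = merged.get(element, 0) - n
            if remaining < 0:
                raise FormulaError(
                    f"subtraction would give {remaining} atoms of {element} "
                    f"({self} - {other})"
                )
            merged[element] = remaining
        return Formula(merged)

    def __mul__(self, k: int) -> "Formula":
        if not isinstance(k, int) or isinstance(k, bool):
            return NotImplemented
        if k < 0:
            raise FormulaError(f"cannot multiply a formula by {k}")
        return Formula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    # Identity --------------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"

    def __str__(self) -> str:
        return self.hill()

    def hill(self) -> str:
        """Canonical Hill-order string: C, H, then other elements A-Z."""
        parts: list[str] = []
        counts = dict(self._counts)
        order = [el for el in ("C", "H") if el in counts and "C" in counts]
        order += sorted(el for el in counts if el not in order)
        for element in order:
            n = counts[element]
            parts.append(element if n == 1 else f"{element}{n}")
        return "".join(parts)

    @property
    def mass(self) -> float:
        """Monoisotopic mass, Da."""
        return monoisotopic_mass(self)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string such as ``"C20H26O2"``.

    An element symbol without a number means a count of one.  Zero counts and
    zero-padded counts (``"C01"``) are rejected, as are unknown symbols.  A
    trailing ``"+"`` charge marker is rejected here; use :func:`parse_ion`
    for ion strings.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    body = text.strip()
    if body.endswith("+"):
        raise FormulaError(
            f"{text!r} carries a charge marker; use parse_ion() for ion strings"
        )
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(body):
        match = _TOKEN.match(body, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        symbol, digits = match.group(1), match.group(2)
        if symbol not in ATOMIC_MASS:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        if digits == "":
            n = 1
        else:
            if digits[0] == "0":
                raise FormulaError(
                    f"zero or zero-padded count for {symbol} in {text!r}"
                )
            n = int(digits)
        counts[symbol] = counts.get(symbol, 0) + n
        pos = match.end()
    return Formula(counts)


def parse_ion(text: str) -> tuple[Formula, int]:
    """Parse an ion string like ``"C20H27O2+"`` into (atoms, charge).

    The atom inventory is the full cation inventory (protons included); the
    number of trailing ``+`` signs is the positive charge.  A bare formula
    parses with charge 0.
    """
    body = text.strip()
    charge = len(body) - len(body.rstrip("+"))
    return parse_formula(body[: len(body) - charge] if charge else body), charge


def monoisotopic_mass(formula: Formula | Mapping[str, int]) -> float:
    """Sum of count x monoisotopic atomic mass over all elements, Da."""
    if not isinstance(formula, Formula):
        formula = Formula(dict(formula))
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


def cation_mz(atoms: Formula | Mapping[str, int], charge: int = 1) -> float:
    """m/z of a cation whose full atom inventory is ``atoms``.

    ``atoms`` must already include the ionizing proton(s); the electron mass
    is subtracted per elementary charge:
    ``(monoisotopic_mass(atoms) - charge * m_e) / charge``.
    """
    if not isinstance(charge, int) or isinstance(charge, bool) or charge <= 0:
        raise ValueError(f"charge must be a positive integer, got {charge!r}")
    return (monoisotopic_mass(atoms) - charge * ELECTRON_MASS) / charge


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million.

    ``(measured - theoretical) / theoretical * 1e6``; kept at full precision
    internally, rounded to two decimals only for display (:func:`format_ppm`).
    """
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical!r}")
    return (measured - theoretical) / theoretical * 1e6


def format_ppm(value: float) -> str:
    """Render a ppm error the way interpretation tables print it (2 decimals)."""
    return f"{value:.2f}"


# Small formulas used throughout assembly and modification chemistry.
WATER = parse_formula("H2O")
CO = parse_formula("CO")
OXYGEN = parse_formula("O")
H2 = parse_formula("H2")
PROTON = parse_formula("H")
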