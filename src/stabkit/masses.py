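"""Chemical-formula grammar and monoisotopic mass arithmetic.

Formulas are plain Hill-notation ASCII strings over the CHNOS element set
(the compositions assignable to vortioxetine and its degradation products).
Charge never lives in a formula string: an adduct/charge state is described
by :class:`IonSpec`, so the same neutral composition can be rendered as
``[M+H]+``, ``[M-H]-`` or a bare (electron-loss) cation.

All masses are monoisotopic, in Da, from the CODATA/NIST atomic mass
evaluation. Positive-mode m/z values subtract the electron mass by default
so that ``[M+H]+`` equals M + 1.00727646 (one proton).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Iterator, Mapping

__all__ = [
    "ElementMassTable",
    "Formula",
    "IonSpec",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "DEFAULT_MASS_TABLE",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "rdbe",
]

#: Mass of the proton, Da (CODATA).
PROTON_MASS = 1.00727646
#: Mass of the electron, Da (CODATA).
ELECTRON_MASS = 0.00054858

# NIST monoisotopic atomic masses (most abundant isotope), Da.
_CHNOS_MASSES = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}


class UnsupportedElementError(ValueError):
    """An element symbol outside the supported mass table."""


class FormulaParseError(ValueError):
    """A formula string that is not valid Hill-notation ASCII."""


class ElementMassTable:
    """Immutable element → monoisotopic mass lookup.

    Parameters
    ----------
    masses :
        Mapping of element symbol to monoisotopic mass in Da. All masses
        must be positive. Defaults to the built-in CHNOS table.
    """

    def __init__(self, masses: Mapping[str, float] | None = None) -> None:
        src = dict(_CHNOS_MASSES if masses is None else masses)
        for el, m in src.items():
            if not (m > 0):
                raise ValueError(f"mass for element {el!r} must be > 0, got {m}")
        self._masses = MappingProxyType(src)
        self.proton_mass = PROTON_MASS
        self.electron_mass = ELECTRON_MASS

    @property
    def elements(self) -> frozenset[str]:
        return frozenset(self._masses)

    def mass(self, element: str) -> float:
        try:
            return self._masses[element]
        except KeyError:
            raise UnsupportedElementError(
                f"element {element!r} is not in the mass table "
                f"(supported: {sorted(self._masses)})"
            ) from None

    def __contains__(self, element: str) -> bool:
        return element in self._masses

    def __iter__(self) -> Iterator[str]:
        return iter(self._masses)

    def to_csv(self, path: str | Path) -> None:
        """Dump the table as an auditable two-column CSV (element, mass_da)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["element", "monoisotopic_mass_da"])
            for el in sorted(self._masses):
                w.writerow([el, repr(self._masses[el])])
            w.writerow(["proton", repr(self.proton_mass)])
            w.writerow(["electron", repr(self.electron_mass)])


#: Shared default CHNOS table.
DEFAULT_MASS_TABLE = ElementMassTable()

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def _hill_order(counts: Mapping[str, int]) -> list[str]:
    # Hill convention: C first, then H, then all others alphabetically;
    # no carbon -> everything alphabetical.
    els = set(counts)
    if "C" in els:
        rest = sorted(els - {"C", "H"})
        return ["C"] + (["H"] if "H" in els else []) + rest
    return sorted(els)


@dataclass(frozen=True)
class Formula:
    """A neutral elemental composition (multiset of atoms).

    Counts are strictly positive; rendering is canonical Hill notation.
    """

    counts: Mapping[str, int]
    table: ElementMassTable = field(default=DEFAULT_MASS_TABLE, compare=False)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in dict(self.counts).items():
            if el not in self.table:
                raise UnsupportedElementError(
                    f"element {el!r} is not supported (have {sorted(self.table)})"
                )
            if not isinstance(n, (int,)) or isinstance(n, bool) or n < 1:
                raise FormulaParseError(
                    f"count for {el} must be a positive integer, got {n!r}"
                )
            clean[el] = int(n)
        object.__setattr__(self, "counts", MappingProxyType(clean))

    @classmethod
    def parse(cls, text: str, table: ElementMassTable = DEFAULT_MASS_TABLE) -> "Formula":
        return parse_formula(text, table=table)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged, table=self.table)

    def __str__(self) -> str:
        parts = []
        for el in _hill_order(self.counts):
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    @property
    def rdbe(self) -> float:
        return rdbe(self)


def parse_formula(text: str, table: ElementMassTable = DEFAULT_MASS_TABLE) -> Formula:
    """Parse a Hill-notation formula string, e.g. ``"C18H23N2S"``.

    Implicit count 1 is allowed (``"H2O"``). Repeated element symbols are
    accumulated. Parentheses, isotope labels and charges are rejected.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaParseError("formula string is empty")
    s = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaParseError(
                f"malformed formula {text!r} at position {pos} ({s[pos:]!r})"
            )
        el, digits = m.group(1), m.group(2)
        if el not in table:
            raise UnsupportedElementError(
                f"element {el!r} in {text!r} is not supported "
                f"(have {sorted(table)})"
            )
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaParseError(f"zero count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return Formula(counts, table=table)


def monoisotopic_mass(formula: Formula | Mapping[str, int] | str) -> float:
    """Monoisotopic mass of a neutral composition, Da.

    Additive over formula union; the empty composition has mass 0.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if isinstance(formula, Formula):
        table, counts = formula.table, formula.counts
    else:
        table, counts = DEFAULT_MASS_TABLE, formula
    return float(sum(n * table.mass(el) for el, n in counts.items()))


@dataclass(frozen=True)
class IonSpec:
    """A charged adduct species of a neutral composition.

    ``adduct`` is one of ``"+H"``, ``"-H"`` or ``None`` (bare ion by
    electron loss/gain). With ``electron_corrected`` (the default) the m/z
    accounts for the ``z`` missing electrons of a positive-mode ion, so a
    ``+H`` adduct adds exactly one proton mass.
    """

    neutral: Formula
    adduct: str | None = "+H"
    charge: int = 1
    electron_corrected: bool = True

    def __post_init__(self) -> None:
        if self.adduct not in ("+H", "-H", None):
            raise ValueError(f"unsupported adduct {self.adduct!r}")
        if not isinstance(self.charge, int) or self.charge < 1:
            raise ValueError(f"charge must be a positive integer, got {self.charge!r}")

    @property
    def mz(self) -> float:
        return ion_mz(self.neutral, self.adduct, self.charge, self.electron_corrected)


def ion_mz(
    neutral: Formula | str,
    adduct: str | None = "+H",
    charge: int = 1,
    electron_corrected: bool = True,
) -> float:
    """m/z of an adduct ion of ``neutral``.

    ``[M+H]+`` (corrected) = (M + z-independent proton mass)/z for z=1;
    ``None`` means a bare cation formed by electron loss.
    """
    if isinstance(neutral, str):
        neutral = parse_formula(neutral)
    if not isinstance(charge, int) or charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge!r}")
    if adduct not in ("+H", "-H", None):
        raise ValueError(f"unsupported adduct {adduct!r}")
    table = neutral.table
    m = monoisotopic_mass(neutral)
    if adduct == "+H":
        m += table.mass("H")
    elif adduct == "-H":
        m -= table.mass("H")
    if electron_corrected:
        # positive mode: the ion is missing z electrons
        m -= charge * table.electron_mass
    mz = m / charge
    if not mz > 0:
        raise ValueError(f"non-positive m/z ({mz}) for {neutral}")
    return mz


def ppm_error(observed: float, calculated: float) -> float:
    """Signed mass accuracy in parts per million.

    ``(observed − calculated)/calculated × 1e6`` — positive when the
    observed m/z is high.
    """
    if not calculated > 0:
        raise ValueError(f"calculated m/z must be > 0, got {calculated}")
    return (observed - calculated) / calculated * 1e6


def rdbe(formula: Formula | Mapping[str, int] | str) -> float:
    """Rings-plus-double-bond equivalents: C − H/2 + N/2 + 1.

    O and S are divalent and do not contribute. Half-integer values are
    legitimate for even-electron cation compositions (e.g. ``[M+H]+``
    written with the extra hydrogen included).
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    counts = formula.counts if isinstance(formula, Formula) else formula
    c = counts.get("C", 0)
    h = counts.get("H", 0)
    n = counts.get("N", 0)
    return c - h / 2.0 + n / 2.0 + 1.0
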