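"""Elemental-composition assignment for high-resolution ESI(+) fragment ions.

Two jobs live here:

* :func:`decompose_mass` — exhaustive search for the compositions whose ion
  m/z falls within a ppm tolerance of an observed mass, under per-element
  count bounds (the classic QTOF "elemental composition" calculation,
  restricted to CHNOS with an RDBE plausibility floor).
* :class:`FragmentAnnotator` — match an observed peak list against a fixed
  candidate set and emit an annotation table (compound, formula, observed,
  calculated, signed ppm error), the standard way degradation-product
  MS/MS tables are reported.

The annotator has two calculation modes. In ``"computed"`` mode (the
default) each candidate formula is interpreted as the *cation* composition
and its m/z is computed from the monoisotopic mass table (minus one
electron). In ``"provided"`` mode every candidate must carry its own
calculated m/z; this reproduces published tables whose calculated masses
come from vendor software and are not re-derivable from first principles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .masses import (
    DEFAULT_MASS_TABLE,
    ElementMassTable,
    Formula,
    ion_mz,
    parse_formula,
    ppm_error,
    rdbe,
)

__all__ = [
    "PeakList",
    "MassMatch",
    "FragmentTable",
    "FragmentAnnotator",
    "decompose_mass",
    "annotate_peaks",
    "build_annotation_report",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PeakList:
    """An observed positive-mode peak list for one compound."""

    compound: str
    mz: tuple[float, ...]
    intensities: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        mz = tuple(float(v) for v in self.mz)
        if any(not v > 0 for v in mz):
            raise ValueError("all m/z values must be strictly positive")
        if list(mz) != sorted(mz):
            mz = tuple(sorted(mz))
        object.__setattr__(self, "mz", mz)
        if self.intensities is not None:
            inten = tuple(float(v) for v in self.intensities)
            if len(inten) != len(mz):
                raise ValueError("intensities must align with m/z values")
            object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class MassMatch:
    observed_mz: float
    formula: str
    calc_mz: float
    ppm: float
    rdbe: float


@dataclass(frozen=True)
class FragmentTable:
    """Annotated ions for one compound, molecular ion first."""

    compound: str
    condition: str = "none"
    matches: tuple[MassMatch, ...] = ()
    unmatched: tuple[tuple[float, str], ...] = ()

    _CONDITIONS = ("oxidative", "photolytic", "oxidative/photolytic", "none")

    def __post_init__(self) -> None:
        if self.condition not in self._CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not one of {self._CONDITIONS}"
            )
        seen = [m.observed_mz for m in self.matches]
        if len(seen) != len(set(seen)):
            raise ValueError("an observed m/z may appear at most once")


def _neutral_window(
    target_mz: float,
    tolerance_ppm: float,
    adduct: str | None,
    charge: int,
    electron_corrected: bool,
    table: ElementMassTable,
) -> tuple[float, float]:
    """Invert the ion-m/z convention to a neutral-mass search window."""
    lo_mz = target_mz * (1.0 - tolerance_ppm * 1e-6)
    hi_mz = target_mz * (1.0 + tolerance_ppm * 1e-6)

    def neutral(mz: float) -> float:
        m = mz * charge
        if electron_corrected:
            m += charge * table.electron_mass
        if adduct == "+H":
            m -= table.mass("H")
        elif adduct == "-H":
            m += table.mass("H")
        return m

    return neutral(lo_mz), neutral(hi_mz)


def _normalize_bounds(
    bounds: dict[str, int | tuple[int, int]], table: ElementMassTable
) -> list[tuple[str, int, int]]:
    out = []
    for el, b in bounds.items():
        if el not in table:
            raise ValueError(f"bounded element {el!r} not in mass table")
        lo, hi = (0, b) if isinstance(b, int) else (int(b[0]), int(b[1]))
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid bounds for {el}: {b!r}")
        out.append((el, lo, hi))
    # heaviest first: tightens the mass pruning earliest
    out.sort(key=lambda t: -table.mass(t[0]))
    return out


def decompose_mass(
    target_mz: float,
    tolerance_ppm: float,
    bounds: dict[str, int | tuple[int, int]],
    adduct: str | None = "+H",
    charge: int = 1,
    electron_corrected: bool = True,
    min_rdbe: float | None = -0.5,
    table: ElementMassTable = DEFAULT_MASS_TABLE,
) -> list[MassMatch]:
    """Enumerate candidate neutral compositions for an observed ion m/z.

    Returns every composition within ``bounds`` whose ion m/z (under the
    given adduct/charge convention) lies within ``tolerance_ppm`` of
    ``target_mz``, as :class:`MassMatch` rows sorted by \\|ppm\\| with
    non-negative-RDBE candidates preferred on ties. Candidates with
    RDBE < ``min_rdbe`` (computed on the neutral composition) are dropped;
    pass ``min_rdbe=None`` to disable the filter.

    The search is an exact depth-first enumeration with mass-interval
    pruning, so it is exhaustive within the bounds.
    """
    if not tolerance_ppm > 0:
        raise ValueError(f"tolerance must be > 0 ppm, got {tolerance_ppm}")
    if not target_mz > 0:
        raise ValueError(f"target m/z must be > 0, got {target_mz}")
    lo, hi = _neutral_window(
        target_mz, tolerance_ppm, adduct, charge, electron_corrected, table
    )
    els = _normalize_bounds(bounds, table)
    if not els:
        return []
    masses = [table.mass(el) for el, _, _ in els]
    # max mass still addable from position i onward
    tail_max = [0.0] * (len(els) + 1)
    tail_min = [0.0] * (len(els) + 1)
    for i in range(len(els) - 1, -1, -1):
        el, lo_n, hi_n = els[i]
        tail_max[i] = tail_max[i + 1] + hi_n * masses[i]
        tail_min[i] = tail_min[i + 1] + lo_n * masses[i]

    found: list[MassMatch] = []
    counts: dict[str, int] = {}

    def dfs(i: int, acc: float) -> None:
        if acc + tail_min[i] > hi:
            return
        if acc + tail_max[i] < lo:
            return
        if i == len(els):
            if lo <= acc <= hi and counts:
                f = Formula({e: n for e, n in counts.items() if n > 0}, table=table)
                r = rdbe(f)
                if min_rdbe is not None and r < min_rdbe:
                    return
                mz = ion_mz(f, adduct, charge, electron_corrected)
                found.append(
                    MassMatch(target_mz, str(f), mz, ppm_error(target_mz, mz), r)
                )
            return
        el, lo_n, hi_n = els[i]
        m = masses[i]
        for n in range(lo_n, hi_n + 1):
            new = acc + n * m
            if new + tail_min[i + 1] > hi:
                break
            counts[el] = n
            dfs(i + 1, new)
        counts.pop(el, None)

    dfs(0, 0.0)
    found.sort(key=lambda mm: (abs(mm.ppm), mm.rdbe < 0, mm.formula))
    return found


class FragmentAnnotator(BaseEstimator):
    """Assign candidate formulas to observed fragment peaks by mass accuracy.

    Parameters
    ----------
    tolerance_ppm : float, default 15.0
        Maximum |ppm error| for an assignment.
    calc_mode : {"computed", "provided"}, default "computed"
        How the calculated m/z of each candidate is obtained. ``computed``
        treats the candidate formula as the cation's elemental composition
        and derives m/z from the mass table (z=1, electron-corrected);
        ``provided`` uses a calculated m/z supplied with each candidate.
    charge : int, default 1
    electron_corrected : bool, default True

    Attributes
    ----------
    candidates_ : list of (formula string, calculated m/z)
        Fixed after :meth:`fit`.
    """

    def __init__(
        self,
        tolerance_ppm: float = 15.0,
        calc_mode: str = "computed",
        charge: int = 1,
        electron_corrected: bool = True,
    ) -> None:
        self.tolerance_ppm = tolerance_ppm
        self.calc_mode = calc_mode
        self.charge = charge
        self.electron_corrected = electron_corrected

    def fit(self, candidates, y=None) -> "FragmentAnnotator":
        """Register the candidate set.

        ``candidates`` is an iterable of formula strings, of
        ``(formula, calc_mz)`` pairs, or a DataFrame with columns
        ``formula`` and (for provided mode) ``calc_mz``.
        """
        if not self.tolerance_ppm > 0:
            raise ValueError("tolerance_ppm must be > 0")
        if self.calc_mode not in ("computed", "provided"):
            raise ValueError(f"calc_mode must be computed|provided, got {self.calc_mode!r}")
        pairs: list[tuple[str, float | None]] = []
        if isinstance(candidates, pd.DataFrame):
            for _, row in candidates.iterrows():
                cm = row.get("calc_mz")
                pairs.append(
                    (str(row["formula"]), None if cm is None or pd.isna(cm) else float(cm))
                )
        else:
            for c in candidates:
                if isinstance(c, str):
                    pairs.append((c, None))
                else:
                    f, cm = c
                    pairs.append((str(f), None if cm is None else float(cm)))
        seen = set()
        resolved: list[tuple[str, float]] = []
        for text, cm in pairs:
            canon = str(parse_formula(text))
            if canon in seen:
                raise ValueError(f"duplicate candidate formula {canon!r}")
            seen.add(canon)
            if self.calc_mode == "provided":
                if cm is None:
                    raise ValueError(
                        f"provided mode requires a calculated m/z for {canon!r}"
                    )
                calc = cm
            else:
                # candidate formula = cation composition, z=1 electron loss
                calc = ion_mz(
                    canon, None, self.charge, self.electron_corrected
                )
            resolved.append((canon, calc))
        self.candidates_ = resolved
        return self

    def annotate(
        self, peaks: PeakList, condition: str = "none"
    ) -> FragmentTable:
        """Assign each observed peak to the candidate with the smallest
        |ppm error| inside the tolerance; ties go to the candidate whose
        RDBE is closest to an integer, then to the lexicographically first
        formula. Peaks with no candidate inside the tolerance are listed
        as unmatched. The match at the highest m/z (the molecular ion, in
        a well-formed table) is ordered first.
        """
        if not hasattr(self, "candidates_"):
            raise ValueError("annotator is not fitted; call fit(candidates) first")
        matches: list[MassMatch] = []
        unmatched: list[tuple[float, str]] = []
        for obs in peaks.mz:
            best = None
            for formula, calc in self.candidates_:
                p = ppm_error(obs, calc)
                if abs(p) > self.tolerance_ppm:
                    continue
                r = rdbe(formula)
                key = (abs(p), abs(r - round(r)), formula)
                if best is None or key < best[0]:
                    best = (key, MassMatch(obs, formula, calc, p, r))
            if best is None:
                unmatched.append((obs, "no candidate within tolerance"))
            else:
                matches.append(best[1])
        matches.sort(key=lambda m: -m.observed_mz)  # molecular ion first
        return FragmentTable(
            compound=peaks.compound,
            condition=condition,
            matches=tuple(matches),
            unmatched=tuple(unmatched),
        )

    # transform is the sklearn-facing alias
    transform = annotate


def annotate_peaks(
    peaks: PeakList,
    candidates,
    tolerance_ppm: float = 15.0,
    calc_mode: str = "computed",
    condition: str = "none",
) -> FragmentTable:
    """Functional wrapper over :class:`FragmentAnnotator`."""
    ann = FragmentAnnotator(tolerance_ppm=tolerance_ppm, calc_mode=calc_mode)
    return ann.fit(candidates).annotate(peaks, condition=condition)


def build_annotation_report(tables: list[FragmentTable]) -> pd.DataFrame:
    """Render annotation tables as one tidy frame, one row per ion.

    Columns: compound, condition, formula, observed_mz, calc_mz,
    ppm_error (full precision) and ppm_error_2dp (half-up rounded, the
    printed-table convention). Compounds keep their input order; within a
    compound the molecular ion leads and fragments follow ascending m/z.
    """
    rows = []
    for t in tables:
        ms = list(t.matches)
        ordered = ms[:1] + sorted(ms[1:], key=lambda m: m.observed_mz)
        for m in ordered:
            rows.append(
                {
                    "compound": t.compound,
                    "condition": t.condition,
                    "formula": m.formula,
                    "observed_mz": m.observed_mz,
                    "calc_mz": m.calc_mz,
                    "ppm_error": m.ppm,
                    "ppm_error_2dp": round_half_up(m.ppm, 2),
                }
            )
        for mz, reason in t.unmatched:
            rows.append(
                {
                    "compound": t.compound,
                    "condition": t.condition,
                    "formula": "",
                    "observed_mz": mz,
                    "calc_mz": np.nan,
                    "ppm_error": np.nan,
                    "ppm_error_2dp": np.nan,
                }
            )
    cols = [
        "compound",
        "condition",
        "formula",
        "observed_mz",
        "calc_mz",
        "ppm_error",
        "ppm_error_2dp",
    ]
    return pd.DataFrame(rows, columns=cols)
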