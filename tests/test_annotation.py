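"""Composition assignment: exhaustive decomposition and peak annotation."""

import itertools

import numpy as np
import pytest

from stabkit.annotation import (
    FragmentAnnotator,
    PeakList,
    annotate_peaks,
    build_annotation_report,
    decompose_mass,
    round_half_up,
)
from stabkit.masses import DEFAULT_MASS_TABLE, ELECTRON_MASS, ion_mz, monoisotopic_mass


def brute_force_decompose(target_mz, tol_ppm, bounds, adduct="+H", _cache={}):
    """Independent oracle: full grid enumeration, no pruning or search."""
    key = tuple(sorted(bounds.items()))
    if key not in _cache:
        names = sorted(bounds)
        table = DEFAULT_MASS_TABLE
        combos = np.array(
            list(itertools.product(*(range(bounds[e] + 1) for e in names))), dtype=int
        )
        masses = combos @ np.array([table.mass(e) for e in names])
        _cache[key] = (names, combos, masses)
    names, combos, masses = _cache[key]
    m = masses.copy()
    if adduct == "+H":
        m += DEFAULT_MASS_TABLE.mass("H")
    m -= ELECTRON_MASS
    ok = (np.abs((target_mz - m) / m) * 1e6 <= tol_ppm) & (combos.sum(axis=1) > 0)
    return {
        frozenset((e, int(n)) for e, n in zip(names, row) if n > 0)
        for row in combos[ok]
    }


class TestDecompose:
    def test_known_piperazine_loss_fragment(self):
        # [M+H]+ of a C10H14N2 phenylpiperazine at 163.1230
        res = decompose_mass(
            163.1230, 5.0, {"C": 12, "H": 20, "N": 3, "O": 2, "S": 1}
        )
        assert "C10H14N2" in [m.formula for m in res]

    def test_self_match_is_unique_at_tight_tolerance(self):
        target = ion_mz("C18H22N2S", "+H")
        res = decompose_mass(
            target, 0.1, {"C": (15, 20), "H": (18, 26), "N": (0, 3), "O": (0, 2), "S": (0, 2)}
        )
        assert [m.formula for m in res] == ["C18H22N2S"]
        assert res[0].ppm == pytest.approx(0.0, abs=1e-6)

    def test_piperazine_marker_ion(self):
        res = decompose_mass(44.0495, 5.0, {"C": 3, "H": 8, "N": 2, "O": 1})
        assert res and res[0].formula == "C2H5N"

    def test_empty_bounds_give_empty_result(self):
        assert decompose_mass(100.0, 5.0, {}) == []

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            decompose_mass(100.0, 0.0, {"C": 5})

    def test_matches_brute_force_oracle_on_random_targets(self, rng):
        bounds = {"C": 10, "H": 20, "N": 4, "O": 4, "S": 2}
        for target in rng.uniform(40.0, 280.0, size=100):
            got = {
                frozenset(
                    (e, n)
                    for e, n in _parse_counts(m.formula).items()
                )
                for m in decompose_mass(float(target), 20.0, bounds, min_rdbe=None)
            }
            assert got == brute_force_decompose(float(target), 20.0, bounds)

    def test_narrowing_tolerance_never_adds_candidates(self, rng):
        bounds = {"C": 10, "H": 20, "N": 4, "O": 4, "S": 2}
        for target in rng.uniform(50.0, 250.0, size=20):
            wide = {m.formula for m in decompose_mass(float(target), 20.0, bounds)}
            narrow = {m.formula for m in decompose_mass(float(target), 5.0, bounds)}
            assert narrow <= wide

    def test_results_sorted_by_abs_ppm(self):
        res = decompose_mass(150.0, 200.0, {"C": 10, "H": 20, "N": 3, "O": 3})
        ppms = [abs(m.ppm) for m in res]
        assert ppms == sorted(ppms)


def _parse_counts(formula: str) -> dict:
    import re

    out = {}
    for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if el:
            out[el] = out.get(el, 0) + (int(num) if num else 1)
    return out


class TestAnnotate:
    def test_provided_mode_reproduces_reported_errors(self, fragments):
        grp = fragments[fragments.compound == "VOR"]
        tab = annotate_peaks(
            PeakList("VOR", tuple(grp.observed_mz)),
            list(zip(grp.formula, grp.calc_mz)),
            tolerance_ppm=15.0,
            calc_mode="provided",
        )
        got = {round(m.observed_mz, 4): round_half_up(m.ppm, 2) for m in tab.matches}
        expected = dict(
            zip(grp.observed_mz.round(4), grp.reported_ppm)
        )
        for mz, printed in expected.items():
            assert got[mz] == pytest.approx(printed, abs=0.011)

    def test_computed_mode_self_generated_spectrum_matches_exactly(self):
        formulas = ["C18H23N2S", "C6H5S", "C8H10N", "C8H8NS", "C16H18NS"]
        mz = tuple(sorted(ion_mz(f, None) for f in formulas))
        tab = annotate_peaks(
            PeakList("VOR", mz), formulas, tolerance_ppm=1.0, calc_mode="computed"
        )
        assert len(tab.matches) == len(formulas)
        assert all(abs(m.ppm) < 1e-9 for m in tab.matches)
        assert tab.matches[0].formula == "C18H23N2S"  # molecular ion first

    def test_unmatched_peak_reported_with_reason(self):
        tab = annotate_peaks(
            PeakList("X", (500.0,)), ["C18H23N2S"], tolerance_ppm=10.0
        )
        assert tab.matches == ()
        assert tab.unmatched == ((500.0, "no candidate within tolerance"),)

    def test_duplicate_candidates_rejected(self):
        ann = FragmentAnnotator()
        with pytest.raises(ValueError, match="duplicate"):
            ann.fit(["C6H6", "C6H6"])

    def test_provided_mode_requires_calc_mz(self):
        ann = FragmentAnnotator(calc_mode="provided")
        with pytest.raises(ValueError, match="provided mode"):
            ann.fit(["C6H6"])

    def test_empty_peak_list_gives_empty_table(self):
        tab = annotate_peaks(PeakList("X", ()), ["C6H6"])
        assert tab.matches == () and tab.unmatched == ()

    def test_sklearn_params_round_trip(self):
        ann = FragmentAnnotator(tolerance_ppm=5.0, calc_mode="provided")
        assert ann.get_params()["tolerance_ppm"] == 5.0
        ann.set_params(tolerance_ppm=7.5)
        assert ann.tolerance_ppm == 7.5


class TestReport:
    def test_single_ion_single_row(self):
        tab = annotate_peaks(PeakList("X", (ion_mz("C6H6", None),)), ["C6H6"])
        rep = build_annotation_report([tab])
        assert len(rep) == 1
        assert rep.loc[0, "formula"] == "C6H6"

    def test_eight_compound_blocks(self, fragments):
        tables = []
        for comp, grp in fragments.groupby("compound", sort=False):
            tables.append(
                annotate_peaks(
                    PeakList(comp, tuple(grp.observed_mz)),
                    list(zip(grp.formula, grp.calc_mz)),
                    calc_mode="provided",
                    condition=grp.condition.iloc[0],
                )
            )
        rep = build_annotation_report(tables)
        assert rep.compound.nunique() == 8
        assert len(rep) == len(fragments)
        # deterministic: same input, same bytes
        assert rep.to_csv() == build_annotation_report(tables).to_csv()

    def test_empty_input_gives_header_only(self):
        rep = build_annotation_report([])
        assert rep.empty and "ppm_error" in rep.columns


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(2.675, 2) == 2.68
    assert round_half_up(-2.675, 2) == -2.68
    assert round_half_up(1.005, 2) == 1.01
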