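"""Bundled reference tables from the vortioxetine stability study.

Two kinds of reference data ship with the package:

* the published LC-ESI-QTOF-MS annotation table for vortioxetine (VOR)
  and its seven degradation products DP1–DP7 — observed fragment m/z,
  assigned cation composition, the calculated m/z reported with the
  assignment, and the reported ppm error (the vendor-calculated masses
  are not re-derivable from standard atomic masses, which is exactly
  what the annotator's provided-mass mode exists for);
* the reported degradation-kinetics designs — stress condition, sampling
  grid, selected order, fitted rate constant — which serve as generating
  parameters for simulations and as inputs when re-deriving half-life
  and shelf-life.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_vortioxetine_fragments",
    "degradation_designs",
    "OXIDATIVE_R2_BY_ORDER",
    "NOMINAL_C0_UG_ML",
]

#: Nominal working concentration of the assay, µg/mL.
NOMINAL_C0_UG_ML = 20.0

#: Reported linearized-fit R² per kinetic order for the oxidative
#: (15% H2O2, room temperature) series — the model-selection worked example.
OXIDATIVE_R2_BY_ORDER = {0: 0.973, 1: 0.9914, 2: 0.988}


def load_vortioxetine_fragments() -> pd.DataFrame:
    """The packaged fragment-annotation reference table.

    Columns: compound, condition, formula (cation composition, Hill
    notation), observed_mz, calc_mz (as reported), reported_ppm,
    is_molecular_ion (0/1). 75 ions over 8 compound blocks.
    """
    with resources.files("stabkit").joinpath(
        "data/vortioxetine_fragments.csv"
    ).open("rb") as fh:
        return pd.read_csv(fh)


def degradation_designs() -> pd.DataFrame:
    """Reported kinetic designs of the three degrading stress conditions.

    Columns: condition, order (selected), k (reported rate constant;
    h⁻¹-scale for order 1, mL·µg⁻¹·h⁻¹-scale for order 2), k_sd,
    times_h (tuple of sampling times).
    """
    rows = [
        {
            "condition": "oxidative_h2o2",
            "order": 1,
            "k": 0.1043,
            "k_sd": 0.0026,
            "times_h": (0, 1, 2, 3, 4, 5, 6),
        },
        {
            "condition": "uv254_solution",
            "order": 2,
            "k": 0.0028,
            "k_sd": 0.0001,
            "times_h": (0, 1, 3, 6, 8, 12, 16),
        },
        {
            "condition": "uv254_solid",
            "order": 2,
            "k": 0.0018,
            "k_sd": 0.0001,
            "times_h": (0, 1, 3, 6, 8, 16),
        },
    ]
    return pd.DataFrame(rows)
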