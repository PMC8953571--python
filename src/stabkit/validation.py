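"""ICH Q2-style method-validation statistics.

External-standard calibration (peak area vs concentration by ordinary
least squares), detection/quantitation limits from the 3.3·SD/S and
10·SD/S rules, inverse prediction of sample concentrations, recovery and
precision (%RSD) summaries, percent degradation, and the aggregation
tables a validation report prints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .annotation import round_half_up

__all__ = [
    "LinearCalibration",
    "RecoveryStats",
    "fit_calibration",
    "llod_lloq",
    "inverse_predict",
    "recovery_stats",
    "percent_degradation",
    "summarize_accuracy_precision",
    "summarize_robustness",
    "summarize_stability",
]


class LinearCalibration(BaseEstimator, RegressorMixin):
    """External-standard calibration line fitted by OLS.

    Fits peak area on concentration, and derives the ICH detection and
    quantitation limits LLOD = 3.3·SD/|S| and LLOQ = 10·SD/|S|.

    Parameters
    ----------
    sd_mode : {"residual", "intercept_se"}, default "residual"
        Which "standard deviation of the response" feeds the LLOD/LLOQ
        rule: the residual SD of the regression, sqrt(SSE/(n-2)), or the
        standard error of the intercept.

    Attributes
    ----------
    slope_ : float          area per µg/mL
    intercept_ : float      area
    r_ : float              Pearson correlation of (conc, area)
    residual_sd_ : float    sqrt(SSE/(n-2)); 0.0 when n == 2
    sd_response_ : float    the SD used for the limits (per ``sd_mode``)
    llod_, lloq_ : float    µg/mL
    n_ : int
    conc_range_ : (float, float)
    """

    def __init__(self, sd_mode: str = "residual") -> None:
        self.sd_mode = sd_mode

    def fit(self, conc, area) -> "LinearCalibration":
        if self.sd_mode not in ("residual", "intercept_se"):
            raise ValueError(f"sd_mode must be residual|intercept_se, got {self.sd_mode!r}")
        x = np.asarray(conc, dtype=float).ravel()
        y = np.asarray(area, dtype=float).ravel()
        if x.shape != y.shape or x.size < 2:
            raise ValueError("conc and area must be equal-length with n >= 2")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("calibration data contain non-finite values")
        if np.any(x <= 0):
            raise ValueError("concentrations must be > 0")
        if np.unique(x).size < 2:
            raise ValueError("degenerate design: need at least 2 distinct levels")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_ = float(res.rvalue)
        self.n_ = int(x.size)
        self.conc_range_ = (float(x.min()), float(x.max()))
        resid = y - (self.slope_ * x + self.intercept_)
        sse = float(np.sum(resid**2))
        self.residual_sd_ = float(np.sqrt(sse / (x.size - 2))) if x.size > 2 else 0.0
        if self.sd_mode == "residual":
            self.sd_response_ = self.residual_sd_
        else:
            self.sd_response_ = float(res.intercept_stderr)
        if self.slope_ == 0.0:
            # flat response: the curve is unusable, limits are undefined;
            # inverse prediction raises on use
            self.llod_ = self.lloq_ = float("nan")
        else:
            self.llod_, self.lloq_ = llod_lloq(self.sd_response_, self.slope_)
        return self

    def predict(self, conc) -> np.ndarray:
        return self.slope_ * np.asarray(conc, dtype=float) + self.intercept_

    def inverse_predict(self, area) -> np.ndarray:
        """Concentration from area: c = (area − intercept)/S.

        Negative and sub-limit results are returned as-is; use
        :meth:`flag` to classify them.
        """
        if self.slope_ == 0:
            raise ZeroDivisionError("slope is zero; cannot invert the curve")
        return (np.asarray(area, dtype=float) - self.intercept_) / self.slope_

    def flag(self, conc) -> np.ndarray:
        """Classify concentrations: 'ok', '<LLOQ', '<LLOD' or 'negative'."""
        c = np.atleast_1d(np.asarray(conc, dtype=float))
        out = np.full(c.shape, "ok", dtype=object)
        out[c < self.lloq_] = "<LLOQ"
        out[c < self.llod_] = "<LLOD"
        out[c < 0] = "negative"
        return out


def fit_calibration(data: pd.DataFrame) -> LinearCalibration:
    """Fit from a tidy calibration table with columns
    ``conc_ug_ml`` and ``area`` (replicate column optional)."""
    return LinearCalibration().fit(data["conc_ug_ml"], data["area"])


def llod_lloq(sd_response: float, slope: float) -> tuple[float, float]:
    """Detection and quantitation limits (µg/mL): 3.3·SD/|S| and 10·SD/|S|.

    The ratio LLOQ/LLOD is 10/3.3 identically.
    """
    if slope == 0:
        raise ZeroDivisionError("slope must be nonzero")
    if sd_response < 0:
        raise ValueError("sd_response must be >= 0")
    base = sd_response / abs(slope)
    return 3.3 * base, 10.0 * base


def inverse_predict(area, curve: LinearCalibration) -> np.ndarray:
    return curve.inverse_predict(area)


@dataclass(frozen=True)
class RecoveryStats:
    mean_recovery: float   # %
    rsd_pct: float         # %RSD over individual recoveries (sample SD)
    n: int
    level: str = ""


def recovery_stats(found, nominal: float, level: str = "") -> RecoveryStats:
    """Mean recovery (%) and %RSD of ``found`` against a nominal value.

    %RSD uses the sample (n−1) standard deviation; with a single
    determination the RSD is reported as 0.
    """
    if not nominal > 0:
        raise ValueError("nominal concentration must be > 0")
    f = np.asarray(found, dtype=float).ravel()
    if f.size < 1:
        raise ValueError("need at least one determination")
    rec = 100.0 * f / nominal
    mean = float(np.mean(rec))
    rsd = float(100.0 * np.std(rec, ddof=1) / mean) if f.size > 1 else 0.0
    return RecoveryStats(mean_recovery=mean, rsd_pct=rsd, n=int(f.size), level=level)


def percent_degradation(area_unstressed: float, area_stressed: float) -> float:
    """Relative loss of analyte peak area under stress, in percent.

    100·(unstressed − stressed)/unstressed; negative when the stressed
    area exceeds the reference (a real occurrence at low degradation).
    """
    if not area_unstressed > 0:
        raise ValueError("unstressed reference area must be > 0")
    return 100.0 * (area_unstressed - area_stressed) / area_unstressed


def _rounded(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        out[c] = out[c].map(lambda v: round_half_up(v, 2))
    return out


def summarize_accuracy_precision(
    found: pd.DataFrame, nominal_by_level: dict[str, float]
) -> pd.DataFrame:
    """Accuracy/precision table: one row per spiking level per series.

    ``found`` columns: level (str), series ("intra"/"inter"/...),
    found_ug_ml. Empty groups are omitted with a warning.
    """
    rows = []
    for (level, series), grp in found.groupby(["level", "series"], sort=True):
        vals = grp["found_ug_ml"].to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"empty group ({level}, {series}) omitted")
            continue
        st = recovery_stats(vals, nominal_by_level[str(level)], level=str(level))
        rows.append(
            {
                "level": str(level),
                "series": str(series),
                "n": st.n,
                "recovery_pct": st.mean_recovery,
                "rsd_pct": st.rsd_pct,
            }
        )
    df = pd.DataFrame(rows, columns=["level", "series", "n", "recovery_pct", "rsd_pct"])
    return _rounded(df, ["recovery_pct", "rsd_pct"])


def summarize_robustness(found: pd.DataFrame, nominal: float) -> pd.DataFrame:
    """Robustness table: per deliberately-varied condition, recovery and %RSD.

    ``found`` columns: condition, found_ug_ml.
    """
    rows = []
    for condition, grp in found.groupby("condition", sort=False):
        vals = grp["found_ug_ml"].to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"empty condition {condition!r} omitted")
            continue
        st = recovery_stats(vals, nominal)
        rows.append(
            {
                "condition": str(condition),
                "n": st.n,
                "recovery_pct": st.mean_recovery,
                "rsd_pct": st.rsd_pct,
            }
        )
    df = pd.DataFrame(rows, columns=["condition", "n", "recovery_pct", "rsd_pct"])
    return _rounded(df, ["recovery_pct", "rsd_pct"])


def summarize_stability(found: pd.DataFrame, nominal: float) -> pd.DataFrame:
    """Solution-stability table: per-time recovery ± SD plus a mean row.

    ``found`` columns: time_h, found_ug_ml.
    """
    rows = []
    for time_h, grp in found.groupby("time_h", sort=True):
        vals = grp["found_ug_ml"].to_numpy(dtype=float)
        rec = 100.0 * vals / nominal
        rows.append(
            {
                "time_h": float(time_h),
                "n": int(vals.size),
                "recovery_pct": float(np.mean(rec)),
                "sd": float(np.std(rec, ddof=1)) if vals.size > 1 else 0.0,
            }
        )
    df = pd.DataFrame(rows, columns=["time_h", "n", "recovery_pct", "sd"])
    if not df.empty:
        mean_row = pd.DataFrame(
            [
                {
                    "time_h": np.nan,
                    "n": int(df["n"].sum()),
                    "recovery_pct": float(df["recovery_pct"].mean()),
                    "sd": float(df["sd"].mean()),
                }
            ]
        )
        df = pd.concat([df, mean_row], ignore_index=True)
    return _rounded(df, ["recovery_pct", "sd"])
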