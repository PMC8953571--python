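"""Degradation-kinetics engine: linearized order fits, model selection by
R² (the "substitution method"), rate constants, half-life and shelf-life.

The three classical rate laws are fitted as straight lines on their
linearizing transforms of concentration C(t):

=====  ==================  ===============  ======================
order  transform           slope            k units
=====  ==================  ===============  ======================
0      C    = C0 − k·t     −k               µg·mL⁻¹·h⁻¹
1      ln C = ln C0 − k·t  −k               h⁻¹
2      1/C  = 1/C0 + k·t   +k               mL·µg⁻¹·h⁻¹
=====  ==================  ===============  ======================

R² is the squared Pearson correlation of (t, transformed C) — i.e. the
goodness of the linearized plot, which is what the substitution method
compares. Half-life and shelf-life (t90, time to 10% loss) default to the
conventional pharmaceutical constants 0.693/k and 0.105/k for first order
(pass ``exact_constants=True`` for ln 2 and ln(10/9)); for zero and second
order they are C0/(2k), 0.1·C0/k and 1/(k·C0), 1/(9·k·C0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "TimeCourse",
    "KineticFit",
    "ModelSelection",
    "KineticModel",
    "KineticOrderSelector",
    "fit_order",
    "select_model",
    "select_order_from_r2",
    "half_life",
    "shelf_life",
    "predict_conc",
]

#: Conventional first-order constants as printed in pharmaceutical texts.
T_HALF_CONST = 0.693
T90_CONST = 0.105


@dataclass(frozen=True)
class TimeCourse:
    """A (t, C) degradation series for one stress condition."""

    times: np.ndarray          # h, strictly increasing, starts at 0
    conc: np.ndarray           # µg/mL, > 0
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("times and conc must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(c))):
            raise ValueError("time course contains non-finite values")
        if t[0] != 0:
            raise ValueError("the series must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c <= 0):
            raise ValueError("concentrations must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)

    @property
    def c0(self) -> float:
        """Measured concentration at t = 0."""
        return float(self.conc[0])

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class KineticFit:
    order: int
    k: float                  # sign convention: > 0 for a degrading series
    intercept: float          # on the transformed scale
    r_squared: float
    k_se: float               # OLS standard error of the slope
    c0: float                 # C0 used for t1/2 / t90
    t_half: float
    t90: float
    zero_variance: bool = False


@dataclass(frozen=True)
class ModelSelection:
    best: KineticFit
    fits: dict[int, KineticFit]
    tie: bool = False

    @property
    def r2_table(self) -> dict[int, float]:
        return {o: f.r_squared for o, f in sorted(self.fits.items())}


def _transform(conc: np.ndarray, order: int) -> np.ndarray:
    if order == 0:
        return conc
    if order == 1:
        return np.log(conc)
    if order == 2:
        return 1.0 / conc
    raise ValueError(f"order must be 0, 1 or 2, got {order!r}")


def half_life(order: int, k: float, c0: float | None = None,
              exact_constants: bool = False) -> float:
    """Time for the concentration to fall to C0/2, in hours."""
    if not k > 0:
        raise ValueError(f"rate constant must be > 0, got {k}")
    if order == 1:
        return (np.log(2.0) if exact_constants else T_HALF_CONST) / k
    if c0 is None or not c0 > 0:
        raise ValueError("orders 0 and 2 need C0 > 0")
    if order == 0:
        return c0 / (2.0 * k)
    if order == 2:
        return 1.0 / (k * c0)
    raise ValueError(f"order must be 0, 1 or 2, got {order!r}")


def shelf_life(order: int, k: float, c0: float | None = None,
               exact_constants: bool = False) -> float:
    """Shelf-life t90 — time to 10% loss (90% potency), in hours."""
    if not k > 0:
        raise ValueError(f"rate constant must be > 0, got {k}")
    if order == 1:
        return (np.log(10.0 / 9.0) if exact_constants else T90_CONST) / k
    if c0 is None or not c0 > 0:
        raise ValueError("orders 0 and 2 need C0 > 0")
    if order == 0:
        return 0.1 * c0 / k
    if order == 2:
        return 1.0 / (9.0 * k * c0)
    raise ValueError(f"order must be 0, 1 or 2, got {order!r}")


def predict_conc(order: int, k: float, c0: float, t) -> np.ndarray | float:
    """Forward model C(t) for a given order; order 0 is floored at 0."""
    if not (k > 0 and c0 > 0):
        raise ValueError("k and C0 must be > 0")
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    if order == 0:
        out = np.maximum(c0 - k * tt, 0.0)
    elif order == 1:
        out = c0 * np.exp(-k * tt)
    elif order == 2:
        out = 1.0 / (1.0 / c0 + k * tt)
    else:
        raise ValueError(f"order must be 0, 1 or 2, got {order!r}")
    return float(out) if np.isscalar(t) else out


class KineticModel(BaseEstimator):
    """One fixed-order linearized kinetic fit.

    Parameters
    ----------
    order : {0, 1, 2}
    c0 : float or None
        Concentration used for t1/2 and t90. ``None`` (default) uses the
        measured concentration at t = 0; pass the nominal working
        concentration to mirror how shelf-life is usually quoted.
    exact_constants : bool, default False
        First-order t1/2/t90 from ln 2 and ln(10/9) instead of the
        conventional 0.693 and 0.105.

    Attributes (after fit)
    ----------------------
    k_, intercept_, r_squared_, k_se_, t_half_, t90_, fit_ (KineticFit)
    """

    def __init__(self, order: int = 1, c0: float | None = None,
                 exact_constants: bool = False) -> None:
        self.order = order
        self.c0 = c0
        self.exact_constants = exact_constants

    def fit(self, times, conc) -> "KineticModel":
        tc = times if isinstance(times, TimeCourse) else TimeCourse(times, conc)
        if len(tc) < 3:
            raise ValueError("need at least 3 time points to fit")
        y = _transform(tc.conc, self.order)
        zero_var = bool(np.allclose(y, y[0]))
        if zero_var:
            slope, intercept, r2, se = 0.0, float(y[0]), 0.0, 0.0
        else:
            res = stats.linregress(tc.times, y)
            slope, intercept = float(res.slope), float(res.intercept)
            r2, se = float(res.rvalue) ** 2, float(res.stderr)
        k = slope if self.order == 2 else -slope
        c0 = float(self.c0) if self.c0 is not None else tc.c0
        if k > 0:
            th = half_life(self.order, k, c0, self.exact_constants)
            t90 = shelf_life(self.order, k, c0, self.exact_constants)
        else:
            th = t90 = float("nan")  # non-degrading series
        self.k_, self.intercept_ = k, intercept
        self.r_squared_, self.k_se_ = r2, se
        self.t_half_, self.t90_ = th, t90
        self.fit_ = KineticFit(
            order=self.order, k=k, intercept=intercept, r_squared=r2,
            k_se=se, c0=c0, t_half=th, t90=t90, zero_variance=zero_var,
        )
        return self

    def predict(self, times) -> np.ndarray:
        """Predicted concentration at ``times`` from the fitted line."""
        t = np.asarray(times, dtype=float)
        y = self.intercept_ + (self.k_ if self.order == 2 else -self.k_) * t
        if self.order == 0:
            return np.maximum(y, 0.0)
        if self.order == 1:
            return np.exp(y)
        return 1.0 / y


class KineticOrderSelector(BaseEstimator):
    """Fit orders 0/1/2 and keep the one with the highest linearized R².

    Exact R² ties go to the lower order and are flagged on the result.
    """

    def __init__(self, c0: float | None = None, exact_constants: bool = False) -> None:
        self.c0 = c0
        self.exact_constants = exact_constants

    def fit(self, times, conc=None) -> "KineticOrderSelector":
        tc = times if isinstance(times, TimeCourse) else TimeCourse(times, conc)
        fits = {
            o: KineticModel(o, self.c0, self.exact_constants).fit(tc, None).fit_
            for o in (0, 1, 2)
        }
        r2 = {o: f.r_squared for o, f in fits.items()}
        best_order, tie = select_order_from_r2(r2)
        self.fits_ = fits
        self.best_order_ = best_order
        self.tie_ = tie
        self.selection_ = ModelSelection(best=fits[best_order], fits=fits, tie=tie)
        return self


def select_order_from_r2(r2_by_order: dict[int, float]) -> tuple[int, bool]:
    """Argmax-R² order selection with a lowest-order tie-break.

    Returns ``(order, tie_flag)``; usable directly on a published
    per-order R² table.
    """
    if not r2_by_order:
        raise ValueError("empty R² table")
    best = max(sorted(r2_by_order), key=lambda o: r2_by_order[o])
    tie = sum(1 for v in r2_by_order.values() if v == r2_by_order[best]) > 1
    if tie:
        best = min(o for o, v in r2_by_order.items() if v == r2_by_order[best])
    return best, tie


def fit_order(tc: TimeCourse, order: int, c0: float | None = None,
              exact_constants: bool = False) -> KineticFit:
    """Functional wrapper over :class:`KineticModel`."""
    return KineticModel(order, c0, exact_constants).fit(tc, None).fit_


def select_model(tc: TimeCourse, c0: float | None = None,
                 exact_constants: bool = False) -> ModelSelection:
    """Functional wrapper over :class:`KineticOrderSelector`."""
    return KineticOrderSelector(c0, exact_constants).fit(tc, None).selection_


def kinetics_report(selections: dict[str, ModelSelection]) -> pd.DataFrame:
    """Summary frame: one row per condition with the selected model."""
    rows = []
    for cond, sel in selections.items():
        f = sel.best
        rows.append(
            {
                "condition": cond,
                "order": f.order,
                "k": f.k,
                "k_se": f.k_se,
                "r_squared": f.r_squared,
                "t_half_h": f.t_half,
                "t90_h": f.t90,
                "tie": sel.tie,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["condition", "order", "k", "k_se", "r_squared", "t_half_h", "t90_h", "tie"],
    )


__all__.append("kinetics_report")
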