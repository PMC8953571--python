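"""System-suitability metrics from sampled chromatogram traces.

Implements the standard single-peak measurements of an isocratic LC assay:
apex retention time, peak height, widths at fractional heights, plate count
(half-height USP formula), asymmetry factor at 10% height, USP tailing
factor at 5% height, and capacity factor.

Measurement conventions (these matter at real grid resolutions):

* baseline — median of the first and last 5% of samples in the window;
  baseline noise — the MAD of the same samples, scaled to Gaussian sigma;
* apex — parabolic interpolation through the three samples around the
  maximum;
* fractional-height crossings — linear interpolation between samples,
  scanning outward from the apex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChromTrace",
    "PeakShape",
    "PeakMetrics",
    "NoPeakError",
    "measure_peak",
    "plates",
    "asymmetry_factor",
    "tailing_factor",
    "capacity_factor",
    "system_suitability",
]

_MAD_TO_SIGMA = 1.4826


class NoPeakError(ValueError):
    """No peak rises above the baseline noise in the requested window."""


@dataclass(frozen=True)
class ChromTrace:
    """A uniformly sampled detector trace (time in minutes)."""

    time: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or s.shape != t.shape:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if t.size < 10:
            raise ValueError("a trace needs at least 10 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
            raise ValueError("trace contains non-finite values")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must be uniform")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)

    @property
    def step(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class PeakShape:
    """Raw shape measurements of one peak (all times in minutes)."""

    apex_time: float
    height: float                 # above baseline
    baseline: float
    width_50: float               # full width at 50% height
    width_10: float               # full width at 10% height
    a10: float                    # leading half-width at 10% height
    b10: float                    # trailing half-width at 10% height
    a5: float                     # leading half-width at 5% height
    b5: float                     # trailing half-width at 5% height


@dataclass(frozen=True)
class PeakMetrics:
    """Suitability metrics derived from a :class:`PeakShape`."""

    t_r: float
    height: float
    width_50: float
    width_10: float
    a10: float
    b10: float
    asymmetry: float              # As = b/a at 10% height
    tailing: float                # USP Tf = (a+b)/(2a) at 5% height
    plates: float                 # N, half-height formula
    plates_per_m: float
    capacity: float | None        # k' (None when t0 unknown)


def _crossing(t: np.ndarray, s: np.ndarray, i_in: int, i_out: int, level: float) -> float:
    """Linear interpolation of the time where s crosses ``level`` between
    adjacent samples i_in (above) and i_out (below or equal)."""
    s0, s1 = s[i_in], s[i_out]
    if s1 == s0:
        return float(t[i_out])
    frac = (s0 - level) / (s0 - s1)
    return float(t[i_in] + frac * (t[i_out] - t[i_in]))


def _half_widths(
    t: np.ndarray, s: np.ndarray, i_apex: int, apex_time: float, level: float
) -> tuple[float, float]:
    """Leading/trailing half-widths at ``level`` around sample ``i_apex``."""
    left = None
    for i in range(i_apex, 0, -1):
        if s[i - 1] <= level < s[i]:
            left = _crossing(t, s, i, i - 1, level)
            break
    right = None
    for i in range(i_apex, len(s) - 1):
        if s[i + 1] <= level < s[i]:
            right = _crossing(t, s, i, i + 1, level)
            break
    if left is None or right is None:
        raise NoPeakError(
            f"peak does not descend to {level:.4g} on both sides inside the window"
        )
    return apex_time - left, right - apex_time


def measure_peak(trace: ChromTrace, window: tuple[float, float]) -> PeakShape:
    """Measure the single peak inside ``window`` (min).

    Raises :class:`NoPeakError` when nothing rises at least 3x the baseline
    noise above the baseline, and :class:`ValueError` when the apex sits on
    the window edge (the peak is cut off).
    """
    t0, t1 = float(window[0]), float(window[1])
    mask = (trace.time >= t0) & (trace.time <= t1)
    t = trace.time[mask]
    s = trace.signal[mask]
    if t.size < 10:
        raise ValueError("window contains fewer than 10 samples")
    edge = max(1, int(round(0.05 * t.size)))
    edges = np.concatenate([s[:edge], s[-edge:]])
    baseline = float(np.median(edges))
    noise = _MAD_TO_SIGMA * float(np.median(np.abs(edges - baseline)))

    y = s - baseline
    i_apex = int(np.argmax(y))
    h_sample = float(y[i_apex])
    floor = max(3.0 * noise, 1e-12 * max(1.0, abs(baseline)))
    if h_sample <= floor:
        raise NoPeakError(
            f"no peak above 3x baseline noise in window ({h_sample:.3g} <= {floor:.3g})"
        )
    if i_apex in (0, t.size - 1):
        raise ValueError("apex lies on the window edge; widen the window")

    # parabolic apex through the three highest samples around the maximum
    y0, y1, y2 = y[i_apex - 1], y[i_apex], y[i_apex + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        apex_time, height = float(t[i_apex]), h_sample
    else:
        delta = 0.5 * (y0 - y2) / denom
        delta = float(np.clip(delta, -1.0, 1.0))
        apex_time = float(t[i_apex] + delta * trace.step)
        height = float(y1 - 0.25 * (y0 - y2) * delta)

    sb = s - baseline
    a50, b50 = _half_widths(t, sb, i_apex, apex_time, 0.5 * height)
    a10, b10 = _half_widths(t, sb, i_apex, apex_time, 0.1 * height)
    a5, b5 = _half_widths(t, sb, i_apex, apex_time, 0.05 * height)
    return PeakShape(
        apex_time=apex_time,
        height=height,
        baseline=baseline,
        width_50=a50 + b50,
        width_10=a10 + b10,
        a10=a10,
        b10=b10,
        a5=a5,
        b5=b5,
    )


def plates(
    t_r: float, width: float, column_length_m: float = 0.15, method: str = "half_height"
) -> tuple[float, float]:
    """Theoretical plate count N and plates per meter N/m.

    ``half_height`` (USP/EP current convention): N = 5.54 (tR/w½)² with the
    width at 50% height. ``tangent``: N = 16 (tR/W)² with the tangent base
    width.
    """
    if not (t_r > 0 and width > 0 and column_length_m > 0):
        raise ValueError("t_r, width and column length must be > 0")
    if method == "half_height":
        n = 5.54 * (t_r / width) ** 2
    elif method == "tangent":
        n = 16.0 * (t_r / width) ** 2
    else:
        raise ValueError(f"unknown plate method {method!r}")
    return n, n / column_length_m


def asymmetry_factor(a: float, b: float) -> float:
    """Asymmetry factor As = b/a from 10%-height half-widths."""
    if not (a > 0 and b > 0):
        raise ValueError("half-widths must be > 0")
    return b / a


def tailing_factor(a5: float, b5: float) -> float:
    """USP tailing factor Tf = (a+b)/(2a) from 5%-height half-widths."""
    if not (a5 > 0 and b5 > 0):
        raise ValueError("half-widths must be > 0")
    return (a5 + b5) / (2.0 * a5)


def capacity_factor(t_r: float, t0: float) -> float:
    """Capacity (retention) factor k' = (tR − t0)/t0."""
    if not t0 > 0:
        raise ValueError("dead time t0 must be > 0")
    if t_r < t0:
        raise ValueError("t_r must be >= t0")
    return (t_r - t0) / t0


def system_suitability(
    trace: ChromTrace,
    window: tuple[float, float],
    t0: float | None = None,
    column_length_m: float = 0.15,
) -> PeakMetrics:
    """One-call suitability summary for the peak inside ``window``."""
    shape = measure_peak(trace, window)
    n, npm = plates(shape.apex_time, shape.width_50, column_length_m)
    return PeakMetrics(
        t_r=shape.apex_time,
        height=shape.height,
        width_50=shape.width_50,
        width_10=shape.width_10,
        a10=shape.a10,
        b10=shape.b10,
        asymmetry=asymmetry_factor(shape.a10, shape.b10),
        tailing=tailing_factor(shape.a5, shape.b5),
        plates=n,
        plates_per_m=npm,
        capacity=None if t0 is None else capacity_factor(shape.apex_time, t0),
    )
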