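"""Seeded generators emulating the instrument outputs of a forced
degradation study, so every analysis stage is testable end to end.

What is emulated, and how:

* time courses — the chosen rate law evaluated exactly, times a
  log-normal-style multiplicative error of a stated %RSD (peak areas and
  the concentrations read off them scale with the signal, so their error
  is proportional, roughly 1% RSD in routine assays);
* calibration tables — a linear detector response S·c + b plus additive
  Gaussian area noise;
* chromatograms — exponentially modified Gaussian (EMG) peaks, the
  standard model of a tailing LC peak, on a linearly drifting baseline
  with additive Gaussian noise (τ = 0 reduces exactly to a Gaussian);
* fragment spectra — exact ion m/z values jittered by a ppm-scale
  relative Gaussian error.

Every generator takes a ``seed`` and is bit-for-bit reproducible; each
call derives its own :class:`numpy.random.Generator`, no global state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erfc, erfcx

from .annotation import PeakList
from .chromatography import ChromTrace
from .kinetics import TimeCourse, predict_conc
from .masses import ion_mz

__all__ = [
    "SimConfig",
    "EMGPeak",
    "gen_time_course",
    "gen_calibration",
    "gen_chromatogram",
    "gen_fragment_spectrum",
    "emg_profile",
]

#: Defaults mirroring the study conditions: 20 µg/mL working concentration,
#: seven-level 1–100 µg/mL calibration, ~1% RSD replicate scatter.
DEFAULT_C0 = 20.0
DEFAULT_CAL_LEVELS = (1.0, 5.0, 10.0, 20.0, 40.0, 80.0, 100.0)
DEFAULT_SLOPE = 49940.0
DEFAULT_INTERCEPT = 31468.0


@dataclass(frozen=True)
class SimConfig:
    """Bundle of noise levels and design parameters for a simulation run."""

    seed: int = 0
    conc_noise_rsd_pct: float = 1.0
    area_noise_sd: float = 0.0
    trace_noise_sd: float = 0.0
    mz_jitter_ppm: float = 0.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("conc_noise_rsd_pct", "area_noise_sd", "trace_noise_sd", "mz_jitter_ppm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def gen_time_course(
    order: int,
    k: float,
    c0: float,
    times,
    noise_rsd_pct: float = 0.0,
    seed: int | None = 0,
    condition: str = "",
    replicates: int = 1,
) -> TimeCourse:
    """Simulate a degradation series C(t) with multiplicative noise.

    The noiseless curve is :func:`~stabkit.kinetics.predict_conc`; noise is
    log-normal-style, ``C·exp(z·rsd/100)`` with z ~ N(0, 1) per injection,
    so the series stays positive and the per-injection relative SD equals
    ``noise_rsd_pct`` to first order. With ``replicates > 1`` each reported
    point is the mean of that many independent noisy injections (stability
    studies typically report triplicate means). ``noise_rsd_pct = 0``
    returns the exact curve.
    """
    if noise_rsd_pct < 0:
        raise ValueError("noise_rsd_pct must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    t = np.asarray(list(times), dtype=float)
    if t.size == 0 or t[0] != 0:
        raise ValueError("times must start at 0")
    c = np.asarray(predict_conc(order, k, c0, t), dtype=float)
    if noise_rsd_pct > 0:
        rng = np.random.default_rng(seed)
        draws = c * np.exp(
            rng.standard_normal((replicates, t.size)) * noise_rsd_pct / 100.0
        )
        c = draws.mean(axis=0)
    return TimeCourse(t, c, condition=condition)


def gen_calibration(
    slope: float = DEFAULT_SLOPE,
    intercept: float = DEFAULT_INTERCEPT,
    concs=DEFAULT_CAL_LEVELS,
    replicates: int = 3,
    noise_sd_area: float = 0.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Simulate a calibration table (conc_ug_ml, replicate, area).

    Areas are S·c + b plus additive Gaussian noise of SD
    ``noise_sd_area``; at zero noise a refit returns the generating line
    with r = 1.
    """
    c = np.asarray(list(concs), dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if np.unique(c).size < 2:
        raise ValueError("need at least 2 distinct levels (design invalid downstream)")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_sd_area < 0:
        raise ValueError("noise_sd_area must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for conc in c:
        for rep in range(1, replicates + 1):
            area = slope * conc + intercept
            if noise_sd_area > 0:
                area += rng.normal(0.0, noise_sd_area)
            rows.append({"conc_ug_ml": conc, "replicate": rep, "area": area})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EMGPeak:
    """An exponentially modified Gaussian peak (times in minutes)."""

    t_r: float       # Gaussian center
    sigma: float     # Gaussian SD
    tau: float       # exponential tail time constant (0 = pure Gaussian)
    height: float    # apex height of the rendered profile

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


def emg_profile(t: np.ndarray, peak: EMGPeak) -> np.ndarray:
    """Evaluate one EMG peak, scaled so its maximum equals ``peak.height``.

    Uses the scaled-complementary-error-function form, numerically stable
    for small τ/σ; τ = 0 is exactly the Gaussian limit.
    """
    t = np.asarray(t, dtype=float)
    mu, s, tau = peak.t_r, peak.sigma, peak.tau
    z = (t - mu) / s
    if tau == 0.0:
        return peak.height * np.exp(-0.5 * z**2)

    def raw(zz: np.ndarray) -> np.ndarray:
        # exp(-z²/2)·erfcx(a) with a=(σ/τ−z)/√2; for a<0 erfcx overflows, so
        # use the equivalent exp(σ²/2τ² − zσ/τ)·erfc(a) there (its exponent
        # is provably negative when a<0)
        a = (s / tau - zz) / np.sqrt(2.0)
        out = np.empty_like(zz)
        pos = a >= 0
        out[pos] = np.exp(-0.5 * zz[pos] ** 2) * erfcx(a[pos])
        out[~pos] = np.exp((s / tau) * (s / (2 * tau) - zz[~pos])) * erfc(a[~pos])
        return out

    # normalize against a fine reference grid so the apex height does not
    # depend on the caller's sampling grid
    zref = np.linspace(-5.0, 5.0 + 10.0 * tau / s, 4001)
    peak_max = raw(zref).max()
    return peak.height * raw(z) / peak_max


def gen_chromatogram(
    peaks: list[EMGPeak],
    baseline_sd: float = 0.0,
    drift_per_min: float = 0.0,
    duration: float = 10.0,
    sampling_hz: float = 20.0,
    seed: int | None = 0,
) -> ChromTrace:
    """Simulate a detector trace: Σ EMG peaks + linear drift + noise.

    Warns when the narrowest peak spans fewer than 10 samples across its
    FWHM (metrics from such traces are grid-limited).
    """
    if baseline_sd < 0:
        raise ValueError("baseline_sd must be >= 0")
    n = int(round(duration * 60.0 * sampling_hz)) + 1
    t = np.linspace(0.0, duration, n)
    for p in peaks:
        if not (0.0 <= p.t_r <= duration):
            raise ValueError(f"peak at {p.t_r} min lies outside the {duration} min run")
        fwhm = 2.3548 * p.sigma
        if fwhm * 60.0 * sampling_hz < 10:
            warnings.warn(
                f"sampling too coarse: peak at {p.t_r} min has <10 points per FWHM"
            )
    signal = np.zeros_like(t)
    for p in peaks:
        signal += emg_profile(t, p)
    signal += drift_per_min * t
    if baseline_sd > 0:
        rng = np.random.default_rng(seed)
        signal += rng.normal(0.0, baseline_sd, size=t.shape)
    return ChromTrace(t, signal)


def gen_fragment_spectrum(
    formulas: list[str],
    compound: str = "synthetic",
    ppm_jitter_sd: float = 0.0,
    seed: int | None = 0,
    electron_corrected: bool = True,
) -> PeakList:
    """Simulate an observed peak list from cation compositions.

    Observed m/z = exact ion m/z × (1 + ε) with ε ~ N(0, ppm·1e-6); zero
    jitter returns the exact masses. Formulas follow the annotator's
    computed-mode convention (each formula is the cation composition).
    """
    if ppm_jitter_sd < 0:
        raise ValueError("ppm_jitter_sd must be >= 0")
    if not formulas:
        return PeakList(compound=compound, mz=())
    exact = np.array(
        [ion_mz(f, None, 1, electron_corrected) for f in formulas], dtype=float
    )
    if ppm_jitter_sd > 0:
        rng = np.random.default_rng(seed)
        exact = exact * (1.0 + rng.standard_normal(exact.size) * ppm_jitter_sd * 1e-6)
    return PeakList(compound=compound, mz=tuple(sorted(exact)))
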