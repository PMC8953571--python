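# Methods

This note records the models behind `stabkit`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data tests
do and do not demonstrate.

## Degradation kinetics

The decay of the intact drug under a stress condition is modelled by one
of three rate laws, fitted on the transform that makes each law linear in
time: C(t) for zero order, ln C(t) for first order, 1/C(t) for second
order. The fit is ordinary least squares of the transformed concentration
on time; k is the negated slope for orders 0–1 and the slope for order 2.
R² is the squared Pearson correlation of (t, transformed C) — the
goodness of the *linearized* plot, because order selection by the
substitution method compares exactly those plots. Nonlinear least squares
on the concentration scale would weight the points differently and is
deliberately not the default; the linearized fit is the method being
modelled.

Selection is argmax-R² over the three orders. Exact ties go to the lower
order (the more parsimonious mechanism) and are flagged.

Half-life and shelf-life use the conventional pharmaceutical constants

- order 1: t½ = 0.693/k, t90 = 0.105/k (`exact_constants=True` switches
  to ln 2 = 0.6931 and ln(10/9) = 0.10536; the rounded constants are the
  default because they are what stability reports print, and at the
  two-decimal reporting precision the choice is visible — 0.693/0.1043 =
  6.64 h but ln 2/0.1043 = 6.65 h);
- order 2: t½ = 1/(k·C₀), t90 = 1/(9·k·C₀);
- order 0: t½ = C₀/(2k), t90 = 0.1·C₀/k (standard extensions, labelled
  as such — zero-order series are fitted for comparison, rarely selected).

C₀ for these formulas defaults to the measured t=0 concentration but
should be the *nominal* working concentration (20 µg/mL in the reference
assay) when reproducing reported shelf-lives: stability reports quote
t½/t90 at the nominal level, not at the fitted intercept. Second-order k
carries units mL·µg⁻¹·h⁻¹ (the product k·C₀ is an inverse time), even
though reports often print it as h⁻¹.

The reported fit uncertainty is the OLS standard error of the slope;
replicate SD across repeated series is a different quantity and is left
to the caller (the generators can produce replicate series to estimate
it).

## Validation statistics

Calibration is OLS of area on concentration; r is the Pearson
correlation; the residual SD is √(SSE/(n−2)). The "standard deviation of
the response" in LLOD = 3.3·SD/|S| and LLOQ = 10·SD/|S| is ambiguous in
the guideline (residual SD, intercept SE and blank SD are all permitted);
the default is the residual SD, with `sd_mode="intercept_se"` available.
LLOQ/LLOD = 10/3.3 identically, whatever SD is used. A flat response
(slope 0) is a legal fit whose limits are NaN; using the curve for
inverse prediction then raises.

%RSD uses the sample (n−1) standard deviation of the individual
recoveries, divided by their mean. Percent degradation takes the
*measured* unstressed area as the reference, passed explicitly — measured
recovery and % degradation need not be complements, so the reference
cannot be inferred from nominal values. Negative % degradation is
representable (a stressed area can exceed the reference within noise).

Report tables round to 2 decimals, half-up (ties away from zero, the
convention of printed tables); machine-readable outputs keep full
precision.

## System suitability

The measurement conventions matter at realistic sampling rates
(10–50 Hz):

- baseline: median of the first and last 5% of the window's samples;
  noise: 1.4826 × MAD of the same samples. A peak must rise 3× the noise
  above baseline, else a no-peak error.
- apex: parabolic interpolation through the three samples around the
  maximum (grid-limited otherwise); an apex on the window edge is an
  error, as the peak is truncated.
- fractional-height crossings (50%, 10%, 5%): linear interpolation
  between samples, scanning outward from the apex.

Plate count uses the half-height form N = 5.54·(t_R/w½)² — the current
compendial formula; the tangent form 16·(t_R/W)² is available as an
option. N/m divides by the column length, default 0.15 m (a standard
150 mm analytical column). The asymmetry factor is b/a at 10% height;
the USP tailing factor (a+b)/(2a) at 5% height is computed separately.
Published suitability values rarely state which variant and height were
used, so recomputations from synthetic shapes are expected to agree only
to a few tenths of a percent in N.

## Mass arithmetic and composition assignment

Element masses are NIST monoisotopic values for C, H, N, O, S (the
composition space of vortioxetine and its degradation products);
proton = 1.00727646 Da, electron = 0.00054858 Da. The table is immutable,
extensible by constructing a new one, and dumpable to CSV for audit.
Formulas are plain Hill-notation strings; charge and adducts live in
`IonSpec`, never in the string. Positive-mode m/z subtracts the electron
mass by default, so [M+H]⁺ = M + one proton; the correction is a flag
because some published "calculated" masses are plainly computed without
it. ppm error is (observed − calculated)/calculated × 10⁶, signed.

Composition search is an exact depth-first enumeration over per-element
count bounds with mass-interval pruning (heaviest element first), checked
in the tests against an unpruned full-grid oracle. Candidates are ranked
by |ppm| (no better ranking information exists in a one-peak match), with
non-negative RDBE preferred on ties; the default plausibility floor is
RDBE ≥ −0.5, and there is deliberately no nitrogen-rule filter —
even-electron fragment cations violate it routinely.

The annotator's default tolerance is 15 ppm: wide for a modern QTOF, but
published degradation-product tables show |errors| up to ~11 ppm, and the
tolerance is a parameter, not a claim. The **provided-mass mode** exists
because vendor-reported "calculated" masses are not always re-derivable
from standard atomic masses (the bundled vortioxetine reference table is
the concrete case: only its (observed, calculated, ppm) triads are
internally consistent); in that mode the annotator reproduces the
published ppm errors exactly and makes no claim about the masses
themselves. Computed mode — formula interpreted as the cation
composition, m/z from the mass table — is the scientifically defensible
default.

## Synthetic data: scope and honesty

The generators encode the statistical structure the analyses assume:
linear detector response with additive area noise; exact rate-law decay
with multiplicative (log-normal-style) concentration noise, optionally
averaged over replicate injections (stability studies typically report
triplicate means, and the replicate structure materially sharpens order
selection); EMG peaks (the standard tailing-peak model) on a drifting
noisy baseline; exact ion masses with relative Gaussian jitter.

They do **not** emulate detector saturation, gradient artifacts,
co-eluting interferents, isotope patterns, intensity-dependent mass
error, or heteroscedastic calibration noise. Passing tests therefore
demonstrate that the analysis stages are correct inverses of the assumed
data-generating processes — not that the assumptions hold for any
particular instrument. Zero-noise generation inverts exactly through the
corresponding analysis stage by construction, and that invariant is
tested for every generator.

Default design sizes mirror a routine study and keep the whole suite
fast: 7-point time courses, 7-level × 3-replicate calibrations, 10-min
traces at 20 Hz, 200-replicate Monte-Carlo checks (≈3 s total test
runtime). The stochastic order-selection check uses triplicate means at
2% per-injection RSD — the study design it emulates; at single-injection
2% noise the selection rate drops to ≈80%, which is a property of the
design, not of the estimator.

## Numerical choices

- EMG evaluation uses erfcx where its argument is non-negative and the
  algebraically equivalent exp(σ²/2τ² − zσ/τ)·erfc form elsewhere, which
  is overflow-free; τ = 0 short-circuits to the exact Gaussian. Peak
  height is normalized on a fine internal grid so the rendered apex
  height does not depend on the caller's sampling grid.
- Constant (zero-variance) series fit with k = 0, R² = 0 and a
  `zero_variance` flag rather than NaNs.
- Random streams: every generator call builds its own
  `numpy.random.default_rng(seed)`; nothing touches global state.
- CSV loaders validate headers and cell types eagerly and report the file
  row and column of the first offending cell; unknown columns warn and
  are dropped.

## Known limitations

- Single-peak windows only; no deconvolution or resolution between
  adjacent peaks.
- Adducts beyond ±H, multiple charging and isotope envelopes are out of
  scope.
- Kinetic models are isothermal single-mechanism laws; no Arrhenius
  extrapolation.
- The provided-mass annotation mode inherits whatever convention the
  upstream software used; it reproduces, it does not validate.
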