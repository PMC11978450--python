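# Methods

This document describes the quantitative methods implemented in
`nirtherm`, the choices behind the synthetic data generators, and the
numerical and statistical conventions used throughout.

## 1. Solar-weighted reflectivity

The central quantity is the reflectivity of a surface over a wavelength
band \[λ₁, λ₂\]:

```
R = ∫ S(λ) I(λ) dλ / ∫ I(λ) dλ
```

where `S(λ)` is the measured reflectance (fraction, against a white
standard) and `I(λ)` a solar irradiance spectrum (W m⁻² nm⁻¹). `R` is
the fraction of incident solar energy in the band that the surface
reflects — the single number governing radiative heat gain. It is
reported in percent.

**Integration.** Both spectra are treated as piecewise-linear
interpolants of their samples. Integrals use the trapezoid rule on the
union of (a) a 1 nm lattice, (b) the band endpoints, and (c) every
measured wavelength of every input spectrum. Because all knots of the
interpolants are included, the trapezoid rule is *exact* for the
interpolants; a consequence used by the tests is that band-energy
fractions over any partition of the reference band sum to exactly 1
(within accumulation error ≈ 1e-15).

**Bands.** The solar reference band is 300–2600 nm; the working full
band is 300–1700 nm; reflectance data for real frogs end at 950 nm, so
the measured band for those is 300–950 nm and the extension tail is
950–1700 nm.

**Irradiance sources.** Quantitative energy-fraction statements use the
ASTM G-173-03 global-tilt reference spectrum (AM1.5, 37° tilt).
`nirtherm.solar.load_astm_g173` reads a local copy of NREL's CSV and
`download_astm_g173` fetches it (one-time, requires network). The table
is not redistributed with the package. For fully offline work,
`synthetic_am15_irradiance` builds a clearly-labelled synthetic
approximation: a 5778 K Planck envelope attenuated at air mass 1.5 by
Rayleigh scattering (τ = 0.008735 λ_µm⁻⁴·⁰⁸), a rural-aerosol Ångström
law (β = 0.05, α = 1.3), an ozone UV cut-off near 305 nm, Gaussian O₂
and H₂O absorption bands, plus a diffuse Rayleigh return term,
normalised to 1000 W m⁻² over 300–2600 nm. Its band fractions
(95.2% / 74.1% / 21.1% for 300–1700 / 300–950 / 950–1700 nm) are
approximations and deliberately *not* tuned to reproduce the standard
table's values (98.9% / 75.4% / 23.5%); use the real table when the
numbers matter.

## 2. Spectral processing

* **Calibration:** `reflectance = standard × (raw − dark) / (white −
  dark)` on the raw spectrum's grid; negative values from dark noise are
  clipped to zero; a white reference that fails to exceed dark at more
  than 1% of grid points is rejected.
* **Resampling** is linear interpolation and never extrapolates; users
  are directed to the extension operations instead.
* **Splicing** joins two instrument ranges (e.g. UV-Vis and NIR
  spectrometers) by averaging within a small window around the boundary;
  a gap larger than 10 nm between the inputs is an error.
* **Extensions** for reflectance data ending at 950 nm:
  * *Exponential decline:* `R(λ) = R(950)·exp(−k(λ − 950))` with
    `k = −m / R(950)`, where `m` is the least-squares slope of the
    trailing 100 nm of data — so the extension's initial derivative
    matches the data's trend. A non-negative trailing slope (or zero
    anchor reflectance) gives a constant extension (`k = 0`).
  * *Linear extension:* the 850–950 nm least-squares slope is continued
    from `R(950)`; negative values are clipped to zero.
  Both extensions are continuous at the anchor by construction, and a
  reflectivity computed over a band reaching past the anchor is tagged
  with the extension method used.

**Rounding convention.** Report tables round half-to-even at 1 decimal.
Because table inputs are decimal-printed values, float arithmetic leaves
~1e-15 representation noise around exact ties (e.g. a mean difference of
exactly 20.25 computes as 20.250000000000004); a guard rounding at 9
decimals removes the noise before the final half-even rounding.

## 3. Chamber heating experiment

The illumination schedule is: 5 min cooling, 30 min full-spectrum
heating (300–1700 nm), 15 min cooling, 30 min NIR-only heating
(700–1700 nm), 15 min cooling, 30 min UV-Vis-only heating (300–700 nm),
15 min cooling — 8400 s in total. Thermocouple traces are sampled
nominally every 20 s (±10% tolerated).

* **Segmentation** assigns samples to phases right-closed: a sample
  exactly on a boundary belongs to the later phase (the sample at the
  schedule's very end therefore belongs to no phase).
* **Heating rate** is the ordinary-least-squares slope of temperature
  against time over the first 2 minutes of a heating phase, converted to
  °C min⁻¹. The window is inclusive, so 20 s sampling yields 7 samples
  (0, 20, …, 120 s).
* **End temperature** is the last sample of the phase by default
  (`mode="final"`); the phase maximum is also reported so that
  non-monotone approaches are visible.

The synthetic trace generator uses a lumped first-order model: during a
heating phase the temperature relaxes exponentially (time constant τ)
toward `T_env + τ·a/60 − evaporative offset` with forcing
`a = gain · (1 − R/100) · f_band`, where `f_band` is the energy fraction
of the phase's illumination band. Stepping is exact (no Euler error).
Two consequences the tests rely on: initial heating rates scale as
`(1 − R/100)`, so R = 10 vs R = 40 gives rates in ratio exactly 1.5, and
the NIR-only and UV-Vis-only rates sum to the full-spectrum rate when
each phase starts from the environment temperature.

## 4. Field study statistics

Data are paired logger series (internal temperature of model frogs on
leaves, 5 min sampling, 09:00–17:00) and thermal-image observations
(model and adjacent-leaf surface temperature, two sessions per day).
Treatments: HNIR-coated, LNIR-coated, uncoated; sizes small/large;
models deployed in pairs within sites.

* **Surface-vs-leaf delta model:** response `model − leaf` surface
  temperature; fixed effects `treatment × size`; random intercepts for
  pair and site. Fitted by restricted maximum likelihood with
  `statsmodels` MixedLM (crossed random intercepts via variance
  components); the optimizer falls back through a sequence of methods
  (L-BFGS, BFGS, Powell, CG), keeping the first converged fit, before
  any variance component is declared singular. Wald
  chi-square tests are Type II: main effects are tested in the additive
  model, the interaction in the full model.
* **Daily 95th percentile model:** response is the daily 95th percentile
  of each logger series (numpy's linear interpolation of order
  statistics); fixed effects `treatment × size`; random intercepts for
  pair, site and logger.
* **Paired AR1 model:** response is the within-pair difference series
  (LNIR − HNIR by convention); fixed effects an intercept plus
  optionally centred air temperature and size; random intercepts for
  site and pair; residuals follow an AR1 process within each series.
  This model is fitted by a purpose-written profile maximum-likelihood
  routine (AR1 whitening plus a Woodbury identity for the random
  intercepts; Nelder-Mead over (arctanh φ, log variance ratios) with β
  and σ² profiled out), because `statsmodels` MixedLM does not support
  AR1 residuals. The implementation is validated in the test suite
  against R's `nlme::lme` (ML, `corAR1`), matching the intercept, its
  standard error, φ and σ² to ≲1e-3. If the optimisation fails the
  model falls back to independent residuals and flags it.
* **Singular variance components** are dropped iteratively (flagged in
  the result); if all are dropped the fit falls back to OLS (flagged).
* **Sunspot events** are transient spikes of a series above a running
  baseline (median of the preceding 60 min): a maximal run with excess
  ≥ 2 °C, provided the rise from half the threshold took ≤ 20 min
  (moving sunspots are sharp; slow drifts are not events). Overlapping
  events of a pair are merged, reporting the maximum within-pair
  difference over the merged window.

### Calibration of the statistical procedures

Wald tests and intervals are asymptotic; their finite-sample behaviour
was measured by simulation *before* the acceptance checks were frozen:

* *Paired AR1 intercept:* under a pure-AR1 null (10 series × 60 samples,
  φ = 0.6), 500 replicates give bias ≈ −0.001 °C and 95% CI coverage
  ≈ 0.97. With substantial between-site/pair variance and few sites the
  same interval *under-covers* (≈ 0.80 at 4 sites, ≈ 0.87 at 16),
  because cluster-level variances are ML-estimated from few clusters —
  the familiar z-vs-t small-cluster effect. Conclusion: intercept CIs
  are trustworthy when series-level information dominates; with few
  sites they should be treated as optimistic.
* *Factorial LMM type-I error:* the treatment term's Wald test is
  asymptotic in the number of pair clusters — the uncoated-vs-coated
  contrast is a between-pair comparison, so its effective sample size is
  the pair count, and the normal approximation to what is really a
  t-like statistic inflates rejection rates when pairs are few. Measured
  null rejection rates at α = 0.05: ≈ 9% at 6 sites × 1 day (18 pairs),
  ≈ 7–8% at 10 sites × 3 days (30 pairs), ≈ 5% at 20 sites × 2 days
  (60 pairs; 4.8% over 500 replicates), for both the delta and daily-p95
  models under REML (ML was a further ≈ 2 points worse at 30 pairs,
  which is why the factorial models use REML). The calibration
  simulations therefore use the 20 × 2 design; results from studies with
  few pairs should treat Wald p-values near the threshold as optimistic.

The synthetic field generator draws site, pair and logger offsets as
*persistent* properties keyed by unit identity (not redrawn per day), so
the generative structure matches the random-intercept structure of the
fitted models; day-to-day weather variation shared across sites is not
generated (a deliberate simplification — with balanced treatments it
would inflate residual variance and make the tests conservative, not
invalid).

## 5. What the synthetic generators do and don't emulate

They emulate: visible-similar/NIR-different coating spectra (Gaussian
green peak + logistic NIR rise to plateaus ≈ 0.55 vs ≈ 0.10), first-order
heating physics under the chamber schedule, diurnal temperature curves
peaking mid-afternoon with AR1 noise (φ = 0.6, 5 min sampling), paired
deployment structure (3 pairs per site: coated-small, coated-large,
uncoated pair), shared within-pair sunspot events with
treatment-dependent magnitudes (LNIR > uncoated > HNIR), an evaporative
≈ −2 °C offset for uncoated (agar) models, and logger calibration bias.

They do not emulate: conduction/convection asymmetries, humidity
dynamics, rain days, seasonal trends, logger dropout, or radiative
coupling between pair members. Absolute reflectivities of the synthetic
coatings (≈ 29% vs ≈ 9% over 300–1700 nm under the synthetic irradiance)
are in the plausible range but are not calibrated to any measured
specimen.

## 6. Reproducibility

Every stochastic routine takes an explicit seed; generators use named,
hashed substreams (`numpy` `SeedSequence` spawn keys from a BLAKE2 hash
of the stream name) so that adding a stream never shifts another
stream's draws, and per-unit effects (site, pair, logger) are functions
of (study seed, unit id) only. Pipeline runs are byte-deterministic for
a fixed configuration; the run report records input hashes, the seed,
the package version and the random-effect structures actually fitted.
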