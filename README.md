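# nirtherm

Solar-weighted reflectivity, radiative heating curves and paired
field-thermal statistics for near-infrared (NIR) reflectance experiments.

Leaves reflect most NIR light (700–2500 nm), which is invisible to known
animal visual systems but carries roughly half of solar energy. An
animal (or a model frog) sitting on a leaf can therefore match the leaf
visually while differing sharply in how much solar energy it absorbs.
`nirtherm` provides the analysis chain for experiments that test the
thermal consequences of that difference:

1. **Spectra** — read, calibrate (white/dark standard), resample, and
   splice reflectance spectra from UV-Vis and NIR spectrometers.
2. **Reflectivity** — the solar-weighted reflectivity
   `R = ∫S(λ)I(λ)dλ / ∫I(λ)dλ` over a wavelength band, band-energy
   fractions of an irradiance spectrum, spectral extensions (exponential
   decline or linear continuation past 950 nm), and group comparisons
   with report-table rounding.
3. **Thermal** — segmentation of chamber thermocouple traces by an
   illumination schedule, 2 min initial heating rates (°C min⁻¹), and
   end-of-phase temperatures.
4. **Field** — daily 95th percentiles of logger series, within-pair
   difference series, linear mixed models with Wald chi-square tests
   (crossed random intercepts; Type II), a paired-difference mixed model
   with AR1 residuals (validated against R's `nlme`), and detection of
   transient "sunspot" heating events.
5. **Synth** — seeded synthetic generators for coating spectra, chamber
   heating traces and multi-site paired field deployments, used for
   testing and for statistical calibration by simulation.
6. **Pipeline** — YAML-configurable end-to-end runs with deterministic
   outputs and a machine-readable run report.

See `docs/methods.md` for the models, conventions and calibration
evidence.

## Worked example

Reproduce a reflectivity report table's group differences from printed
per-specimen values (note the half-to-even rounding at the exact tie):

```python
from nirtherm import Band, group_comparison
from nirtherm.reflectivity import ReflectivityResult

band = Band(300.0, 950.0)
hi = [ReflectivityResult("", band, "measured", r) for r in (26.0, 33.3, 29.2)]
lo = [ReflectivityResult("", band, "measured", r) for r in (10.7, 7.8)]
cmp_ = group_comparison(hi, lo)
print(cmp_.mean_hi, cmp_.mean_lo, cmp_.mean_difference)
print(cmp_.mean_difference_rounded)
```

```
29.5 9.25 20.25
20.2
```

Compute the reflectivity of a synthetic high-NIR coating over
300–1700 nm under the bundled synthetic irradiance:

```python
from nirtherm import Band, reflectivity
from nirtherm.solar import synthetic_am15_irradiance
from nirtherm import synth

irr = synthetic_am15_irradiance()
spec = synth.spectrum(synth.hnir_spectrum_params(seed=0), label="HNIR")
print(reflectivity(spec, irr, Band(300.0, 1700.0)))
```

```
ReflectivityResult(label='HNIR', band=Band(lo_nm=300.0, hi_nm=1700.0), method='measured', R_percent=29.35...)
```

Fit the paired LNIR-vs-HNIR AR1 mixed model on a synthetic field study:

```python
import pandas as pd
from nirtherm import field as fm
from nirtherm import synth

series, obs = synth.field_study(synth.FieldParams(n_sites=5, n_days=3, seed=42,
                                                  sunspot_rate_per_day=0.5))
p95 = pd.concat([fm.daily_p95(s) for s in series if s.treatment != "air"],
                ignore_index=True)
fit = fm.fit_p95_lmm(p95)
print(fit.terms["treatment"])
```

## The ASTM G-173 solar reference table

Band-energy-fraction statements at standard quality (98.9% of 300–2600 nm
solar energy within 300–1700 nm; 75.4% within 300–950 nm; 23.5% within
950–1700 nm) require the ASTM G-173-03 global-tilt spectrum, which is
not redistributed here. With network access, download it once:

```python
from nirtherm.solar import download_astm_g173
download_astm_g173()  # stores it next to the package data
```

Offline, `synthetic_am15_irradiance()` provides a clearly-labelled
smooth approximation adequate for testing and relative comparisons, but
its band fractions (95.2% / 74.1% / 21.1%) are not the standard's.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes closed-form oracles, hypothesis property tests, an
independent cross-check of the AR1 mixed model against R's `nlme::lme`
(requires `Rscript` with the `nlme` package, as in the development
environment), and simulation-based calibration of the Wald tests and
intervals. One test requires a local copy of the ASTM G-173 table and
fails with a `FileNotFoundError` pointing to the download route when the
table is absent.
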