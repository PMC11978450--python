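"""Synthetic generators: determinism, structure and statistical character."""

from __future__ import annotations

import numpy as np
import pytest

from nirtherm import synth
from nirtherm.reflectivity import reflectivity
from nirtherm.spectra import Band
from nirtherm.thermal import default_schedule, heating_rate

FULL = Band(300.0, 1700.0)


# ---------------------------------------------------------------------------
# Reflectance spectra
# ---------------------------------------------------------------------------


def test_spectrum_generation_is_deterministic():
    a = synth.spectrum(synth.hnir_spectrum_params(seed=4))
    b = synth.spectrum(synth.hnir_spectrum_params(seed=4))
    assert np.array_equal(a.values, b.values)
    c = synth.spectrum(synth.hnir_spectrum_params(seed=5))
    assert not np.array_equal(a.values, c.values)


def test_hnir_and_lnir_spectra_differ_mainly_in_the_nir(irradiance):
    hi = synth.spectrum(synth.hnir_spectrum_params(seed=1), label="HNIR")
    lo = synth.spectrum(synth.lnir_spectrum_params(seed=1), label="LNIR")
    r_hi = reflectivity(hi, irradiance, FULL).R_percent
    r_lo = reflectivity(lo, irradiance, FULL).R_percent
    assert r_hi - r_lo > 15.0  # coatings are far apart overall …
    r_hi_vis = reflectivity(hi, irradiance, Band(300.0, 700.0)).R_percent
    r_lo_vis = reflectivity(lo, irradiance, Band(300.0, 700.0)).R_percent
    assert abs(r_hi_vis - r_lo_vis) < 5.0  # … but nearly identical in the visible


def test_generated_spectrum_spans_full_band():
    s = synth.spectrum(synth.hnir_spectrum_params(seed=0))
    assert s.covers(FULL)
    assert s.kind == "reflectance"


# ---------------------------------------------------------------------------
# Heating traces
# ---------------------------------------------------------------------------


def test_heating_trace_initial_rates_scale_with_absorbed_fraction(irradiance):
    """R = 10 vs R = 40 gives 2 min rates in exact ratio (1-0.1)/(1-0.4) = 1.5."""
    sched = default_schedule()
    params = synth.HeatParams()  # noiseless
    t10 = synth.heating_trace(10.0, sched, params, irradiance=irradiance)
    t40 = synth.heating_trace(40.0, sched, params, irradiance=irradiance)
    r10 = heating_rate(t10, sched, "full_spectrum", "internal_C")
    r40 = heating_rate(t40, sched, "full_spectrum", "internal_C")
    assert r10 / r40 == pytest.approx(1.5, rel=1e-9)


def test_heating_trace_band_ordering(irradiance):
    """Full-band forcing exceeds each sub-band's, and the sub-band rates
    sum to the full-band rate (energy fractions partition).

    Cooling phases here last 6 relaxation times so each heating phase
    starts from the environment temperature; with the study schedule's
    15 min cool-downs the later phases start slightly warm and their
    initial rates are correspondingly lower."""
    from nirtherm.spectra import FULL_BAND, NIR_BAND, UVVIS_BAND
    from nirtherm.thermal import Phase, RegimeSchedule

    sched = RegimeSchedule((
        Phase("pre_cool", "cooling", None, 300.0),
        Phase("full_spectrum", "heating", FULL_BAND, 1800.0),
        Phase("cool_1", "cooling", None, 3600.0),
        Phase("nir_only", "heating", NIR_BAND, 1800.0),
        Phase("cool_2", "cooling", None, 3600.0),
        Phase("uvvis_only", "heating", UVVIS_BAND, 1800.0),
        Phase("post_cool", "cooling", None, 900.0),
    ))
    tr = synth.heating_trace(20.0, sched, synth.HeatParams(), irradiance=irradiance)
    rates = {ph: heating_rate(tr, sched, ph, "internal_C")
             for ph in ("full_spectrum", "nir_only", "uvvis_only")}
    assert rates["full_spectrum"] > rates["nir_only"]
    assert rates["full_spectrum"] > rates["uvvis_only"]
    assert rates["nir_only"] + rates["uvvis_only"] == pytest.approx(
        rates["full_spectrum"], rel=0.02
    )


def test_uncoated_trace_is_depressed_by_evaporation(irradiance):
    sched = default_schedule()
    dry = synth.heating_trace(10.0, sched, synth.HeatParams(evap_offset_C=2.0),
                              irradiance=irradiance, treatment="LNIR")
    wet = synth.heating_trace(10.0, sched, synth.HeatParams(evap_offset_C=2.0),
                              irradiance=irradiance, treatment="uncoated")
    assert dry.internal_C.max() - wet.internal_C.max() == pytest.approx(2.0, abs=0.2)


# ---------------------------------------------------------------------------
# Field study
# ---------------------------------------------------------------------------


def test_field_day_structure_and_determinism():
    params = synth.FieldParams(n_sites=2, seed=9)
    series, obs = synth.field_day(params)
    # per site: 1 air series + 3 pairs × 2 members
    assert len(series) == 2 * 7
    treatments = [s.treatment for s in series]
    assert treatments.count("air") == 2
    assert treatments.count("HNIR") == treatments.count("LNIR") == 4
    assert treatments.count("uncoated") == 4
    # two sessions per model
    assert len(obs) == 2 * 6 * 2
    series2, _ = synth.field_day(params)
    for a, b in zip(series, series2):
        assert np.array_equal(a.internal_C, b.internal_C)


def test_site_and_pair_effects_persist_across_days():
    """Deploying the same models on another day keeps site/pair offsets:
    the between-day difference of a pair's daily means reflects only noise,
    not redrawn effects."""
    params = synth.FieldParams(n_sites=4, n_days=2, seed=3)
    series, _ = synth.field_study(params)
    by_model = {}
    for s in series:
        if s.treatment == "air":
            continue
        by_model.setdefault(s.model_id, []).append(float(np.mean(s.internal_C)))
    diffs = [abs(v[0] - v[1]) for v in by_model.values()]
    # AR1 noise mean over 96 samples has sd ≈ 0.05 °C; persistent effects
    # would add nothing, redrawn ±0.3 °C pair effects would dominate
    assert np.mean(diffs) < 0.15


def test_logger_bias_is_constant_within_a_logger():
    params = synth.FieldParams(n_sites=2, n_days=2, seed=8, logger_sd_C=1.0)
    base = synth.FieldParams(n_sites=2, n_days=2, seed=8, logger_sd_C=0.0)
    series_b, _ = synth.field_study(params)
    series_0, _ = synth.field_study(base)
    bias = {}
    for sb, s0 in zip(series_b, series_0):
        if sb.treatment == "air":
            continue
        assert sb.model_id == s0.model_id
        bias.setdefault(sb.model_id, []).append(
            float(np.mean(sb.internal_C - s0.internal_C))
        )
    for vals in bias.values():
        assert vals[0] == pytest.approx(vals[1], abs=1e-9)  # same bias both days
    assert np.std([v[0] for v in bias.values()]) > 0.3  # but varies across loggers


def test_ar1_noise_autocorrelation_increases_with_phi():
    rng1 = np.random.default_rng(1)
    rng2 = np.random.default_rng(1)
    low = synth._ar1_noise(rng1, 2000, 0.1, 1.0)
    high = synth._ar1_noise(rng2, 2000, 0.9, 1.0)

    def lag1(x):
        return float(np.corrcoef(x[:-1], x[1:])[0, 1])

    assert lag1(low) == pytest.approx(0.1, abs=0.1)
    assert lag1(high) == pytest.approx(0.9, abs=0.05)


def test_sunspot_magnitudes_follow_treatment():
    params = synth.FieldParams(n_sites=3, seed=21, sunspot_rate_per_day=3.0)
    series, _ = synth.field_day(params)
    base = synth.FieldParams(n_sites=3, seed=21, sunspot_rate_per_day=0.0)
    series0, _ = synth.field_day(base)
    peak = {}
    for sb, s0 in zip(series, series0):
        if sb.treatment in ("HNIR", "LNIR"):
            peak.setdefault(sb.treatment, []).append(
                float(np.max(sb.internal_C - s0.internal_C))
            )
    # LNIR models heat more in sunspots than their HNIR partners
    assert np.mean(peak["LNIR"]) > np.mean(peak["HNIR"])
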