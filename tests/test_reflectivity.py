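"""Solar-weighted reflectivity, band fractions, extensions and comparisons."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from nirtherm.reflectivity import (
    band_energy_fraction,
    extend_exponential,
    extend_linear,
    group_comparison,
    reflectivity,
    round_half_even,
)
from nirtherm.spectra import Band, SOLAR_REFERENCE_BAND, Spectrum, SpectrumError

FULL = Band(300.0, 1700.0)


# ---------------------------------------------------------------------------
# Reflectivity integral
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None)
@given(const=st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
def test_constant_reflectance_gives_the_constant(const):
    """R of a flat spectrum equals the constant, whatever the irradiance."""
    w = np.linspace(300.0, 1700.0, 8)
    s = Spectrum(w, np.full(8, const), kind="reflectance")
    wi = np.linspace(300.0, 1700.0, 57)
    irr = Spectrum(wi, 1.0 + np.sin(wi / 90.0) ** 2, kind="irradiance")
    r = reflectivity(s, irr, FULL)
    assert r.R_percent == pytest.approx(100.0 * const, abs=1e-9)


def test_reflectivity_matches_adaptive_quadrature(irradiance):
    """Trapezoid on the knot-union grid agrees with scipy.integrate.quad."""
    w = np.linspace(300.0, 1700.0, 29)
    vals = 0.1 + 0.4 / (1.0 + np.exp(-(w - 705.0) / 30.0))
    s = Spectrum(w, vals, kind="reflectance")
    r = reflectivity(s, irradiance, FULL)

    knots = np.unique(np.concatenate([w, irradiance.wavelengths_nm]))
    knots = knots[(knots >= 300.0) & (knots <= 1700.0)]

    def f_num(x):
        return s.interp([x])[0] * irradiance.interp([x])[0]

    def f_den(x):
        return irradiance.interp([x])[0]

    # integrate piecewise between knots (the integrand is piecewise smooth)
    num = sum(quad(f_num, a, b, limit=200)[0] for a, b in zip(knots[:-1], knots[1:]))
    den = sum(quad(f_den, a, b, limit=200)[0] for a, b in zip(knots[:-1], knots[1:]))
    assert r.R_percent == pytest.approx(100.0 * num / den, rel=1e-6)


def test_reflectivity_requires_band_coverage(irradiance):
    short = Spectrum(np.linspace(300.0, 950.0, 10), np.full(10, 0.2), kind="reflectance")
    with pytest.raises(SpectrumError, match="950"):
        reflectivity(short, irradiance, FULL)


def test_reflectivity_checks_spectrum_kinds(irradiance):
    s = Spectrum([300.0, 1700.0], [0.2, 0.2], kind="reflectance")
    with pytest.raises(SpectrumError):
        reflectivity(irradiance, irradiance, FULL)
    with pytest.raises(SpectrumError):
        reflectivity(s, s, FULL)


# ---------------------------------------------------------------------------
# Band energy fractions
# ---------------------------------------------------------------------------


def test_band_fractions_partition_to_one(irradiance):
    """Fractions over a partition of the reference band sum to exactly 1."""
    edges = [300.0, 700.0, 950.0, 1444.5, 1700.0, 2600.0]
    total = sum(
        band_energy_fraction(irradiance, Band(a, b), reference=SOLAR_REFERENCE_BAND)
        for a, b in zip(edges[:-1], edges[1:])
    )
    assert total == pytest.approx(1.0, abs=1e-9)


@settings(max_examples=20, deadline=None)
@given(
    cut=st.floats(min_value=301.0, max_value=2599.0, allow_nan=False),
)
def test_two_piece_partition_sums_to_one(irradiance, cut):
    f1 = band_energy_fraction(irradiance, Band(300.0, cut))
    f2 = band_energy_fraction(irradiance, Band(cut, 2600.0))
    assert f1 + f2 == pytest.approx(1.0, abs=1e-9)


def test_band_fraction_of_reference_is_one(irradiance):
    assert band_energy_fraction(irradiance, SOLAR_REFERENCE_BAND) == pytest.approx(1.0)


def test_band_outside_reference_rejected(irradiance):
    with pytest.raises(SpectrumError):
        band_energy_fraction(irradiance, Band(200.0, 400.0))


# ---------------------------------------------------------------------------
# Rounding
# ---------------------------------------------------------------------------


def test_round_half_even_ties():
    assert round_half_even(20.25, 1) == 20.2
    assert round_half_even(20.35, 1) == 20.4
    assert round_half_even(-20.25, 1) == -20.2


def test_round_half_even_is_robust_to_float_noise():
    # means of decimal-printed table values carry ~1e-15 representation noise
    assert round_half_even(20.250000000000004, 1) == 20.2
    assert round_half_even(20.249999999999996, 1) == 20.2


# ---------------------------------------------------------------------------
# Spectral extensions
# ---------------------------------------------------------------------------


def _declining_spectrum():
    w = np.arange(300.0, 951.0, 10.0)
    vals = 0.05 + 0.3 * np.exp(-(w - 300.0) / 500.0)
    return Spectrum(w, vals, kind="reflectance", label="declining")


def test_exponential_extension_continuous_at_anchor():
    s = _declining_spectrum()
    ext = extend_exponential(s)
    assert ext.interp([950.0])[0] == pytest.approx(s.interp([950.0])[0], abs=1e-12)
    assert ext.support.hi_nm == 1700.0
    assert ext.extension_method == "exponential_decline"


def test_exponential_extension_closed_form():
    # flat-then-linear tail: R(950) = 0.10, slope over 850-950 = -0.075/1000
    w = np.array([300.0, 850.0, 950.0])
    s = Spectrum(w, [0.175, 0.175, 0.10], kind="reflectance")
    ext = extend_exponential(s)
    k = (0.075 / 100.0) / 0.10  # -slope / R(anchor)
    expected = 0.10 * np.exp(-k * (1700.0 - 950.0))
    assert ext.interp([1700.0])[0] == pytest.approx(expected, rel=1e-6)


def test_exponential_extension_flat_tail_stays_constant():
    w = np.arange(800.0, 951.0, 10.0)
    s = Spectrum(w, np.full(w.size, 0.2), kind="reflectance")
    ext = extend_exponential(s)
    assert ext.interp([1700.0])[0] == pytest.approx(0.2)


def test_exponential_extension_rising_tail_stays_constant():
    w = np.arange(800.0, 951.0, 10.0)
    s = Spectrum(w, 0.1 + (w - 800.0) / 1500.0, kind="reflectance")
    ext = extend_exponential(s)
    anchor_val = s.interp([950.0])[0]
    assert ext.interp([1700.0])[0] == pytest.approx(anchor_val)


def test_linear_extension_continuous_and_clipped():
    # slope -0.10 per 100 nm from R(950) = 0.5 hits zero at 1450 nm
    w = np.array([300.0, 850.0, 950.0])
    s = Spectrum(w, [0.6, 0.6, 0.5], kind="reflectance")
    ext = extend_linear(s)
    assert ext.interp([950.0])[0] == pytest.approx(0.5, abs=1e-12)
    assert ext.interp([1200.0])[0] == pytest.approx(0.25, rel=1e-9)
    assert ext.interp([1450.0])[0] == pytest.approx(0.0, abs=1e-12)
    assert np.all(ext.values >= 0.0)
    assert ext.interp([1700.0])[0] == 0.0


@settings(max_examples=20, deadline=None)
@given(
    level=st.floats(min_value=0.05, max_value=0.8),
    slope=st.floats(min_value=-0.002, max_value=0.001),
)
def test_both_extensions_are_continuous_at_950(level, slope):
    w = np.arange(300.0, 951.0, 10.0)
    vals = np.clip(level + slope * (w - 900.0), 1e-4, 2.0)
    s = Spectrum(w, vals, kind="reflectance")
    at = s.interp([950.0])[0]
    for ext in (extend_exponential(s), extend_linear(s)):
        assert ext.interp([950.0])[0] == pytest.approx(at, abs=1e-9)
        assert np.all(ext.values >= 0.0)


def test_extension_requires_fit_window():
    s = Spectrum([900.0, 950.0], [0.2, 0.1], kind="reflectance")
    with pytest.raises(SpectrumError):
        extend_exponential(s)  # needs coverage from 850 nm
    with pytest.raises(SpectrumError):
        extend_linear(s)


def test_reflectivity_tags_extension_method(irradiance):
    s = extend_exponential(_declining_spectrum())
    tagged = reflectivity(s, irradiance, FULL)
    assert tagged.method == "exponential_decline"
    # a band that stops at the anchor is still fully measured
    measured = reflectivity(s, irradiance, Band(300.0, 950.0))
    assert measured.method == "measured"


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def _res(label, r, band=FULL, method="measured"):
    from nirtherm.reflectivity import ReflectivityResult

    return ReflectivityResult(label=label, band=band, method=method, R_percent=r)


def test_group_comparison_means_and_difference_are_exact():
    hi = [_res("a", 30.0), _res("b", 34.0)]
    lo = [_res("c", 10.0)]
    cmp_ = group_comparison(hi, lo)
    assert cmp_.mean_hi == 32.0
    assert cmp_.mean_lo == 10.0
    assert cmp_.mean_difference == 22.0
    assert cmp_.mean_difference_rounded == 22.0


def test_group_comparison_rejects_mixed_bands_and_methods():
    with pytest.raises(ValueError, match="bands"):
        group_comparison([_res("a", 30.0)], [_res("b", 10.0, band=Band(300.0, 950.0))])
    with pytest.raises(ValueError, match="methods"):
        group_comparison([_res("a", 30.0)], [_res("b", 10.0, method="linear_extension")])


def test_group_comparison_requires_nonempty_groups():
    with pytest.raises(ValueError):
        group_comparison([], [_res("b", 10.0)])
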