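"""Field-series statistics: quantiles, pairing, mixed models, sunspots."""

from __future__ import annotations

import os
import subprocess

import numpy as np
import pandas as pd
import pytest

from nirtherm import field as fm
from nirtherm import synth

from conftest import simulate_diff_series


def _series(temps, treatment="HNIR", size="small", pair_id="p0", site_id="s0",
            model_id="m0", start="2022-10-01T09:00:00", step_s=300):
    temps = np.asarray(temps, dtype=float)
    t0 = np.datetime64(start)
    times = t0 + np.arange(temps.size) * np.timedelta64(step_s, "s")
    return fm.FieldSeries(times=times, internal_C=temps, model_id=model_id,
                          treatment=treatment, size=size, pair_id=pair_id,
                          site_id=site_id, logger_id=model_id)


# ---------------------------------------------------------------------------
# Daily p95
# ---------------------------------------------------------------------------


def test_daily_p95_matches_order_statistic_interpolation():
    rng = np.random.default_rng(7)
    temps = rng.normal(25.0, 2.0, 96)
    out = fm.daily_p95(_series(temps))
    assert len(out) == 1
    x = np.sort(temps)
    # linear interpolation of order statistics at (n-1)·p
    pos = (temps.size - 1) * 0.95
    k = int(np.floor(pos))
    expected = x[k] + (pos - k) * (x[k + 1] - x[k])
    assert out["p95_C"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_daily_p95_splits_calendar_days():
    temps = np.concatenate([np.full(96, 20.0), np.full(96, 30.0)])
    t0 = np.datetime64("2022-10-01T09:00:00")
    times = np.concatenate(
        [t0 + np.arange(96) * np.timedelta64(300, "s"),
         t0 + np.timedelta64(1, "D") + np.arange(96) * np.timedelta64(300, "s")]
    )
    s = fm.FieldSeries(times=times, internal_C=temps, model_id="m", treatment="HNIR",
                       size="small", pair_id="p", site_id="s", logger_id="m")
    out = fm.daily_p95(s)
    assert list(out["p95_C"]) == [20.0, 30.0]
    assert list(out["day"]) == ["2022-10-01", "2022-10-02"]


def test_daily_p95_omits_short_days_with_warning():
    temps = np.full(10, 25.0)
    with pytest.warns(UserWarning, match="omitted"):
        out = fm.daily_p95(_series(temps))
    assert out.empty


# ---------------------------------------------------------------------------
# Pair differences
# ---------------------------------------------------------------------------


def test_pair_difference_orientation_lnir_minus_hnir():
    a = _series(np.full(96, 30.0), treatment="HNIR", model_id="h")
    b = _series(np.full(96, 31.0), treatment="LNIR", model_id="l")
    d1 = fm.pair_difference(a, b)
    d2 = fm.pair_difference(b, a)
    assert d1.orientation == d2.orientation == "LNIR-HNIR"
    assert np.allclose(d1.diff_C, 1.0)
    assert np.allclose(d2.diff_C, 1.0)


def test_pair_difference_explicit_orientation_is_antisymmetric():
    rng = np.random.default_rng(3)
    a = _series(25.0 + rng.normal(0, 1, 96), model_id="a")
    b = _series(25.0 + rng.normal(0, 1, 96), model_id="b", treatment="LNIR")
    dab = fm.pair_difference(a, b, orient=None)
    dba = fm.pair_difference(b, a, orient=None)
    assert np.allclose(dab.diff_C, -dba.diff_C)


def test_pair_difference_requires_same_pair():
    a = _series(np.full(96, 25.0), pair_id="p0")
    b = _series(np.full(96, 25.0), pair_id="p1", treatment="LNIR")
    with pytest.raises(fm.FieldDataError, match="pairs"):
        fm.pair_difference(a, b)


def test_pair_difference_rejects_poor_overlap():
    a = _series(np.full(96, 25.0))
    b = _series(np.full(96, 25.0), treatment="LNIR", start="2022-10-02T09:00:00")
    with pytest.raises(fm.FieldDataError, match="match"):
        fm.pair_difference(a, b)


def test_pair_difference_carries_matched_air():
    a = _series(np.full(96, 25.0))
    b = _series(np.full(96, 24.0), treatment="LNIR")
    air = _series(np.full(96, 20.0), treatment="air", model_id="air")
    d = fm.pair_difference(a, b, air=air)
    assert d.air_C is not None
    assert np.allclose(d.air_C, 20.0)


# ---------------------------------------------------------------------------
# Surface-vs-leaf deltas and the factorial mixed model
# ---------------------------------------------------------------------------


def test_surface_leaf_delta_drops_missing_leaf():
    obs = [
        fm.ThermalObservation(pair_id="p", model_id="m1", session="morning",
                              model_surface_C=26.0, leaf_surface_C=24.0,
                              treatment="HNIR", size="small", site_id="s"),
        fm.ThermalObservation(pair_id="p", model_id="m2", session="morning",
                              model_surface_C=26.0, leaf_surface_C=None,
                              treatment="LNIR", size="small", site_id="s"),
    ]
    out = fm.surface_leaf_delta(obs)
    assert len(out) == 1
    assert out["delta_C"].iloc[0] == pytest.approx(2.0)


def test_delta_lmm_recovers_treatment_offsets():
    """With a strong uncoated offset the treatment term is significant and
    the model-based group means recover the simulated offsets."""
    params = synth.FieldParams(n_sites=8, n_days=2, seed=11,
                               treatment_offset_C={"HNIR": 0.0, "LNIR": 0.0,
                                                   "uncoated": -2.0})
    _, obs = synth.field_study(params)
    fit = fm.fit_delta_lmm(fm.surface_leaf_delta(obs))
    assert fit.terms["treatment"].p < 1e-6
    assert fit.terms["treatment"].df == 2
    gm = fit.group_means
    assert gm["uncoated"][0] - gm["HNIR"][0] == pytest.approx(-2.0, abs=0.3)
    assert abs(gm["LNIR"][0] - gm["HNIR"][0]) < 0.3


def test_factorial_lmm_needs_enough_levels():
    df = pd.DataFrame({
        "delta_C": np.random.default_rng(0).normal(0, 1, 20),
        "treatment": ["HNIR"] * 20,
        "size": ["small"] * 10 + ["large"] * 10,
        "pair_id": [f"p{i%5}" for i in range(20)],
        "site_id": [f"s{i%3}" for i in range(20)],
    })
    with pytest.raises(fm.FieldDataError, match="level"):
        fm.fit_delta_lmm(df)


# ---------------------------------------------------------------------------
# Paired AR1 mixed model
# ---------------------------------------------------------------------------


def test_paired_ar1_recovers_phi_and_intercept():
    diffs = simulate_diff_series(seed=5, mu=0.8, n_sites=6, pairs_per_site=2,
                                 n=80, phi=0.6, innov=0.2)
    fit = fm.fit_paired_ar1(diffs, include_air=False, include_size=False)
    est, lo, hi = fit.intercept
    assert est == pytest.approx(0.8, abs=0.15)
    assert lo <= 0.8 <= hi
    assert not fit.intercept_crosses_zero
    assert fit.ar1_phi == pytest.approx(0.6, abs=0.15)


def test_paired_ar1_null_interval_covers_zero():
    diffs = simulate_diff_series(seed=19, mu=0.0, n_sites=6, pairs_per_site=2,
                                 n=80, phi=0.6, innov=0.2)
    fit = fm.fit_paired_ar1(diffs, include_air=False, include_size=False)
    assert fit.intercept_crosses_zero


def test_paired_ar1_matches_r_nlme(tmp_path):
    """Independent oracle: the same model fitted by R's nlme::lme (ML with
    an AR1 within-series correlation and site/pair random intercepts)."""
    diffs = simulate_diff_series(seed=123, mu=0.3, n_sites=3, pairs_per_site=2,
                                 n=60, phi=0.6, innov=0.2, site_sd=0.15,
                                 pair_sd=0.15)
    fit = fm.fit_paired_ar1(diffs, include_air=False, include_size=False)

    rows = []
    for d in diffs:
        for k, y in enumerate(d.diff_C):
            rows.append({"y": y, "site": d.site_id, "pair": d.pair_id, "t": k})
    csv = tmp_path / "diffs.csv"
    pd.DataFrame(rows).to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        "suppressMessages(library(nlme))\n"
        f'd <- read.csv("{csv}")\n'
        "m <- lme(y ~ 1, random = ~1 | site/pair, data = d,\n"
        "         correlation = corAR1(form = ~ t | site/pair), method = \"ML\")\n"
        "cat(fixef(m)[1], sqrt(vcov(m)[1,1]),\n"
        "    coef(m$modelStruct$corStruct, unconstrained=FALSE), m$sigma, sep=\"\\n\")\n"
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                         check=True, env={**os.environ})
    r_int, r_se, r_phi, r_sigma = (float(x) for x in out.stdout.split())

    est, lo, hi = fit.intercept
    se = (hi - est) / 1.959963984540054
    assert est == pytest.approx(r_int, abs=1e-3)
    assert se == pytest.approx(r_se, rel=1e-2)
    assert fit.ar1_phi == pytest.approx(r_phi, abs=1e-3)
    assert fit.sigma2 == pytest.approx(r_sigma**2, rel=1e-2)


def test_paired_ar1_filters_short_series():
    diffs = simulate_diff_series(seed=2, n=10)
    with pytest.raises(fm.FieldDataError, match="matched samples"):
        fm.fit_paired_ar1(diffs, include_air=False, include_size=False)


# ---------------------------------------------------------------------------
# Sunspot events
# ---------------------------------------------------------------------------


def _square_spike(base=24.0, spike=3.0, start=48, length=5, n=96):
    temps = np.full(n, base)
    temps[start:start + length] += spike
    return temps


def test_square_spike_is_one_event_with_known_excess():
    s = _series(_square_spike())
    events = fm.detect_sunspot_events(s, rise_C=2.0)
    assert len(events) == 1
    ev = events[0]
    assert ev.peak_excess_C == pytest.approx(3.0)
    # 5 samples at 5 min spacing: run span 20 min + one sample interval
    assert ev.duration_min == pytest.approx(25.0)


def test_slow_drift_is_not_an_event():
    temps = 24.0 + np.linspace(0.0, 6.0, 96)  # +6 °C over 8 h
    events = fm.detect_sunspot_events(_series(temps), rise_C=2.0)
    assert events == []


def test_subthreshold_spike_is_not_an_event():
    s = _series(_square_spike(spike=1.5))
    assert fm.detect_sunspot_events(s, rise_C=2.0) == []


def test_paired_events_report_paired_excess():
    a = _series(_square_spike(spike=4.0), treatment="LNIR", model_id="l")
    b = _series(_square_spike(spike=2.5), treatment="HNIR", model_id="h")
    paired = fm.paired_sunspot_events(a, b)
    assert len(paired) == 1
    assert paired[0].paired_excess_C == pytest.approx(1.5)
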