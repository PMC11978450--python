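"""Synthetic spectra, heating traces and field days.

These generators produce data with the statistical structure the analysis
modules assume, so the whole pipeline is testable without the original
measurements:

* reflectance spectra with a green peak and a high or low NIR plateau;
* first-order (lumped-capacitance) radiative heating curves under a
  cooling/heating regime schedule, where the radiative forcing scales with
  (1 − R/100) and the fraction of source energy inside the illumination
  band;
* diurnal field-logger series with a shared site-level signal, AR1 noise,
  and transient sunspot spikes whose timing is shared within a pair but
  whose magnitude depends on the coating.

All generators are deterministic per seed.  Each call derives independent
named substreams (e.g. noise vs event timing) from the seed, so switching
noise on or off does not shift event times.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from nirtherm.field import FieldSeries, ThermalObservation
from nirtherm.reflectivity import band_energy_fraction
from nirtherm.solar import synthetic_am15_irradiance
from nirtherm.spectra import Band, FULL_BAND, Spectrum
from nirtherm.thermal import HeatingTrace, RegimeSchedule, default_schedule

__all__ = [
    "SpectrumParams",
    "HeatParams",
    "FieldParams",
    "spectrum",
    "hnir_spectrum_params",
    "lnir_spectrum_params",
    "heating_trace",
    "field_day",
    "field_study",
]


def _rng(seed: int, stream: str) -> np.random.Generator:
    """A named substream of the given seed.

    The stream name is hashed in full so that names sharing a prefix
    (e.g. per-unit streams like ``"pair-effect:<id>"``) get independent
    substreams; the hash is stable across platforms and sessions.
    """
    digest = hashlib.blake2s(stream.encode(), digest_size=8).digest()
    key = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumParams:
    """Shape parameters for a synthetic frog-model reflectance spectrum.

    The curve is baseline + a Gaussian green peak + a logistic rise to a
    NIR plateau, mimicking measured model/frog spectra: similar green
    reflectance, strongly diverging NIR plateaus.
    """

    green_peak_nm: float = 550.0
    green_peak_height: float = 0.12
    green_width_nm: float = 40.0
    nir_plateau: float = 0.55
    nir_rise_nm: float = 705.0
    nir_rise_scale_nm: float = 30.0
    baseline: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("green_peak_height", "nir_plateau", "baseline"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.green_width_nm <= 0 or self.nir_rise_scale_nm <= 0:
            raise ValueError("widths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def hnir_spectrum_params(seed: int = 0, noise_sd: float = 0.005) -> SpectrumParams:
    """Preset for a high-NIR-reflectance coating (NIR plateau 0.55)."""
    return SpectrumParams(nir_plateau=0.55, noise_sd=noise_sd, seed=seed)


def lnir_spectrum_params(seed: int = 0, noise_sd: float = 0.005) -> SpectrumParams:
    """Preset for a low-NIR-reflectance coating (NIR plateau 0.10)."""
    return SpectrumParams(nir_plateau=0.10, noise_sd=noise_sd, seed=seed)


def spectrum(params: SpectrumParams, label: str = "synthetic") -> Spectrum:
    """Synthetic reflectance spectrum on a 1 nm grid from 300 to 1700 nm."""
    grid = np.arange(300.0, 1700.0 + 0.5, 1.0)
    green = params.green_peak_height * np.exp(
        -0.5 * ((grid - params.green_peak_nm) / params.green_width_nm) ** 2
    )
    nir = (params.nir_plateau - params.baseline) / (
        1.0 + np.exp(-(grid - params.nir_rise_nm) / params.nir_rise_scale_nm)
    )
    values = params.baseline + green + nir
    if params.noise_sd > 0:
        values = values + _rng(params.seed, "spectrum-noise").normal(
            0.0, params.noise_sd, grid.size
        )
    return Spectrum(grid, np.clip(values, 0.0, None), kind="reflectance", label=label)


# ---------------------------------------------------------------------------
# Heating traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeatParams:
    """Lumped first-order thermal model of a model frog in the chamber.

    ``gain_C_per_min`` is the initial radiative heating rate a perfectly
    absorbing (R = 0) model would show under full-band illumination;
    ``tau_s`` the exponential relaxation time toward equilibrium;
    ``evap_offset_C`` the equilibrium depression from evaporative cooling
    (applies to uncoated models only).
    """

    T_env_C: float = 18.0
    gain_C_per_min: float = 2.0
    tau_s: float = 600.0
    evap_offset_C: float = 0.0
    noise_sd_C: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.gain_C_per_min < 0:
            raise ValueError("gain must be non-negative")


def heating_trace(
    R_percent: float,
    schedule: Optional[RegimeSchedule] = None,
    params: HeatParams = HeatParams(),
    irradiance: Optional[Spectrum] = None,
    reference_band: Band = FULL_BAND,
    dt_s: float = 20.0,
    channel: str = "internal_C",
    label: str = "synthetic",
    treatment: str = "",
    size: str = "",
) -> HeatingTrace:
    """Simulate a 20 s-sampled temperature trace under a regime schedule.

    During a heating phase the temperature relaxes exponentially toward
    ``T_env + tau_s·a/60 − evaporative offset`` with forcing

        a = gain · (1 − R/100) · (energy fraction of the phase's band),

    where the energy fraction is computed from the illumination band of
    the phase relative to ``reference_band`` under ``irradiance`` (the
    synthetic AM1.5-like spectrum by default).  Cooling phases relax back
    toward the environment.  Exact exponential stepping at ``dt_s``;
    Gaussian observation noise per the seed.
    """
    schedule = schedule or default_schedule()
    if not (0.0 <= R_percent <= 100.0):
        raise ValueError("R_percent must be within [0, 100]")
    if irradiance is None:
        irradiance = synthetic_am15_irradiance()

    fractions: Dict[str, float] = {}
    for phase in schedule.phases:
        if phase.mode == "heating":
            fractions[phase.label] = band_energy_fraction(
                irradiance, phase.illumination, reference=reference_band
            )

    total = schedule.total_duration_s
    times = np.arange(0.0, total + 0.5 * dt_s, dt_s)
    temps = np.empty_like(times)
    bounds = schedule.boundaries_s
    T = params.T_env_C
    evap = params.evap_offset_C if treatment == "uncoated" else 0.0
    decay = np.exp(-dt_s / params.tau_s)
    for i, t in enumerate(times):
        temps[i] = T
        pidx = min(int(np.searchsorted(bounds, t, side="right")) - 1, len(schedule.phases) - 1)
        phase = schedule.phases[pidx]
        if phase.mode == "heating":
            a = params.gain_C_per_min * (1.0 - R_percent / 100.0) * fractions[phase.label]
            T_eq = params.T_env_C + params.tau_s * a / 60.0 - evap
        else:
            T_eq = params.T_env_C
        T = T_eq + (T - T_eq) * decay

    if params.noise_sd_C > 0:
        temps = temps + _rng(params.seed, "trace-noise").normal(0.0, params.noise_sd_C, temps.size)

    kwargs = {channel: temps}
    return HeatingTrace(time_s=times, label=label, treatment=treatment, size=size, **kwargs)


# ---------------------------------------------------------------------------
# Field days
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldParams:
    """Structure of a synthetic field deployment.

    Each site hosts three pairs: a small LNIR+HNIR pair, a large LNIR+HNIR
    pair and an uncoated large+small pair (six models per site, the pairing
    used in the field protocol).  Series share a site-level diurnal signal,
    carry per-series AR1 noise, and may be hit by transient sunspot events
    whose timing is shared within a pair and whose magnitude depends on the
    treatment (a low-NIR coating absorbs more of a sunspot's energy).
    Deployment runs 09:00–17:00 with 5 min logging; thermal images are
    taken in a morning and an afternoon session.
    """

    n_sites: int = 5
    n_days: int = 3
    diurnal_mean_C: float = 26.0
    diurnal_amplitude_C: float = 3.0
    site_sd_C: float = 0.6
    pair_sd_C: float = 0.3
    ar1_phi: float = 0.6
    innovation_sd_C: float = 0.15
    sunspot_rate_per_day: float = 0.0
    sunspot_magnitude_C: Optional[Dict[str, float]] = None
    sunspot_duration_min: float = 20.0
    evap_offset_C: float = -2.0
    treatment_offset_C: Optional[Dict[str, float]] = None
    obs_noise_sd_C: float = 0.3
    logger_sd_C: float = 0.0  # per-logger calibration bias, constant across days
    seed: int = 0

    def __post_init__(self) -> None:
        if not (abs(self.ar1_phi) < 1):
            raise ValueError("|ar1_phi| must be < 1")
        if self.n_sites < 1 or self.n_days < 1:
            raise ValueError("counts must be ≥ 1")
        if self.sunspot_magnitude_C is None:
            object.__setattr__(
                self, "sunspot_magnitude_C", {"HNIR": 2.5, "LNIR": 4.0, "uncoated": 3.0}
            )
        if self.treatment_offset_C is None:
            object.__setattr__(
                self,
                "treatment_offset_C",
                {"HNIR": 0.0, "LNIR": 0.0, "uncoated": self.evap_offset_C},
            )


def _ar1_noise(rng: np.random.Generator, n: int, phi: float, innovation_sd: float) -> np.ndarray:
    if innovation_sd == 0:
        return np.zeros(n)
    e = rng.normal(0.0, innovation_sd, n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, innovation_sd / np.sqrt(1.0 - phi**2))
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


_PAIR_LAYOUT = (
    ("coated_small", (("LNIR", "small"), ("HNIR", "small"))),
    ("coated_large", (("LNIR", "large"), ("HNIR", "large"))),
    ("uncoated", (("uncoated", "large"), ("uncoated", "small"))),
)


def field_day(
    params: FieldParams, day_index: int = 0
) -> Tuple[List[FieldSeries], List[ThermalObservation]]:
    """One deployment day of logger series and thermal-image observations.

    Returns six logger series per site (three pairs) plus one air series
    per site, and two thermal observations (morning and afternoon session)
    per model.  Deterministic per (seed, day_index).
    """
    base = np.datetime64("2022-10-01T09:00:00") + np.timedelta64(day_index, "D")
    n = 96  # 09:00–17:00 at 5 min
    times = base + np.arange(n) * np.timedelta64(300, "s")
    hours = 9.0 + np.arange(n) * 300.0 / 3600.0

    seed = params.seed + 7919 * day_index
    rng_noise = _rng(seed, "ar1-noise")
    rng_events = _rng(seed, "sunspot-events")
    rng_obs = _rng(seed, "thermal-observations")

    series: List[FieldSeries] = []
    observations: List[ThermalObservation] = []
    session_hours = {"morning": 11.5, "afternoon": 15.5}

    for s in range(params.n_sites):
        site_id = f"site{s:02d}"
        # site and pair effects are persistent properties (keyed by the study
        # seed and the unit id), so repeated deployments see the same offsets
        site_shift = _rng(params.seed, "site-effect:" + site_id).normal(0.0, params.site_sd_C)
        # diurnal bump peaking mid-afternoon
        diurnal = params.diurnal_mean_C + site_shift + params.diurnal_amplitude_C * np.exp(
            -0.5 * ((hours - 14.0) / 2.5) ** 2
        )
        series.append(
            FieldSeries(
                times=times,
                internal_C=diurnal
                + _ar1_noise(rng_noise, n, params.ar1_phi, params.innovation_sd_C),
                model_id=f"{site_id}_air",
                treatment="air",
                size="",
                pair_id=f"{site_id}_air",
                site_id=site_id,
                logger_id=f"{site_id}_air",
            )
        )

        for kind, members in _PAIR_LAYOUT:
            pair_id = f"{site_id}_{kind}"
            pair_shift = _rng(params.seed, "pair-effect:" + pair_id).normal(
                0.0, params.pair_sd_C
            )
            # sunspot event times are shared within the pair
            n_events = rng_events.poisson(params.sunspot_rate_per_day)
            event_starts = rng_events.uniform(0.5, 7.0, size=n_events)  # hours after 09:00
            bump = np.zeros(n)
            for t0 in event_starts:
                width_h = params.sunspot_duration_min / 60.0
                centre = 9.0 + t0 + width_h / 2.0
                bump += np.exp(-0.5 * ((hours - centre) / (width_h / 2.355)) ** 2)

            for treatment, size in members:
                model_id = f"{site_id}_{kind}_{treatment}_{size}"
                trend = (
                    diurnal
                    + pair_shift
                    + params.treatment_offset_C.get(treatment, 0.0)
                    + params.sunspot_magnitude_C.get(treatment, 0.0) * bump
                )
                noise = _ar1_noise(rng_noise, n, params.ar1_phi, params.innovation_sd_C)
                # logger calibration bias: tied to the logger, not the day
                logger_bias = (
                    _rng(params.seed, "logger-bias:" + model_id).normal(0.0, params.logger_sd_C)
                    if params.logger_sd_C > 0
                    else 0.0
                )
                series.append(
                    FieldSeries(
                        times=times,
                        internal_C=trend + noise + logger_bias,
                        model_id=model_id,
                        treatment=treatment,
                        size=size,
                        pair_id=pair_id,
                        site_id=site_id,
                        logger_id=model_id,  # each logger stays embedded in its model
                    )
                )
                for session, h in session_hours.items():
                    i = int(np.argmin(np.abs(hours - h)))
                    leaf = diurnal[i] + rng_obs.normal(0.0, params.obs_noise_sd_C)
                    surf = (
                        diurnal[i]
                        + pair_shift
                        + params.treatment_offset_C.get(treatment, 0.0)
                        + rng_obs.normal(0.0, params.obs_noise_sd_C)
                    )
                    observations.append(
                        ThermalObservation(
                            pair_id=pair_id,
                            model_id=model_id,
                            session=session,
                            model_surface_C=float(surf),
                            leaf_surface_C=float(leaf),
                            treatment=treatment,
                            size=size,
                            site_id=site_id,
                            air_C=float(diurnal[i]),
                        )
                    )
    return series, observations


def field_study(params: FieldParams) -> Tuple[List[FieldSeries], List[ThermalObservation]]:
    """A multi-day study: ``params.n_days`` deployments of the same models."""
    all_series: List[FieldSeries] = []
    all_obs: List[ThermalObservation] = []
    for d in range(params.n_days):
        s, o = field_day(params, day_index=d)
        all_series.extend(s)
        all_obs.extend(o)
    return all_series, all_obs
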