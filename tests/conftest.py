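"""Shared fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from nirtherm import field as fm
from nirtherm.solar import synthetic_am15_irradiance
from nirtherm.spectra import Spectrum


@pytest.fixture(scope="session")
def irradiance() -> Spectrum:
    """The bundled synthetic AM1.5-like irradiance (session-wide: it is pure)."""
    return synthetic_am15_irradiance()


@pytest.fixture
def flat_reflectance():
    """Factory for constant reflectance spectra on a coarse grid."""

    def make(value: float = 0.3, lo: float = 300.0, hi: float = 1700.0, n: int = 15) -> Spectrum:
        w = np.linspace(lo, hi, n)
        return Spectrum(w, np.full(n, value), kind="reflectance", label=f"flat{value}")

    return make


def simulate_diff_series(
    seed: int,
    mu: float = 0.0,
    n_sites: int = 5,
    pairs_per_site: int = 2,
    n: int = 60,
    phi: float = 0.6,
    innov: float = 0.2,
    site_sd: float = 0.0,
    pair_sd: float = 0.0,
) -> list:
    """Paired-difference series with known intercept and AR1 residuals.

    Used both by the field-model tests and the parameter-recovery
    acceptance checks; with ``site_sd = pair_sd = 0`` the data match the
    fitted model exactly up to boundary variance components.
    """
    rng = np.random.default_rng(seed)
    t0 = np.datetime64("2022-10-01T09:00:00")
    times = t0 + np.arange(n) * np.timedelta64(300, "s")
    diffs = []
    site_eff = rng.normal(0, site_sd, n_sites) if site_sd > 0 else np.zeros(n_sites)
    for s in range(n_sites):
        for p in range(pairs_per_site):
            pair_eff = rng.normal(0, pair_sd) if pair_sd > 0 else 0.0
            e = np.empty(n)
            e[0] = rng.normal(0, innov / np.sqrt(1 - phi**2))
            for k in range(1, n):
                e[k] = phi * e[k - 1] + rng.normal(0, innov)
            diffs.append(
                fm.DiffSeries(
                    times=times,
                    diff_C=mu + site_eff[s] + pair_eff + e,
                    pair_id=f"s{s}p{p}",
                    site_id=f"s{s}",
                    orientation="LNIR-HNIR",
                )
            )
    return diffs
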