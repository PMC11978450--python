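"""Solar irradiance references.

Two sources of the solar spectrum are supported:

* :func:`load_astm_g173` reads the ASTM G-173-03 reference table (AM1.5,
  37° tilt) if a local copy is available; :func:`download_astm_g173`
  fetches it from NREL when the machine has network access.  This is the
  spectrum used for quantitative solar-energy-fraction statements.
* :func:`synthetic_am15_irradiance` builds a SYNTHETIC smooth approximation
  of the AM1.5 global-tilt spectrum from a 5778 K Planck envelope and
  standard parametric atmospheric attenuation (Rayleigh scattering, a
  rural-aerosol Ångström law, an ozone UV cut-off, and the major O₂ and
  H₂O absorption bands).  It reproduces the qualitative shape of the solar
  spectrum so the whole pipeline is testable offline, but it is not the
  standard table and band-energy fractions computed from it are
  approximations.
"""

from __future__ import annotations

import csv
import io
import logging
import urllib.request
from pathlib import Path
from typing import Optional

import numpy as np

from nirtherm.spectra import SOLAR_REFERENCE_BAND, Spectrum, SpectrumError

logger = logging.getLogger(__name__)

__all__ = [
    "ASTM_G173_URL",
    "DEFAULT_ASTM_PATH",
    "download_astm_g173",
    "load_astm_g173",
    "synthetic_am15_irradiance",
]

#: NREL's CSV rendering of the ASTM G-173-03 reference spectra
ASTM_G173_URL = (
    "https://www.nrel.gov/grid/solar-resource/assets/data/astmg173.csv"
)

#: conventional location for a user-supplied copy of the table
DEFAULT_ASTM_PATH = Path(__file__).resolve().parent / "data" / "astmg173.csv"

_COLUMN_INDEX = {"extraterrestrial": 1, "global_tilt": 2, "direct_circumsolar": 3}


def download_astm_g173(dest: str | Path = DEFAULT_ASTM_PATH, url: str = ASTM_G173_URL) -> Path:
    """Download the ASTM G-173 table to ``dest`` (requires network access)."""
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(url, timeout=60) as resp:  # noqa: S310 - fixed https URL
        dest.write_bytes(resp.read())
    logger.info("downloaded ASTM G-173 table to %s", dest)
    return dest


def load_astm_g173(
    path: str | Path = DEFAULT_ASTM_PATH, column: str = "global_tilt"
) -> Spectrum:
    """Load one irradiance column of a local ASTM G-173 table.

    The expected layout is the NREL CSV: wavelength (nm) followed by the
    extraterrestrial, global-tilt and direct+circumsolar irradiance
    columns (W m⁻² nm⁻¹); header lines are skipped.  Wavelengths outside
    250–2600 nm are dropped (the solar reference band used throughout is
    300–2600 nm).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"ASTM G-173 table not found at {path}. Download it once with "
            f"nirtherm.solar.download_astm_g173() or manually from {ASTM_G173_URL} "
            "and pass its path."
        )
    if column not in _COLUMN_INDEX:
        raise ValueError(f"column must be one of {sorted(_COLUMN_INDEX)}")
    idx = _COLUMN_INDEX[column]
    rows = []
    with path.open(newline="") as fh:
        for record in csv.reader(fh):
            if len(record) <= idx:
                continue
            try:
                w = float(record[0])
                v = float(record[idx])
            except ValueError:
                continue  # header / units line
            rows.append((w, v))
    if len(rows) < 100:
        raise SpectrumError(f"{path}: does not look like an ASTM G-173 table")
    arr = np.array(rows)
    mask = (arr[:, 0] >= 250.0) & (arr[:, 0] <= 2600.0)
    arr = arr[mask]
    return Spectrum(arr[:, 0], np.clip(arr[:, 1], 0.0, None), kind="irradiance",
                    label=f"ASTM G-173 {column}")


# ---------------------------------------------------------------------------
# Synthetic AM1.5-like spectrum
# ---------------------------------------------------------------------------

_H = 6.62607015e-34  # J s
_C = 2.99792458e8  # m/s
_KB = 1.380649e-23  # J/K
_T_SUN = 5778.0  # K
_AIR_MASS = 1.5

# (centre nm, sigma nm, optical depth at band centre for AM1.5)
# O₂ A-band at 760 nm and the main telluric water-vapour bands; depths are
# typical clear-sky values for ~1.4 cm precipitable water.
_ABSORPTION_BANDS = (
    (687.0, 5.0, 0.25),   # O2 B
    (723.0, 12.0, 0.35),  # H2O
    (760.0, 6.0, 1.0),    # O2 A
    (820.0, 12.0, 0.45),  # H2O
    (940.0, 25.0, 1.1),   # H2O
    (1130.0, 30.0, 1.5),  # H2O
    (1400.0, 45.0, 4.0),  # H2O (nearly opaque)
    (1870.0, 55.0, 4.0),  # H2O (nearly opaque)
    (2500.0, 80.0, 2.5),  # H2O/CO2
)


def _planck_spectral(lambda_nm: np.ndarray) -> np.ndarray:
    lam = lambda_nm * 1e-9
    x = _H * _C / (lam * _KB * _T_SUN)
    return (2 * _H * _C**2 / lam**5) / np.expm1(x)


def synthetic_am15_irradiance(
    grid_nm: Optional[np.ndarray] = None, total_w_m2: float = 1000.0
) -> Spectrum:
    """SYNTHETIC approximation of the AM1.5 global-tilt solar spectrum.

    A Planck envelope at the solar effective temperature is attenuated by
    a parametric clear-sky atmosphere at air mass 1.5 — Rayleigh
    scattering (τ = 0.008735 λ_µm⁻⁴·⁰⁸), a rural-aerosol Ångström law
    (β = 0.05, α = 1.3), an ozone UV cut-off near 305 nm and Gaussian O₂
    and H₂O absorption bands — then scaled so the 300–2600 nm integral is
    ``total_w_m2`` (1000 W m⁻², the conventional AM1.5G normalisation).

    This is a stand-in for offline testing; use the real ASTM G-173 table
    for standard-quality energy fractions.
    """
    if grid_nm is None:
        grid_nm = np.arange(300.0, 2600.0 + 0.5, 1.0)
    grid_nm = np.asarray(grid_nm, dtype=float)
    lam_um = grid_nm / 1000.0

    envelope = _planck_spectral(grid_nm)

    tau_rayleigh = 0.008735 * lam_um**-4.08
    tau_aerosol = 0.05 * lam_um**-1.3
    tau = (tau_rayleigh + tau_aerosol) * _AIR_MASS
    for centre, sigma, depth in _ABSORPTION_BANDS:
        tau = tau + depth * np.exp(-0.5 * ((grid_nm - centre) / sigma) ** 2)
    transmission = np.exp(-tau)
    # ozone Hartley/Huggins cut-off: transmission collapses below ~305 nm
    transmission = transmission / (1.0 + np.exp(-(grid_nm - 305.0) / 4.0))
    # diffuse (global) component softens the pure Beer-Lambert attenuation
    # at short wavelengths: half of the Rayleigh-scattered light returns
    diffuse = 0.5 * (1.0 - np.exp(-tau_rayleigh * _AIR_MASS))
    values = envelope * (transmission + diffuse / (1.0 + np.exp(-(grid_nm - 305.0) / 4.0)))

    scale = total_w_m2 / np.trapezoid(values, grid_nm)
    return Spectrum(grid_nm, values * scale, kind="irradiance",
                    label="synthetic AM1.5G approximation")
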