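"""Spectrum containers and spectral file handling.

A :class:`Spectrum` is a wavelength-indexed curve: either a reflectance
measured against a white standard (dimensionless fraction) or a spectral
irradiance (W m⁻² nm⁻¹).  All downstream operations (reflectivity
integrals, spectral extensions) consume this container.

Wavelengths are restricted to 250–2600 nm, the range over which the
terrestrial solar spectrum carries essentially all of its energy.
Reflectance is stored as a fraction; values slightly above 1 are allowed
(up to 2.0) because measurements against a 99% standard on glossy surfaces
can exceed the standard.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

WAVELENGTH_MIN_NM = 250.0
WAVELENGTH_MAX_NM = 2600.0
#: maximum admissible reflectance fraction (measurements against a 99%
#: standard may slightly exceed 1)
REFLECTANCE_MAX = 2.0

KINDS = ("reflectance", "irradiance")


class SpectrumError(ValueError):
    """Raised for invalid spectral data or unsatisfiable spectral operations."""


@dataclass(frozen=True)
class Band:
    """A closed wavelength interval [lo_nm, hi_nm] in nanometres."""

    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if not (WAVELENGTH_MIN_NM <= self.lo_nm < self.hi_nm <= WAVELENGTH_MAX_NM):
            raise SpectrumError(
                f"invalid band [{self.lo_nm}, {self.hi_nm}] nm: need "
                f"{WAVELENGTH_MIN_NM} <= lo < hi <= {WAVELENGTH_MAX_NM}"
            )

    @property
    def width_nm(self) -> float:
        return self.hi_nm - self.lo_nm

    def contains(self, other: "Band") -> bool:
        return self.lo_nm <= other.lo_nm and other.hi_nm <= self.hi_nm

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.lo_nm:g}-{self.hi_nm:g} nm"


# Bands used throughout: the full measured range, the visible/UV range and
# the near-infrared range.
FULL_BAND = Band(300.0, 1700.0)
UVVIS_BAND = Band(300.0, 700.0)
NIR_BAND = Band(700.0, 1700.0)
SOLAR_REFERENCE_BAND = Band(300.0, 2600.0)


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed curve (reflectance fraction or irradiance).

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nm, within [250, 2600].
    values
        Non-negative values; reflectance fractions must not exceed 2.0.
    kind
        ``"reflectance"`` or ``"irradiance"``.
    label
        Free-text identity (species / model / treatment).
    extension_method, extension_start_nm
        Set by the spectral-extension operations so that downstream
        reflectivity results can be tagged with how the curve beyond the
        measured range was produced.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"
    label: str = ""
    extension_method: Optional[str] = None
    extension_start_nm: Optional[float] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)
        if w.ndim != 1 or v.ndim != 1 or w.shape != v.shape:
            raise SpectrumError("wavelengths and values must be 1-D and equal length")
        if w.size < 2:
            raise SpectrumError("a spectrum needs at least 2 samples")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(v)):
            raise SpectrumError("non-finite wavelength or value")
        if np.any(np.diff(w) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if w[0] < WAVELENGTH_MIN_NM or w[-1] > WAVELENGTH_MAX_NM:
            raise SpectrumError(
                f"wavelengths outside [{WAVELENGTH_MIN_NM}, {WAVELENGTH_MAX_NM}] nm"
            )
        if np.any(v < 0):
            raise SpectrumError("values must be non-negative")
        if self.kind not in KINDS:
            raise SpectrumError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "reflectance" and np.any(v > REFLECTANCE_MAX):
            raise SpectrumError(f"reflectance above {REFLECTANCE_MAX} — wrong units?")

    # -- basic queries -------------------------------------------------
    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def support(self) -> Band:
        return Band(float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1]))

    def covers(self, band: Band) -> bool:
        return (
            self.wavelengths_nm[0] <= band.lo_nm and band.hi_nm <= self.wavelengths_nm[-1]
        )

    def interp(self, grid: np.ndarray) -> np.ndarray:
        """Piecewise-linear values at ``grid`` (must lie inside the support)."""
        grid = np.asarray(grid, dtype=float)
        if grid.size and (
            grid.min() < self.wavelengths_nm[0] or grid.max() > self.wavelengths_nm[-1]
        ):
            raise SpectrumError(
                f"grid [{grid.min():g}, {grid.max():g}] outside spectral support "
                f"[{self.wavelengths_nm[0]:g}, {self.wavelengths_nm[-1]:g}] nm; "
                "use extend_exponential/extend_linear to extrapolate"
            )
        return np.interp(grid, self.wavelengths_nm, self.values)

    def with_label(self, label: str) -> "Spectrum":
        return replace(self, label=label)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_DELIMITERS = (",", "\t", ";", None)  # None = any whitespace
_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _split_line(line: str, delim: Optional[str]) -> list[str]:
    if delim is None:
        return line.split()
    return [tok.strip() for tok in line.split(delim)]


def _detect_delimiter(lines: Sequence[str]) -> Optional[str]:
    """Pick the delimiter that yields two numeric columns most often."""
    best, best_hits = None, -1
    for delim in _DELIMITERS:
        hits = 0
        for line in lines:
            toks = _split_line(line, delim)
            if len(toks) >= 2 and _NUMBER_RE.match(toks[0]) and _NUMBER_RE.match(toks[1]):
                hits += 1
        if hits > best_hits:
            best, best_hits = delim, hits
    return best


def read_spectrum(
    path: str | Path,
    kind: str = "reflectance",
    label: Optional[str] = None,
    delimiter: Optional[str] = "auto",
) -> Spectrum:
    """Read a two-column delimited spectral file.

    The delimiter is auto-detected among comma, tab, semicolon and
    whitespace; a single non-numeric header line is tolerated.  Rows are
    sorted by wavelength, duplicate wavelengths are collapsed by their
    mean, and rows outside [250, 2600] nm are dropped (counted in the log).

    Raises
    ------
    SpectrumError
        If more than 10% of the rows are unparseable (the first offending
        line is named) or no usable rows remain.
    """
    path = Path(path)
    raw_lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not raw_lines:
        raise SpectrumError(f"{path}: empty file")

    if delimiter == "auto":
        delim = _detect_delimiter(raw_lines[:50])
    else:
        delim = delimiter

    rows: list[tuple[float, float]] = []
    bad: list[tuple[int, str]] = []
    for i, line in enumerate(raw_lines, start=1):
        toks = _split_line(line, delim)
        if len(toks) >= 2 and _NUMBER_RE.match(toks[0]) and _NUMBER_RE.match(toks[1]):
            rows.append((float(toks[0]), float(toks[1])))
        else:
            bad.append((i, line))

    # a single leading header line is expected and not counted as bad
    if bad and bad[0][0] == 1:
        bad = bad[1:]
    n_considered = len(rows) + len(bad)
    if n_considered == 0 or len(bad) > 0.1 * n_considered:
        first = bad[0] if bad else (0, "<none>")
        raise SpectrumError(
            f"{path}: {len(bad)} unparseable rows (>10%); first bad line "
            f"{first[0]}: {first[1]!r}"
        )

    arr = np.array(rows, dtype=float)
    inside = (arr[:, 0] >= WAVELENGTH_MIN_NM) & (arr[:, 0] <= WAVELENGTH_MAX_NM)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows outside [250, 2600] nm", path, n_dropped)
    arr = arr[inside]
    if arr.shape[0] < 2:
        raise SpectrumError(f"{path}: fewer than 2 usable rows inside [250, 2600] nm")

    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    # collapse duplicate wavelengths by mean
    w, inverse = np.unique(arr[:, 0], return_inverse=True)
    v = np.bincount(inverse, weights=arr[:, 1]) / np.bincount(inverse)
    return Spectrum(w, v, kind=kind, label=label if label is not None else path.stem)


def write_spectrum(path: str | Path, s: Spectrum, delimiter: str = ",") -> None:
    """Write a spectrum as two-column delimited text with a header line.

    Values are written with 17 significant digits so a read → write → read
    round trip reproduces the float64 data exactly.
    """
    path = Path(path)
    header = f"wavelength_nm{delimiter}{s.kind}"
    lines = [header]
    for w, v in zip(s.wavelengths_nm, s.values):
        lines.append(f"{w:.17g}{delimiter}{v:.17g}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Calibration / resampling / splicing
# ---------------------------------------------------------------------------


def calibrate(
    raw: Spectrum,
    white: Spectrum,
    dark: Optional[Spectrum] = None,
    standard_reflectance: float = 0.99,
) -> Spectrum:
    """Convert raw counts to reflectance against a white standard.

    reflectance = standard_reflectance × (raw − dark) / (white − dark),
    evaluated on raw's wavelength grid after resampling white (and dark)
    onto it.  Negative results — possible with dark noise — are clipped to
    zero rather than rejected.

    Raises
    ------
    SpectrumError
        If the white reference does not exceed dark at more than 1% of the
        shared grid points (saturated or invalid reference).
    """
    lo = max(raw.wavelengths_nm[0], white.wavelengths_nm[0])
    hi = min(raw.wavelengths_nm[-1], white.wavelengths_nm[-1])
    if dark is not None:
        lo = max(lo, dark.wavelengths_nm[0])
        hi = min(hi, dark.wavelengths_nm[-1])
    if lo >= hi:
        raise SpectrumError("raw and reference spectra share no wavelength overlap")

    mask = (raw.wavelengths_nm >= lo) & (raw.wavelengths_nm <= hi)
    grid = raw.wavelengths_nm[mask]
    if grid.size < 2:
        raise SpectrumError("fewer than 2 raw samples inside the reference overlap")
    raw_v = raw.values[mask]
    white_v = white.interp(grid)
    dark_v = dark.interp(grid) if dark is not None else np.zeros_like(grid)

    denom = white_v - dark_v
    invalid = denom <= 0
    if invalid.mean() > 0.01:
        raise SpectrumError(
            f"white − dark ≤ 0 at {invalid.sum()}/{grid.size} points: "
            "saturated or invalid reference"
        )
    keep = ~invalid
    refl = standard_reflectance * (raw_v[keep] - dark_v[keep]) / denom[keep]
    refl = np.clip(refl, 0.0, None)
    return Spectrum(grid[keep], refl, kind="reflectance", label=raw.label)


def resample(s: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Resample a spectrum onto a new grid by linear interpolation.

    No extrapolation: every grid point must lie inside the spectrum's
    support (otherwise a :class:`SpectrumError` pointing at the extension
    operations is raised).
    """
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid, dtype=float)
    if grid.size < 2:
        raise SpectrumError("resampling grid needs at least 2 points")
    if np.any(np.diff(grid) <= 0):
        raise SpectrumError("resampling grid must be strictly increasing")
    vals = s.interp(grid)
    return replace(s, wavelengths_nm=grid, values=vals)


def splice(vis: Spectrum, nir: Spectrum, boundary_nm: float = 1000.0, overlap_nm: float = 5.0) -> Spectrum:
    """Join spectra from two spectrometer ranges at a boundary wavelength.

    The visible-range spectrum is used strictly below
    ``boundary − overlap``, the NIR-range spectrum strictly above
    ``boundary + overlap``.  Inside the ±overlap window the two curves are
    resampled onto a 1 nm grid and averaged where both are defined (the
    single available curve is used where only one is defined).

    Raises
    ------
    SpectrumError
        If the two supports leave a gap of more than 10 nm, or the kinds
        differ.
    """
    if vis.kind != nir.kind:
        raise SpectrumError("cannot splice spectra of different kinds")
    if vis.wavelengths_nm[-1] < boundary_nm - overlap_nm and (
        nir.wavelengths_nm[0] - vis.wavelengths_nm[-1]
    ) > 10.0:
        raise SpectrumError(
            f"gap of {nir.wavelengths_nm[0] - vis.wavelengths_nm[-1]:g} nm between "
            "spectrometer ranges (limit 10 nm)"
        )
    if nir.wavelengths_nm[0] > boundary_nm + overlap_nm and (
        nir.wavelengths_nm[0] - vis.wavelengths_nm[-1]
    ) > 10.0:
        raise SpectrumError("NIR spectrum starts more than 10 nm past the boundary window")

    lo_w, hi_w = boundary_nm - overlap_nm, boundary_nm + overlap_nm
    left_mask = vis.wavelengths_nm < lo_w
    right_mask = nir.wavelengths_nm > hi_w

    window = np.arange(np.ceil(lo_w), np.floor(hi_w) + 0.5, 1.0)
    win_vals = []
    win_w = []
    for w in window:
        have_vis = vis.wavelengths_nm[0] <= w <= vis.wavelengths_nm[-1]
        have_nir = nir.wavelengths_nm[0] <= w <= nir.wavelengths_nm[-1]
        if have_vis and have_nir:
            win_vals.append(0.5 * (vis.interp([w])[0] + nir.interp([w])[0]))
        elif have_vis:
            win_vals.append(vis.interp([w])[0])
        elif have_nir:
            win_vals.append(nir.interp([w])[0])
        else:
            continue
        win_w.append(w)

    w_all = np.concatenate([vis.wavelengths_nm[left_mask], win_w, nir.wavelengths_nm[right_mask]])
    v_all = np.concatenate([vis.values[left_mask], win_vals, nir.values[right_mask]])
    order = np.argsort(w_all, kind="stable")
    w_all, v_all = w_all[order], v_all[order]
    uniq, inverse = np.unique(w_all, return_inverse=True)
    v_uniq = np.bincount(inverse, weights=v_all) / np.bincount(inverse)
    return Spectrum(uniq, v_uniq, kind=vis.kind, label=vis.label or nir.label)
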