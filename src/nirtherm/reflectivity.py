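"""Solar-weighted reflectivity and spectral extensions.

The central quantity is the reflectivity

    R = ∫ S(λ) I(λ) dλ / ∫ I(λ) dλ

over a wavelength band, where S is a reflectance spectrum (fraction) and I
a solar irradiance spectrum (W m⁻² nm⁻¹).  R is the fraction of incident
solar energy in the band that the surface reflects, the single number that
governs radiative heat gain.  Internally R is a fraction; reporting is in
percent.

Reflectance measurements that stop short of the NIR (e.g. published frog
spectra ending at 950 nm) can be extended to 1700 nm by either an
exponential decline anchored at 950 nm or a linear continuation of the
850–950 nm slope, with negative values clipped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Optional, Sequence

import numpy as np

from nirtherm.spectra import Band, SOLAR_REFERENCE_BAND, Spectrum, SpectrumError

__all__ = [
    "ReflectivityResult",
    "GroupComparison",
    "band_energy_fraction",
    "reflectivity",
    "extend_exponential",
    "extend_linear",
    "group_comparison",
    "round_half_even",
]


@dataclass(frozen=True)
class ReflectivityResult:
    """Reflectivity of one spectrum over one band under one irradiance."""

    label: str
    band: Band
    method: str  # measured | exponential_decline | linear_extension
    R_percent: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.R_percent <= 200.0):
            raise ValueError(f"reflectivity {self.R_percent}% outside [0, 200]")


@dataclass(frozen=True)
class GroupComparison:
    """Mean reflectivity of a high group and a low group and their difference."""

    group_hi: tuple
    group_lo: tuple
    mean_hi: float
    mean_lo: float
    mean_difference: float
    rounding: int

    @property
    def mean_hi_rounded(self) -> float:
        return round_half_even(self.mean_hi, self.rounding)

    @property
    def mean_lo_rounded(self) -> float:
        return round_half_even(self.mean_lo, self.rounding)

    @property
    def mean_difference_rounded(self) -> float:
        return round_half_even(self.mean_difference, self.rounding)


def round_half_even(x: float, dp: int) -> float:
    """Round half to even at ``dp`` decimals, robust to binary noise.

    Inputs that originate from decimal-printed tables carry float64
    representation noise around 1e-15; a guard rounding at ``dp + 8``
    decimals removes it before the final half-even rounding, so e.g. a
    mean difference of 20.250000000000004 reports as 20.2, not 20.3.
    """
    guard = Decimal(repr(float(x))).quantize(Decimal(1).scaleb(-(dp + 8)))
    return float(guard.quantize(Decimal(1).scaleb(-dp), rounding=ROUND_HALF_EVEN))


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def _integration_grid(band: Band, *spectra: Spectrum) -> np.ndarray:
    """Union of a 1 nm lattice, the band endpoints and all spectral knots.

    Including every knot makes the trapezoid rule exact for the
    piecewise-linear interpolants, which in turn makes band integrals
    exactly additive over partitions.
    """
    pieces = [np.arange(np.ceil(band.lo_nm), np.floor(band.hi_nm) + 0.5, 1.0),
              np.array([band.lo_nm, band.hi_nm])]
    for s in spectra:
        w = s.wavelengths_nm
        pieces.append(w[(w >= band.lo_nm) & (w <= band.hi_nm)])
    return np.unique(np.concatenate(pieces))


def _check_coverage(s: Spectrum, band: Band, role: str) -> None:
    if not s.covers(band):
        lo, hi = s.wavelengths_nm[0], s.wavelengths_nm[-1]
        missing = []
        if lo > band.lo_nm:
            missing.append(f"[{band.lo_nm:g}, {min(lo, band.hi_nm):g}] nm")
        if hi < band.hi_nm:
            missing.append(f"[{max(hi, band.lo_nm):g}, {band.hi_nm:g}] nm")
        raise SpectrumError(
            f"{role} spectrum {s.label!r} does not cover {missing and ' and '.join(missing)}"
        )


def band_energy_fraction(I: Spectrum, band: Band, reference: Band = SOLAR_REFERENCE_BAND) -> float:
    """Fraction of the irradiance's energy in ``band`` relative to ``reference``.

    Both integrals use the trapezoid rule on a grid containing the 1 nm
    lattice, all measured wavelengths and both bands' endpoints.
    """
    if I.kind != "irradiance":
        raise SpectrumError("band_energy_fraction expects an irradiance spectrum")
    if not reference.contains(band):
        raise SpectrumError(f"band {band} not contained in reference {reference}")
    _check_coverage(I, reference, "irradiance")
    grid_ref = _integration_grid(reference, I)
    total = np.trapezoid(I.interp(grid_ref), grid_ref)
    grid_band = _integration_grid(band, I)
    part = np.trapezoid(I.interp(grid_band), grid_band)
    return float(part / total)


def reflectivity(S: Spectrum, I: Spectrum, band: Band) -> ReflectivityResult:
    """Solar-weighted reflectivity R = ∫S·I dλ / ∫I dλ over ``band``, in %.

    Both spectra must cover the band (after any extension); the trapezoid
    rule is applied on the merged 1 nm grid of both spectra.
    """
    if S.kind != "reflectance":
        raise SpectrumError("reflectivity expects S to be a reflectance spectrum")
    if I.kind != "irradiance":
        raise SpectrumError("reflectivity expects I to be an irradiance spectrum")
    _check_coverage(S, band, "reflectance")
    _check_coverage(I, band, "irradiance")
    grid = _integration_grid(band, S, I)
    s_vals = S.interp(grid)
    i_vals = I.interp(grid)
    num = np.trapezoid(s_vals * i_vals, grid)
    den = np.trapezoid(i_vals, grid)
    if den <= 0:
        raise SpectrumError("irradiance integrates to zero over the band")
    method = "measured"
    if S.extension_method is not None and S.extension_start_nm is not None:
        if band.hi_nm > S.extension_start_nm:
            method = S.extension_method
    return ReflectivityResult(
        label=S.label, band=band, method=method, R_percent=100.0 * float(num / den)
    )


# ---------------------------------------------------------------------------
# Spectral extensions
# ---------------------------------------------------------------------------


def _ols_slope(w: np.ndarray, v: np.ndarray) -> float:
    """Least-squares slope of v against w."""
    if w.size < 2:
        raise SpectrumError("need at least 2 samples to fit a slope")
    wc = w - w.mean()
    denom = float(np.dot(wc, wc))
    if denom == 0.0:
        raise SpectrumError("degenerate wavelength window for slope fit")
    return float(np.dot(wc, v - v.mean()) / denom)


def extend_exponential(
    S: Spectrum, anchor_nm: float = 950.0, stop_nm: float = 1700.0, fit_window_nm: float = 100.0
) -> Spectrum:
    """Extend a reflectance spectrum by an exponential decline from the anchor.

    The extension is R(λ) = R(a)·exp(−k (λ − a)) on a 1 nm grid for
    λ ∈ (a, stop].  The decay rate k = −m / R(a), where m is the
    least-squares slope of the measured spectrum over the trailing
    ``fit_window_nm`` before the anchor, so the extension's initial
    derivative matches the data's trend.  A non-negative trailing slope
    (or zero reflectance at the anchor) gives k = 0, i.e. a constant
    extension.  Data beyond the anchor are replaced by the extension.
    """
    fit_band = Band(anchor_nm - fit_window_nm, anchor_nm)
    if not S.covers(fit_band):
        raise SpectrumError(
            f"spectrum {S.label!r} does not cover the anchor window {fit_band}"
        )
    r_anchor = float(S.interp([anchor_nm])[0])
    mask = (S.wavelengths_nm >= fit_band.lo_nm) & (S.wavelengths_nm <= fit_band.hi_nm)
    m = _ols_slope(S.wavelengths_nm[mask], S.values[mask])
    k = (-m / r_anchor) if (m < 0 and r_anchor > 0) else 0.0

    lam = np.arange(np.floor(anchor_nm) + 1.0, stop_nm + 0.5, 1.0)
    if lam.size == 0 or lam[-1] < stop_nm:
        lam = np.append(lam, stop_nm)
    ext = r_anchor * np.exp(-k * (lam - anchor_nm))

    keep = S.wavelengths_nm <= anchor_nm
    w_out = np.concatenate([S.wavelengths_nm[keep], [anchor_nm], lam])
    v_out = np.concatenate([S.values[keep], [r_anchor], ext])
    w_out, idx = np.unique(w_out, return_index=True)
    return replace(
        S,
        wavelengths_nm=w_out,
        values=v_out[idx],
        extension_method="exponential_decline",
        extension_start_nm=anchor_nm,
    )


def extend_linear(
    S: Spectrum,
    slope_window: Band = Band(850.0, 950.0),
    stop_nm: float = 1700.0,
    clip_at_zero: bool = True,
) -> Spectrum:
    """Extend a reflectance spectrum by continuing the 850–950 nm slope.

    The least-squares slope m over ``slope_window`` is continued from the
    window's upper edge: R(λ) = R(950) + m (λ − 950) on a 1 nm grid up to
    ``stop_nm``.  With ``clip_at_zero`` (default) negative extrapolated
    values are set to zero.  Data beyond the window's upper edge are
    replaced by the extension.
    """
    if not S.covers(slope_window):
        raise SpectrumError(
            f"spectrum {S.label!r} does not cover the slope window {slope_window}"
        )
    anchor = slope_window.hi_nm
    r_anchor = float(S.interp([anchor])[0])
    mask = (S.wavelengths_nm >= slope_window.lo_nm) & (S.wavelengths_nm <= slope_window.hi_nm)
    m = _ols_slope(S.wavelengths_nm[mask], S.values[mask])

    lam = np.arange(np.floor(anchor) + 1.0, stop_nm + 0.5, 1.0)
    if lam.size == 0 or lam[-1] < stop_nm:
        lam = np.append(lam, stop_nm)
    ext = r_anchor + m * (lam - anchor)
    if clip_at_zero:
        ext = np.clip(ext, 0.0, None)

    keep = S.wavelengths_nm <= anchor
    w_out = np.concatenate([S.wavelengths_nm[keep], [anchor], lam])
    v_out = np.concatenate([S.values[keep], [r_anchor], ext])
    w_out, idx = np.unique(w_out, return_index=True)
    return replace(
        S,
        wavelengths_nm=w_out,
        values=v_out[idx],
        extension_method="linear_extension",
        extension_start_nm=anchor,
    )


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def group_comparison(
    hi: Sequence[ReflectivityResult],
    lo: Sequence[ReflectivityResult],
    round_dp: int = 1,
) -> GroupComparison:
    """Average reflectivity per group and the high-minus-low difference.

    All results in one call must share the same band and extension method;
    means and the difference are computed exactly and reported rounded
    half-to-even at ``round_dp`` decimals (the precision used in reflectivity
    report tables).
    """
    if not hi or not lo:
        raise ValueError("both groups must be non-empty")
    results = list(hi) + list(lo)
    bands = {(r.band.lo_nm, r.band.hi_nm) for r in results}
    methods = {r.method for r in results}
    if len(bands) > 1:
        raise ValueError(f"mixed bands within one comparison: {sorted(bands)}")
    if len(methods) > 1:
        raise ValueError(f"mixed extension methods within one comparison: {sorted(methods)}")
    mean_hi = float(np.mean([r.R_percent for r in hi]))
    mean_lo = float(np.mean([r.R_percent for r in lo]))
    return GroupComparison(
        group_hi=tuple(hi),
        group_lo=tuple(lo),
        mean_hi=mean_hi,
        mean_lo=mean_lo,
        mean_difference=mean_hi - mean_lo,
        rounding=round_dp,
    )
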