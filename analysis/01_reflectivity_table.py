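"""Reflectivity table: published per-specimen values and synthetic coatings.

Reproduces the group-difference arithmetic of the reflectivity report
table from the printed per-specimen values, and computes solar-weighted
reflectivities of the synthetic HNIR/LNIR coating spectra under the
bundled synthetic irradiance.

Writes results/reflectivity_table.csv and results/band_fractions.csv.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from nirtherm import synth
from nirtherm.reflectivity import (
    ReflectivityResult,
    band_energy_fraction,
    group_comparison,
    reflectivity,
)
from nirtherm.solar import synthetic_am15_irradiance
from nirtherm.spectra import Band

OUT = Path(__file__).resolve().parent.parent / "results"
FULL = Band(300.0, 1700.0)
MEASURED = Band(300.0, 950.0)
NIR_TAIL = Band(950.0, 1700.0)

# published per-specimen reflectivities (percent)
PUBLISHED = {
    "measured_300_950": {
        "band": MEASURED, "method": "measured",
        "frogs_hi": (26.0, 33.3, 29.2), "frogs_lo": (10.7, 7.8),
        "models_hi": (24.7,), "models_lo": (9.5,),
    },
    "exponential_300_1700": {
        "band": FULL, "method": "exponential_decline",
        "frogs_hi": (26.1, 32.6, 28.4), "frogs_lo": (9.4, 6.8),
        "models_hi": (39.5,), "models_lo": (13.7,),
    },
    "linear_300_1700": {
        "band": FULL, "method": "linear_extension",
        "frogs_hi": (27.7, 39.7, 33.3), "frogs_lo": (13.2, 9.7),
        "models_hi": (39.5,), "models_lo": (13.7,),
    },
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for variant, spec in PUBLISHED.items():
        def res(r):
            return ReflectivityResult(label="", band=spec["band"],
                                      method=spec["method"], R_percent=r)

        for group in ("frogs", "models"):
            cmp_ = group_comparison([res(r) for r in spec[f"{group}_hi"]],
                                    [res(r) for r in spec[f"{group}_lo"]])
            rows.append({
                "variant": variant, "group": group,
                "mean_high": cmp_.mean_hi_rounded,
                "mean_low": cmp_.mean_lo_rounded,
                "difference_high_low": cmp_.mean_difference_rounded,
            })

    irr = synthetic_am15_irradiance()
    hi = synth.spectrum(synth.hnir_spectrum_params(seed=0), label="HNIR")
    lo = synth.spectrum(synth.lnir_spectrum_params(seed=1), label="LNIR")
    for s in (hi, lo):
        r = reflectivity(s, irr, FULL)
        rows.append({"variant": "synthetic_coating_300_1700", "group": s.label,
                     "mean_high": "", "mean_low": "",
                     "difference_high_low": round(r.R_percent, 1)})
    pd.DataFrame(rows).to_csv(OUT / "reflectivity_table.csv", index=False)

    fractions = pd.DataFrame([
        {"band": "300-1700", "fraction_pct": 100 * band_energy_fraction(irr, FULL)},
        {"band": "300-950", "fraction_pct": 100 * band_energy_fraction(irr, MEASURED)},
        {"band": "950-1700", "fraction_pct": 100 * band_energy_fraction(irr, NIR_TAIL)},
    ])
    fractions["source"] = "synthetic AM1.5G approximation (not the ASTM G-173 standard)"
    fractions.to_csv(OUT / "band_fractions.csv", index=False)
    print(pd.DataFrame(rows).to_string(index=False))
    print(fractions.to_string(index=False))


if __name__ == "__main__":
    main()
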