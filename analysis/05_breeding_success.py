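"""Breeding success vs environmental covariates by penalized-spline GAM.

Generates an 18-year breeding-success series with a hump-shaped response
to the box SSTA (an optimum at intermediate anomalies) and no real effect
of the other covariates, then fits one Gaussian GAM per covariate and
reports the comparison table (F-test, P-value, Adjusted R2).

Writes results/05_gam_table.csv.
"""

import sys
from pathlib import Path

import numpy as np

from divepop import breeding_gam, ocean, synth

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    ds, _ = synth.gen_sst_fields(synth.SSTTruth(), n_years=18, seed=SEED)
    anoms = ocean.anomalies(ds)
    ssta = ocean.box_ssta(anoms).to_numpy()
    pf = ocean.locate_pf(ds)
    saiod = ocean.eof_leading(anoms)

    rng = np.random.default_rng(SEED)
    success = np.clip(0.55 - 0.35 * (ssta - ssta.mean()) ** 2
                      + rng.normal(0, 0.06, ssta.size), 0.0, 1.0)

    tab = breeding_gam.gam_compare({
        "SSTA": (ssta, success),
        "Dist": (pf.distance_km, success),
        "SAIOD": (saiod.pc, success),
    })
    tab.to_csv(OUT / "05_gam_table.csv")
    print("GAM comparison (effect planted through the box SSTA; the front "
          "distance inherits it via the 130 km/degC coupling, the dipole "
          "index is decorrelated by construction)")
    print(tab.round(3).to_string())
    best = tab["Adjusted R2"].idxmax()
    print(f"\nbest-supported covariate: {best}")


if __name__ == "__main__":
    sys.exit(main())
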