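#!/usr/bin/env python
"""Scale fitted rate constants to intrinsic clearance.

Converts each non-NSD fish's k to in vitro intrinsic clearance
(mL h⁻¹ cell⁻¹) and extrapolates to intrinsic hepatic clearance
(mL h⁻¹ g liver⁻¹) with the spheroid-derived trout hepatocellularity
(91×10⁶ cells/g), in both scaling modes.  Also places the human literature
propranolol clearances (S9 and hepatocyte scale) on the same per-gram axis
for comparison.

Input: results/fits.csv    Output: results/clearance.csv
"""

from pathlib import Path

import pandas as pd

from spherokin import ScalingFactors, convert_literature_clearance
from spherokin.clearance import UNIT_HEPATOCYTES, UNIT_S9, scale_fit
from spherokin.io_cli import read_fits

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fits = read_fits(RESULTS / "fits.csv")
    factors = ScalingFactors()
    rows = []
    for mode in ("paper_literal", "volume_corrected"):
        for f in fits:
            if f.nsd:
                continue
            r = scale_fit(f.fish_id, f.compound, f.k_h, factors, mode)
            rows.append(
                {
                    "fish_id": r.fish_id,
                    "compound": r.compound,
                    "mode": r.mode,
                    "cl_int_in_vitro_mL_per_h_per_cell":
                        r.cl_int_in_vitro_mL_per_h_per_cell,
                    "cl_int_hepatic_mL_per_h_per_g":
                        r.cl_int_hepatic_mL_per_h_per_g,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "clearance.csv", index=False, lineterminator="\n")

    for mode, grp in df.groupby("mode"):
        mean_hep = grp["cl_int_hepatic_mL_per_h_per_g"].mean()
        print(f"{mode}: cohort mean Cl_int,hepatic = {mean_hep:.1f} mL/h/g "
              f"({len(grp)} fish)")
    s9 = convert_literature_clearance(17.5, UNIT_S9, factors, "human")
    hep = convert_literature_clearance(11.4167, UNIT_HEPATOCYTES, factors, "human")
    print(f"human S9 literature scale (17.5 uL/min/mg): {s9:.1f} mL/h/g")
    print(f"human hepatocyte literature scale (11.42 uL/min/1e6): {hep:.1f} mL/h/g")
    print(f"wrote {RESULTS / 'clearance.csv'}")


if __name__ == "__main__":
    main()
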