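#!/usr/bin/env python
"""Cohort aggregates and inter-individual variability.

Summarises the fitted cohort (mean ± SD of % depletion, k, t½ over non-NSD
fish), then tests inter-individual differences by one-way ANOVA on
ln(per-well % depletion) with Tukey HSD, printing the compact letter display
(fish sharing a letter are not significantly different).

Inputs: results/wells.csv, results/fits.csv
Outputs: results/summary.csv, results/tukey_letters.csv
"""

from pathlib import Path

import pandas as pd

from spherokin import (
    anova_ln_depletion,
    per_well_percent_depletion,
    read_wells,
    summarize_cohort,
)
from spherokin.cohort_stats import format_p
from spherokin.io_cli import read_fits

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    wells = read_wells(RESULTS / "wells.csv")
    fits = read_fits(RESULTS / "fits.csv")

    s = summarize_cohort(fits)
    pd.DataFrame([{
        "compound": s.compound,
        "n_fish": s.n_fish,
        "mean_percent_depletion": s.mean_percent,
        "sd_percent_depletion": s.sd_percent,
        "mean_k_per_h": s.mean_k_h,
        "sd_k_per_h": s.sd_k_h,
        "mean_t_half_h": s.mean_t_half_h,
        "sd_t_half_h": s.sd_t_half_h,
    }]).to_csv(RESULTS / "summary.csv", index=False, lineterminator="\n")
    print(f"{s.compound}, n = {s.n_fish} fish:")
    print(f"  % depletion  {s.mean_percent:.0f} +/- {s.sd_percent:.1f}")
    print(f"  k            {s.mean_k_h:.3f} +/- {s.sd_k_h:.3f} per h")
    print(f"  t1/2         {s.mean_t_half_h:.1f} +/- {s.sd_t_half_h:.1f} h")

    active = {f.fish_id for f in fits if not f.nsd}
    per_well = per_well_percent_depletion(
        [w for w in wells if w.fish_id in active]
    )
    g = anova_ln_depletion(per_well, alpha=0.05)
    print(f"\none-way ANOVA on ln(%): F = {g.F_statistic:.1f}, {format_p(g.anova_p)}")
    print(f"{'fish':<10}letters")
    letter_rows = []
    for fid in sorted(g.letters):
        print(f"{fid:<10}{g.letters_string(fid)}")
        letter_rows.append({"fish_id": fid, "letters": g.letters_string(fid)})
    pd.DataFrame(letter_rows).to_csv(
        RESULTS / "tukey_letters.csv", index=False, lineterminator="\n"
    )
    print(f"\nwrote {RESULTS / 'summary.csv'} and {RESULTS / 'tukey_letters.csv'}")


if __name__ == "__main__":
    main()
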