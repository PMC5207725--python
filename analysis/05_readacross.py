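#!/usr/bin/env python
"""Human→trout metabolic read-across scoring.

Scores the packaged seven-compound table: a compound is concordant when its
human extensive-metabolism status matches the observed trout-spheroid
depletion outcome.  Compounds whose major human CYP routes include an enzyme
absent from the trout genome (CYP2D6) are flagged as mechanistic candidates
for discordance.

Output: results/concordance.csv
"""

from pathlib import Path

from spherokin import concordance_table, default_profiles, default_trout_inventory

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table, counts = concordance_table(default_profiles(), default_trout_inventory())
    table.to_csv(RESULTS / "concordance.csv", index=False, lineterminator="\n")
    print(table[["compound", "human_metabolised", "trout_observed_metabolised",
                 "concordance", "major_cyp_absent_in_trout"]]
          .to_string(index=False))
    print(f"\n{counts['concordant']} of {len(table)} compounds concordant "
          f"({counts['discordant']} discordant)")
    print(f"wrote {RESULTS / 'concordance.csv'}")


if __name__ == "__main__":
    main()
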