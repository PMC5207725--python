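"""Human→trout metabolic read-across scoring.

Each compound carries human metabolism metadata — BDDCS class, percent of dose
metabolised in humans, the major responsible CYP enzymes — plus the observed
trout-spheroid depletion outcome.  A compound is concordant when its human
extensive-metabolism status (percent metabolised ≥ a 50% threshold by default)
matches the observed trout outcome.  A separate mechanistic flag marks
compounds whose major human CYPs are absent from the trout genome (e.g. CYP2D6
for metoprolol), which is a candidate explanation for discordance but is kept
distinct from the concordance score itself.

The seven-compound table shipped with the package covers two β-blockers that
deplete differently despite similar structures, two NSAIDs, an anticonvulsant
and a benzodiazepine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "CompoundProfile",
    "SpeciesCypInventory",
    "concordance",
    "concordance_table",
    "default_profiles",
    "default_trout_inventory",
    "load_profiles",
    "EXTENSIVE_METABOLISM_THRESHOLD",
]

EXTENSIVE_METABOLISM_THRESHOLD = 50.0  # % of dose metabolised in humans

CONCORDANT = "concordant"
DISCORDANT = "discordant"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class CompoundProfile:
    name: str
    bddcs_class: int
    percent_metabolised_human: float
    major_cyps: frozenset[str]
    human_metabolised: bool
    trout_observed_metabolised: bool | None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.bddcs_class not in (1, 2, 3):
            raise ValueError("BDDCS class must be 1, 2 or 3")
        expected = self.percent_metabolised_human >= EXTENSIVE_METABOLISM_THRESHOLD
        if self.human_metabolised != expected:
            raise ValueError(
                f"{self.name}: human_metabolised flag inconsistent with "
                f"{self.percent_metabolised_human}% metabolised"
            )
        if self.human_metabolised and not self.major_cyps:
            raise ValueError(f"{self.name}: metabolised compound needs major CYPs")


@dataclass(frozen=True)
class SpeciesCypInventory:
    species: str
    present_cyps: frozenset[str] = frozenset()
    absent_cyps: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.present_cyps & self.absent_cyps:
            raise ValueError("present and absent CYP sets must be disjoint")


def default_trout_inventory() -> SpeciesCypInventory:
    """Trout CYP inventory: genomic studies show no CYP2D6 ortholog."""
    return SpeciesCypInventory(species="trout", absent_cyps=frozenset({"2D6"}))


def concordance(profile: CompoundProfile) -> str:
    """'concordant' when the human status predicts the trout observation."""
    if profile.trout_observed_metabolised is None:
        return UNKNOWN
    return (
        CONCORDANT
        if profile.human_metabolised == profile.trout_observed_metabolised
        else DISCORDANT
    )


def concordance_table(
    profiles: list[CompoundProfile],
    inventory: SpeciesCypInventory | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-compound concordance plus counts.

    Returns a table (one row per compound) and a counts dict with keys
    'concordant', 'discordant', 'unknown'.  When ``inventory`` is given, each
    compound is annotated with whether any of its major human CYPs is absent
    in that species (mechanistic flag).
    """
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate compound names: {dupes}")
    rows = []
    counts = {CONCORDANT: 0, DISCORDANT: 0, UNKNOWN: 0}
    for p in profiles:
        verdict = concordance(p)
        counts[verdict] += 1
        row = {
            "compound": p.name,
            "bddcs_class": p.bddcs_class,
            "percent_metabolised_human": p.percent_metabolised_human,
            "major_cyps": ";".join(sorted(p.major_cyps)),
            "human_metabolised": p.human_metabolised,
            "trout_observed_metabolised": p.trout_observed_metabolised,
            "concordance": verdict,
        }
        if inventory is not None:
            row["major_cyp_absent_in_" + inventory.species] = bool(
                p.major_cyps & inventory.absent_cyps
            )
        rows.append(row)
    return pd.DataFrame(rows), counts


def _parse_bool(x) -> bool | None:
    if isinstance(x, bool):
        return x
    if pd.isna(x) or x == "":
        return None
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"unparseable boolean {x!r}")


def load_profiles(path) -> list[CompoundProfile]:
    """Read compound profiles from a CSV with the packaged schema."""
    df = pd.read_csv(path, dtype={"notes": str}, keep_default_na=False,
                     na_values=[""])
    profiles = []
    for row in df.itertuples(index=False):
        profiles.append(
            CompoundProfile(
                name=str(row.name),
                bddcs_class=int(row.bddcs_class),
                percent_metabolised_human=float(row.percent_metabolised_human),
                major_cyps=frozenset(
                    c.strip() for c in str(row.major_cyps).split(";") if c.strip()
                ),
                human_metabolised=bool(_parse_bool(row.human_metabolised)),
                trout_observed_metabolised=_parse_bool(
                    row.trout_observed_metabolised
                ),
                notes="" if pd.isna(row.notes) else str(row.notes),
            )
        )
    return profiles


def default_profiles() -> list[CompoundProfile]:
    """The seven packaged compound profiles."""
    ref = resources.files("spherokin.data").joinpath("compounds.csv")
    with resources.as_file(ref) as path:
        return load_profiles(path)
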