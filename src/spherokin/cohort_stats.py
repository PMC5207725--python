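"""Cohort aggregation and inter-individual statistics.

Per-fish depletion fits are aggregated into mean ± SD summaries (sample SD,
n−1 denominator, over non-NSD fish only; the mean half-life is the mean of
per-fish half-lives, not ln2 over the mean rate constant).  Inter-individual
differences are tested on the natural log of per-well percent depletion with
one-way ANOVA and Tukey's HSD, and fish are labelled with a compact letter
display: fish sharing a letter are not significantly different.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .kinetics import DepletionFit
from .synthetic_data import WellMeasurement

__all__ = [
    "CohortSummary",
    "TukeyGrouping",
    "summarize_cohort",
    "per_well_percent_depletion",
    "anova_ln_depletion",
    "compact_letter_display",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortSummary:
    compound: str
    n_fish: int
    mean_percent: float
    sd_percent: float
    mean_k_h: float
    sd_k_h: float
    mean_t_half_h: float
    sd_t_half_h: float
    all_nsd: bool = False


@dataclass(frozen=True)
class TukeyGrouping:
    """ANOVA + Tukey HSD results with per-fish compact letters.

    ``letters`` maps fish_id to its letter set; two fish share at least one
    letter if and only if their Tukey-adjusted pairwise difference is not
    significant at ``alpha``.  ``pairwise`` is a long-form table
    (fish_a, fish_b, mean_diff_ln, p_adj, significant).
    """

    letters: dict[str, frozenset[str]]
    pairwise: pd.DataFrame
    F_statistic: float
    anova_p: float
    alpha: float
    n_excluded_nonpositive: int = 0

    def letters_string(self, fish_id: str) -> str:
        return ",".join(sorted(self.letters[fish_id]))


def summarize_cohort(fits: list[DepletionFit]) -> CohortSummary:
    """Mean ± SD of percent depletion, k and t½ across non-NSD fish."""
    if not fits:
        raise ValueError("no fits to summarize")
    compounds = {f.compound for f in fits}
    if len(compounds) != 1:
        raise ValueError(f"fits span multiple compounds: {sorted(compounds)}")
    compound = compounds.pop()
    active = [f for f in fits if not f.nsd]
    if not active:
        nan = float("nan")
        return CohortSummary(compound, 0, nan, nan, nan, nan, nan, nan, all_nsd=True)
    if len(active) < 2:
        raise ValueError("need >= 2 non-NSD fits for a cohort summary")
    pct = np.array([f.percent_depletion for f in active])
    k = np.array([f.k_h for f in active])
    th = np.array([f.t_half_h for f in active])
    return CohortSummary(
        compound=compound,
        n_fish=len(active),
        mean_percent=float(pct.mean()),
        sd_percent=float(pct.std(ddof=1)),
        mean_k_h=float(k.mean()),
        sd_k_h=float(k.std(ddof=1)),
        mean_t_half_h=float(th.mean()),
        sd_t_half_h=float(th.std(ddof=1)),
    )


def per_well_percent_depletion(
    wells: list[WellMeasurement], end_h: float | None = None
) -> pd.DataFrame:
    """Per-well percent depletion at the incubation end, one row per well.

    Each endpoint exposure well is expressed against the fish's time-zero
    exposure-well mean: 100·(1 − C_well(end)/C̄(0)).  This is the per-well
    observational unit for the ANOVA.
    """
    rows = []
    df = pd.DataFrame(
        [
            {
                "fish_id": w.fish_id,
                "compound": w.compound,
                "time_h": w.time_h,
                "concentration": w.concentration_ug_per_L,
            }
            for w in wells
            if w.well_role == "exposure"
        ]
    )
    if df.empty:
        raise ValueError("no exposure wells")
    end = float(df["time_h"].max()) if end_h is None else float(end_h)
    for (fid, cmpd), grp in df.groupby(["fish_id", "compound"], sort=True):
        c0 = grp.loc[grp["time_h"] == 0.0, "concentration"]
        cend = grp.loc[grp["time_h"] == end, "concentration"]
        if c0.empty or cend.empty:
            raise ValueError(f"missing t=0 or t={end} exposure wells for {fid}")
        c0_mean = float(c0.mean())
        for conc in cend:
            rows.append(
                {
                    "fish_id": fid,
                    "compound": cmpd,
                    "percent_depletion": 100.0 * (1.0 - conc / c0_mean),
                }
            )
    return pd.DataFrame(rows)


def compact_letter_display(
    groups: list[str],
    means: dict[str, float],
    significant: dict[tuple[str, str], bool],
) -> dict[str, frozenset[str]]:
    """Insertion–absorption compact letter display.

    ``significant[(a, b)]`` is True when groups a and b differ.  Letters are
    assigned in decreasing order of group mean starting at "A"; ties in means
    are broken by the order of ``groups``.  Deterministic given its inputs.
    """
    order = sorted(range(len(groups)), key=lambda i: (-means[groups[i]], i))
    ranked = [groups[i] for i in order]
    # start with one column containing every group, then split on each
    # significant pair and absorb redundant (subset) columns
    columns: list[set[str]] = [set(ranked)]
    for a, b in itertools.combinations(ranked, 2):
        if not significant.get((a, b), significant.get((b, a), False)):
            continue
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorption: drop columns contained in another column
        columns = [
            col
            for col in new_columns
            if col and not any(col < other for other in new_columns)
        ]
        # dedupe while preserving order
        seen: list[set[str]] = []
        for col in columns:
            if col not in seen:
                seen.append(col)
        columns = seen
    rank = {g: i for i, g in enumerate(ranked)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    if len(columns) > 26:
        raise ValueError("more than 26 letter groups; widen the labelling scheme")
    letters: dict[str, set[str]] = {g: set() for g in groups}
    for i, col in enumerate(columns):
        letter = chr(ord("A") + i)
        for g in col:
            letters[g].add(letter)
    return {g: frozenset(s) for g, s in letters.items()}


def anova_ln_depletion(
    per_well: pd.DataFrame, alpha: float = 0.05
) -> TukeyGrouping:
    """One-way ANOVA + Tukey HSD on ln(per-well % depletion) across fish.

    Non-positive percent values cannot be log-transformed; they are excluded
    with a warning and their count recorded.  The compact letter display is
    validated on every run: shared-letter status must equal Tukey
    non-significance for every pair.
    """
    df = per_well[["fish_id", "percent_depletion"]].copy()
    n_bad = int((df["percent_depletion"] <= 0).sum())
    if n_bad:
        warnings.warn(
            f"excluding {n_bad} non-positive percent-depletion wells from the "
            "ln-transform", UserWarning, stacklevel=2,
        )
        df = df[df["percent_depletion"] > 0]
    fish = sorted(df["fish_id"].unique())
    if len(fish) < 2:
        raise ValueError("need >= 2 fish for ANOVA")
    counts = df.groupby("fish_id").size()
    if (counts < 2).any():
        raise ValueError("need >= 2 wells per fish for ANOVA")
    df["ln_pct"] = np.log(df["percent_depletion"])

    samples = [df.loc[df["fish_id"] == f, "ln_pct"].to_numpy() for f in fish]
    F, p = stats.f_oneway(*samples)

    # Tukey HSD (Tukey-Kramer on unbalanced data) via statsmodels
    res = pairwise_tukeyhsd(df["ln_pct"].to_numpy(), df["fish_id"].to_numpy(), alpha)
    pw = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    pairwise = pd.DataFrame(
        {
            "fish_a": pw["group1"].astype(str),
            "fish_b": pw["group2"].astype(str),
            "mean_diff_ln": pw["meandiff"].astype(float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
            "significant": np.asarray(res.reject, dtype=bool),
        }
    )
    significant = {
        (r.fish_a, r.fish_b): bool(r.significant) for r in pairwise.itertuples()
    }
    means = df.groupby("fish_id")["ln_pct"].mean().to_dict()
    letters = compact_letter_display(fish, means, significant)

    for a, b in itertools.combinations(fish, 2):
        sig = significant.get((a, b), significant.get((b, a)))
        shared = bool(letters[a] & letters[b])
        if shared == sig:
            raise AssertionError(
                f"letter display inconsistent for pair ({a}, {b})"
            )

    return TukeyGrouping(
        letters=letters,
        pairwise=pairwise,
        F_statistic=float(F),
        anova_p=float(p),
        alpha=alpha,
        n_excluded_nonpositive=n_bad,
    )


def format_p(p: float) -> str:
    """Report-style p formatting: three decimals, 'p<0.001' below that."""
    return "p<0.001" if p < 0.001 else f"p={p:.3f}"
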