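"""Cohort aggregation, ANOVA/Tukey letters, and the letter-display oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from spherokin import (
    anova_ln_depletion,
    per_well_percent_depletion,
    summarize_cohort,
)
from spherokin.cohort_stats import compact_letter_display, format_p
from tests.conftest import (
    COHORT_MEAN_K,
    COHORT_MEAN_THALF,
    COHORT_SD_K,
    COHORT_SD_THALF,
    PER_FISH_PROPRANOLOL,
    make_wells,
    table_fits,
)


class TestSummaries:
    def test_published_per_fish_values_reproduce_cohort_row(self):
        s = summarize_cohort(table_fits())
        assert s.n_fish == 12
        # one unit in the last printed digit of tolerance for input rounding
        assert abs(s.mean_k_h - COHORT_MEAN_K) <= 0.001
        assert abs(s.sd_k_h - COHORT_SD_K) <= 0.001
        assert abs(s.mean_t_half_h - COHORT_MEAN_THALF) <= 0.1
        assert abs(s.sd_t_half_h - COHORT_SD_THALF) <= 0.1

    def test_sd_matches_two_pass_computation(self):
        s = summarize_cohort(table_fits())
        ks = [k for _, _, _, k, _ in PER_FISH_PROPRANOLOL]
        mean = sum(ks) / len(ks)
        var = sum((k - mean) ** 2 for k in ks) / (len(ks) - 1)
        assert s.sd_k_h == pytest.approx(var**0.5, rel=1e-12)

    def test_identical_fits_have_zero_sd(self):
        import dataclasses

        base = table_fits()[0]
        twin = dataclasses.replace(base, fish_id="fish_900")
        s = summarize_cohort([base, twin])
        assert s.mean_k_h == pytest.approx(base.k_h)
        assert s.sd_k_h == 0.0

    def test_mean_half_life_is_mean_of_per_fish_values(self):
        s = summarize_cohort(table_fits())
        ths = [th for *_, th in PER_FISH_PROPRANOLOL]
        assert s.mean_t_half_h == pytest.approx(np.mean(ths), rel=1e-12)
        # and explicitly not ln2 / mean k
        assert s.mean_t_half_h != pytest.approx(np.log(2) / s.mean_k_h, rel=0.05)

    def test_all_nsd_cohort_has_no_kinetic_aggregates(self):
        import dataclasses

        fits = [dataclasses.replace(f, nsd=True) for f in table_fits()]
        s = summarize_cohort(fits)
        assert s.all_nsd and s.n_fish == 0
        assert np.isnan(s.mean_k_h)

    def test_nsd_fish_excluded_from_aggregates(self):
        import dataclasses

        fits = table_fits()
        fits[0] = dataclasses.replace(fits[0], nsd=True)
        s = summarize_cohort(fits)
        assert s.n_fish == 11
        assert s.mean_k_h == pytest.approx(
            np.mean([f.k_h for f in fits[1:]]), rel=1e-12
        )


class TestPerWellDepletion:
    def test_per_well_values_against_time_zero_mean(self):
        wells = make_wells(k=0.022, c0=98.0)
        df = per_well_percent_depletion(wells)
        assert len(df) == 6
        expected = 100.0 * (1.0 - np.exp(-0.022 * 24.0))
        assert df["percent_depletion"].to_numpy() == pytest.approx(
            np.full(6, expected), rel=1e-12
        )


def _brute_force_letters(groups, significant):
    """Oracle: letters = maximal cliques of the non-significance graph."""
    def compatible(subset):
        return all(
            not significant.get((a, b), significant.get((b, a), False))
            for a, b in itertools.combinations(subset, 2)
        )

    cliques = []
    for r in range(1, len(groups) + 1):
        for subset in itertools.combinations(groups, r):
            if compatible(subset):
                cliques.append(frozenset(subset))
    return {c for c in cliques if not any(c < d for d in cliques)}


class TestCompactLetterDisplay:
    def test_matches_exhaustive_oracle_on_all_four_group_patterns(self):
        groups = ["g1", "g2", "g3", "g4"]
        means = {"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0}
        pairs = list(itertools.combinations(groups, 2))
        for bits in range(2 ** len(pairs)):
            significant = {
                pair: bool(bits >> i & 1) for i, pair in enumerate(pairs)
            }
            letters = compact_letter_display(groups, means, significant)
            # rebuild letter columns and compare with the clique oracle
            all_letters = sorted({l for ls in letters.values() for l in ls})
            columns = {
                frozenset(g for g in groups if letter in letters[g])
                for letter in all_letters
            }
            assert columns == _brute_force_letters(groups, significant)
            for a, b in pairs:
                shared = bool(letters[a] & letters[b])
                assert shared != significant[(a, b)]

    def test_letters_ordered_by_decreasing_mean(self):
        groups = ["lo", "hi", "mid"]
        means = {"lo": 1.0, "mid": 2.0, "hi": 3.0}
        significant = {p: True for p in itertools.combinations(groups, 2)}
        letters = compact_letter_display(groups, means, significant)
        assert letters["hi"] == frozenset({"A"})
        assert letters["mid"] == frozenset({"B"})
        assert letters["lo"] == frozenset({"C"})

    def test_no_significant_pairs_share_single_letter(self):
        groups = ["a", "b", "c"]
        means = {g: 1.0 for g in groups}
        letters = compact_letter_display(groups, means, {})
        assert all(ls == frozenset({"A"}) for ls in letters.values())


def _simulated_cohort_frame(rng):
    rows = []
    for i, pct, sd, _k, _th in PER_FISH_PROPRANOLOL:
        vals = np.clip(rng.normal(pct, sd, 6), 0.5, None)
        rows += [
            {"fish_id": f"fish_{i:02d}", "percent_depletion": float(v)} for v in vals
        ]
    return pd.DataFrame(rows)


class TestAnova:
    def test_widely_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        rows = []
        for fid, mean in [("f1", 10.0), ("f2", 40.0), ("f3", 90.0)]:
            for v in rng.normal(mean, 0.5, 6):
                rows.append({"fish_id": fid, "percent_depletion": float(v)})
        g = anova_ln_depletion(pd.DataFrame(rows))
        assert g.anova_p < 0.001
        assert g.letters["f1"] == frozenset({"C"})
        assert g.letters["f2"] == frozenset({"B"})
        assert g.letters["f3"] == frozenset({"A"})
        assert format_p(g.anova_p) == "p<0.001"

    def test_indistinguishable_groups_share_one_letter(self):
        rng = np.random.default_rng(1)
        rows = [
            {"fish_id": fid, "percent_depletion": float(v)}
            for fid in ("f1", "f2", "f3")
            for v in rng.normal(40.0, 5.0, 6)
        ]
        g = anova_ln_depletion(pd.DataFrame(rows))
        assert g.letters["f1"] & g.letters["f2"] & g.letters["f3"]

    def test_f_statistic_invariant_under_constant_shift_of_ln_values(self):
        rng = np.random.default_rng(2)
        rows = [
            {"fish_id": fid, "percent_depletion": float(v)}
            for fid, m in [("f1", 20.0), ("f2", 50.0)]
            for v in rng.normal(m, 5.0, 6)
        ]
        df = pd.DataFrame(rows)
        g1 = anova_ln_depletion(df)
        shifted = df.copy()
        shifted["percent_depletion"] *= 3.0  # constant shift on the ln scale
        g2 = anova_ln_depletion(shifted)
        assert g2.F_statistic == pytest.approx(g1.F_statistic, rel=1e-9)

    def test_non_positive_wells_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        rows = [
            {"fish_id": fid, "percent_depletion": float(v)}
            for fid, m in [("f1", 20.0), ("f2", 50.0)]
            for v in rng.normal(m, 5.0, 6)
        ]
        rows.append({"fish_id": "f1", "percent_depletion": -2.0})
        with pytest.warns(UserWarning, match="non-positive"):
            g = anova_ln_depletion(pd.DataFrame(rows))
        assert g.n_excluded_nonpositive == 1

    def test_slowest_fish_separates_from_cohort(self):
        """Cohorts resampled at the published per-fish means ± sd: the slowest
        fish is always distinct from the fast half and is fully isolated in a
        majority of replicates (its nearest neighbour sits at the Tukey
        significance boundary, so full isolation is not guaranteed)."""
        rng = np.random.default_rng(11)
        reps = 200
        isolated = 0
        fast_half = {f"fish_{i:02d}" for i in (4, 6, 8, 10, 11)}
        for _ in range(reps):
            g = anova_ln_depletion(_simulated_cohort_frame(rng))
            others = [f for f in g.letters if f != "fish_12"]
            assert not any(
                g.letters["fish_12"] & g.letters[f] for f in fast_half
            )
            if not any(g.letters["fish_12"] & g.letters[f] for f in others):
                isolated += 1
        assert isolated / reps > 0.5
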