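"""Shared fixtures: published per-fish propranolol kinetics and well builders.

The twelve-fish propranolol reference values (per-fish depletion rate
constant, half-life, and percent depletion mean ± sd over six wells) are the
published per-fish results for the trout liver spheroid assay; tests use them
as frozen inputs for aggregate checks.
"""

from __future__ import annotations

import math

import pytest

from spherokin import SimulationConfig, WellMeasurement
from spherokin.kinetics import DepletionFit

# Published per-fish propranolol results: (fish, pct_mean, pct_sd, k, t_half)
PER_FISH_PROPRANOLOL = [
    (1, 24, 5, 0.010, 70.0),
    (2, 36, 9, 0.017, 40.3),
    (3, 39, 10, 0.020, 34.1),
    (4, 68, 11, 0.045, 15.5),
    (5, 39, 5, 0.019, 36.5),
    (6, 51, 12, 0.027, 25.7),
    (7, 34, 4, 0.018, 39.6),
    (8, 56, 5, 0.032, 21.6),
    (9, 34, 4, 0.017, 41.0),
    (10, 52, 6, 0.029, 23.7),
    (11, 50, 7, 0.029, 24.0),
    (12, 15, 5, 0.007, 100.4),
]

COHORT_MEAN_K = 0.022
COHORT_SD_K = 0.010
COHORT_MEAN_THALF = 39.4
COHORT_SD_THALF = 23.8


def make_wells(
    k: float,
    c0: float = 100.0,
    times: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 24.0),
    n_exposure: int = 6,
    n_medium: int = 3,
    fish_id: str = "fish_001",
    compound: str = "propranolol",
    abiotic_k: float = 0.0,
) -> list[WellMeasurement]:
    """Noise-free plate: exposure wells at c0·e^(-k t), medium at abiotic rate."""
    wells = []
    for t in times:
        for rep in range(n_exposure):
            wells.append(
                WellMeasurement(
                    fish_id, compound, "exposure", t, c0 * math.exp(-k * t), rep
                )
            )
        for rep in range(n_medium):
            wells.append(
                WellMeasurement(
                    fish_id, compound, "medium_control", t,
                    c0 * math.exp(-abiotic_k * t), rep,
                )
            )
    return wells


def table_fits() -> list[DepletionFit]:
    """The published per-fish values wrapped as fit records."""
    return [
        DepletionFit(
            fish_id=f"fish_{i:03d}",
            compound="propranolol",
            a_ug_per_L=98.0,
            k_h=k,
            k_se_h=float("nan"),
            t_half_h=th,
            percent_depletion=float(pct),
            nsd=False,
            incubation_end_h=24.0,
            rss=float("nan"),
            n_points=36,
        )
        for i, pct, _sd, k, th in PER_FISH_PROPRANOLOL
    ]


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 5-fish simulated cohort reused across read-only tests."""
    from spherokin import simulate_cohort

    cfg = SimulationConfig(n_fish=5, seed=42)
    wells, truths = simulate_cohort(cfg)
    return cfg, wells, truths
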