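"""Seeded generator for plate-format substrate-depletion experiments.

The generator emulates the assay design used for trout liver spheroid
exposures: 96-well plates with one row per time point (0, 0.5, 1, 2, 4, 24 h),
six exposure wells (spheroids + medium + drug), three solvent-control wells
(spheroids + medium + solvent, no drug) and three medium-control wells (drug,
no spheroids) per time point, 100 spheroids of ~500 cells in 75 µL per well.

Per-fish depletion rate constants are drawn from a lognormal moment-matched to
the cohort mean and SD (positivity is guaranteed by construction), the true
time-zero concentration from a normal around the measured dose, and
measurement error is multiplicative lognormal with a configurable CV, mimicking
signal-proportional LC-MS/MS error.  Exposure wells follow C0·e^(-k·t), medium
controls follow the abiotic loss rate (zero by default: plates are sealed), and
solvent controls carry concentration zero so that real plate exports with that
layout parse through the same reader.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "SimulationConfig",
    "WellMeasurement",
    "TrueParameters",
    "simulate_fish",
    "simulate_cohort",
]

WELL_ROLES = ("exposure", "solvent_control", "medium_control")


class ConfigError(ValueError):
    """Raised for an impossible simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Design and statistical parameters of one simulated experiment.

    Defaults reproduce the study conditions of the propranolol assay:
    time points {0, 0.5, 1, 2, 4, 24} h, 6 exposure + 3 solvent-control +
    3 medium-control wells per time point, measured time-zero dose
    98 ± 4 µg/L at a nominal 100 µg/L, per-fish rate constants with mean
    0.022 h⁻¹ and SD 0.010 h⁻¹, and 10% multiplicative measurement CV.
    """

    n_fish: int = 12
    compound: str = "propranolol"
    time_points_h: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 24.0)
    n_exposure_wells: int = 6
    n_solvent_wells: int = 3
    n_medium_wells: int = 3
    nominal_dose_ug_per_L: float = 100.0
    dose_mean_ug_per_L: float = 98.0
    dose_sd_ug_per_L: float = 4.0
    k_mean_h: float = 0.022
    k_sd_h: float = 0.010
    measurement_cv: float = 0.10
    abiotic_loss_rate_h: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 1:
            raise ConfigError("n_fish must be >= 1")
        for name in ("n_exposure_wells", "n_solvent_wells", "n_medium_wells"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        tp = tuple(float(t) for t in self.time_points_h)
        object.__setattr__(self, "time_points_h", tp)
        if len(tp) < 2 or any(t < 0 for t in tp):
            raise ConfigError("time points must be non-negative, at least two")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigError("time points must be strictly increasing")
        if tp[0] != 0.0:
            raise ConfigError("time points must include 0")
        if self.k_mean_h < 0 or self.k_sd_h < 0:
            raise ConfigError("k_mean_h and k_sd_h must be >= 0")
        if not (0 <= self.measurement_cv < 1):
            raise ConfigError("measurement_cv must be in [0, 1)")
        if self.dose_mean_ug_per_L <= 0 or self.dose_sd_ug_per_L < 0:
            raise ConfigError("dose mean must be > 0 and SD >= 0")
        if self.abiotic_loss_rate_h < 0:
            raise ConfigError("abiotic_loss_rate_h must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["time_points_h"] = list(self.time_points_h)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "time_points_h" in d:
            d["time_points_h"] = tuple(d["time_points_h"])
        return cls(**d)


@dataclass(frozen=True)
class WellMeasurement:
    """One measured parent-compound concentration in one well at one time."""

    fish_id: str
    compound: str
    well_role: str
    time_h: float
    concentration_ug_per_L: float
    replicate_index: int

    def __post_init__(self) -> None:
        if self.well_role not in WELL_ROLES:
            raise ValueError(f"unknown well_role {self.well_role!r}")
        if self.concentration_ug_per_L < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class TrueParameters:
    """Ground-truth per-fish parameters, kept for parameter-recovery tests."""

    fish_id: str
    true_k_h: float
    true_C0_ug_per_L: float


def _fish_rng(seed: int, fish_id: str) -> np.random.Generator:
    # Stable substream per (seed, fish_id): fish i is reproducible regardless
    # of how many fish the cohort contains or the order they are generated in.
    digest = hashlib.sha256(fish_id.encode("utf-8")).digest()
    sub = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), sub]))


def _lognormal_moment_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_positive(rng: np.random.Generator, draw, max_tries: int = 1000) -> float:
    # Redraw deterministically from the seeded stream on non-finite or
    # non-positive values; the dose distribution puts these ~24 SD out, so
    # in practice the first draw is accepted.
    for _ in range(max_tries):
        x = float(draw(rng))
        if math.isfinite(x) and x > 0:
            return x
    raise ConfigError("could not draw a finite positive value")


def _draw_true_k(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    if cfg.k_mean_h == 0.0:
        return 0.0
    if cfg.k_sd_h == 0.0:
        return cfg.k_mean_h
    mu, sigma = _lognormal_moment_params(cfg.k_mean_h, cfg.k_sd_h)
    return _draw_positive(rng, lambda r: r.lognormal(mu, sigma))


def _noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = math.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=size)


def simulate_fish(
    config: SimulationConfig, fish_id: str
) -> tuple[list[WellMeasurement], TrueParameters]:
    """Simulate one fish's full plate: all wells at all time points.

    Exposure wells decay as C0·e^(-k·t) with per-fish k; medium controls decay
    at the abiotic loss rate only (no cell-mediated depletion); solvent
    controls contain no compound and are emitted with concentration 0.
    Returns the well list together with the ground-truth parameters.
    """
    rng = _fish_rng(config.seed, fish_id)
    true_k = _draw_true_k(rng, config)
    if config.dose_sd_ug_per_L == 0.0:
        true_c0 = config.dose_mean_ug_per_L
    else:
        true_c0 = _draw_positive(
            rng,
            lambda r: r.normal(config.dose_mean_ug_per_L, config.dose_sd_ug_per_L),
        )

    wells: list[WellMeasurement] = []
    for t in config.time_points_h:
        exposure_true = true_c0 * math.exp(-true_k * t)
        medium_true = true_c0 * math.exp(-config.abiotic_loss_rate_h * t)
        eps_exp = _noise(rng, config.measurement_cv, config.n_exposure_wells)
        eps_med = _noise(rng, config.measurement_cv, config.n_medium_wells)
        for rep in range(config.n_exposure_wells):
            wells.append(
                WellMeasurement(
                    fish_id, config.compound, "exposure", t,
                    exposure_true * float(eps_exp[rep]), rep,
                )
            )
        for rep in range(config.n_solvent_wells):
            wells.append(
                WellMeasurement(
                    fish_id, config.compound, "solvent_control", t, 0.0, rep
                )
            )
        for rep in range(config.n_medium_wells):
            wells.append(
                WellMeasurement(
                    fish_id, config.compound, "medium_control", t,
                    medium_true * float(eps_med[rep]), rep,
                )
            )
    return wells, TrueParameters(fish_id, true_k, true_c0)


def fish_ids(n_fish: int) -> list[str]:
    """Canonical cohort fish identifiers: fish_001, fish_002, ..."""
    return [f"fish_{i:03d}" for i in range(1, n_fish + 1)]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[WellMeasurement], list[TrueParameters]]:
    """Simulate ``config.n_fish`` independent fish.

    Each fish uses its own RNG substream keyed on (seed, fish_id), so the data
    for fish i is identical whether the cohort has 1 or 1000 fish.
    """
    all_wells: list[WellMeasurement] = []
    truths: list[TrueParameters] = []
    for fid in fish_ids(config.n_fish):
        wells, truth = simulate_fish(config, fid)
        all_wells.extend(wells)
        truths.append(truth)
    return all_wells, truths
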