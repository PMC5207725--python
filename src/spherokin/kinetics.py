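"""First-order substrate-depletion fitting and NSD classification.

Exposure-well time courses are fitted by nonlinear least squares with the
two-parameter exponential decay C(t) = a·e^(-k·t); the depletion rate constant
k (h⁻¹) gives the half-life t½ = ln2/k, and percent depletion over the
incubation is computed from the endpoint and time-zero well means.  Compounds
whose fitted k is not distinguishable from zero, or whose exposure-well loss
does not exceed the abiotic loss seen in cell-free medium controls, are
classified NSD ("no substrate depletion").

The regression is performed on individual wells, not per-time-point means, to
preserve replicate information; k is constrained non-negative (negative
depletion has no biological meaning here — apparent negative slopes surface as
NSD instead).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .synthetic_data import WellMeasurement

__all__ = [
    "DepletionFit",
    "FitError",
    "fit_depletion",
    "half_life",
    "percent_depletion",
    "classify_nsd",
    "k_significance_p",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics in args."""


@dataclass(frozen=True)
class DepletionFit:
    """Fitted decay parameters and diagnostics for one fish × compound.

    ``t_half_h`` is NaN when the fit is classified NSD (no finite half-life
    for a compound that is not depleted); otherwise t_half_h·k_h = ln 2
    exactly.  ``percent_depletion`` may be negative on noisy null data and is
    then reported as computed.
    """

    fish_id: str
    compound: str
    a_ug_per_L: float
    k_h: float
    k_se_h: float
    t_half_h: float
    percent_depletion: float
    nsd: bool
    incubation_end_h: float
    rss: float
    n_points: int


def _select(
    wells: list[WellMeasurement], fish_id: str, compound: str, role: str
) -> list[WellMeasurement]:
    return [
        w
        for w in wells
        if w.fish_id == fish_id and w.compound == compound and w.well_role == role
    ]


def half_life(k_h: float) -> float:
    """Half-life ln(2)/k in hours; k must be strictly positive."""
    if not (k_h > 0):
        raise ValueError("half_life requires k > 0; check the NSD flag first")
    return math.log(2.0) / k_h


def percent_depletion(
    wells: list[WellMeasurement], fish_id: str, compound: str, end_h: float
) -> float:
    """Percent loss over the incubation: 100·(1 − C̄(end)/C̄(0)).

    Means are over exposure wells at the two time points.
    """
    exp = _select(wells, fish_id, compound, "exposure")
    c0 = [w.concentration_ug_per_L for w in exp if w.time_h == 0.0]
    cend = [w.concentration_ug_per_L for w in exp if w.time_h == end_h]
    if not c0 or not cend:
        raise ValueError(
            f"exposure wells required at t=0 and t={end_h} h for {fish_id}/{compound}"
        )
    return 100.0 * (1.0 - float(np.mean(cend)) / float(np.mean(c0)))


def _initial_guess(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    a0 = float(np.mean(c[t == 0.0]))
    if not (a0 > 0):
        a0 = max(float(np.mean(c)), 1e-9)
    # slope of ln(mean concentration) vs t using time points with positive means
    ts = np.unique(t)
    means = np.array([np.mean(c[t == u]) for u in ts])
    pos = means > 0
    k0 = 0.01
    if pos.sum() >= 2:
        slope = np.polyfit(ts[pos], np.log(means[pos]), 1)[0]
        k0 = max(1e-6, -float(slope))
    return a0, k0


def fit_depletion(
    wells: list[WellMeasurement],
    fish_id: str,
    compound: str,
    alpha: float = DEFAULT_ALPHA,
) -> DepletionFit:
    """Fit C(t) = a·e^(-k·t) to all exposure wells of one fish × compound.

    Requires at least three distinct time points including t = 0.  The fit is
    bounded (a > 0, k ≥ 0) and the standard error of k comes from the fit
    covariance.  The NSD flag recorded here uses the k-significance criterion
    alone (one-sided Wald test of k > 0 at ``alpha``); combine with
    :func:`classify_nsd` when medium controls are available.
    """
    exp = _select(wells, fish_id, compound, "exposure")
    t = np.array([w.time_h for w in exp], dtype=float)
    c = np.array([w.concentration_ug_per_L for w in exp], dtype=float)
    times = np.unique(t)
    if len(times) < 3:
        raise ValueError(
            f"need >= 3 distinct time points for {fish_id}/{compound}, got {len(times)}"
        )
    if 0.0 not in times:
        raise ValueError(f"time 0 missing for {fish_id}/{compound}")

    def model(x: np.ndarray, a: float, k: float) -> np.ndarray:
        return a * np.exp(-k * x)

    a0, k0 = _initial_guess(t, c)
    last_err: Exception | None = None
    popt = pcov = None
    for guess in ((a0, k0), (a0, 0.01)):
        try:
            popt, pcov = optimize.curve_fit(
                model, t, c, p0=guess,
                bounds=([1e-12, 0.0], [np.inf, np.inf]),
                maxfev=10000,
            )
            break
        except (RuntimeError, optimize.OptimizeWarning) as err:  # non-convergence
            last_err = err
    if popt is None:
        raise FitError(
            f"exponential-decay fit failed for {fish_id}/{compound}", last_err
        )

    a_hat, k_hat = float(popt[0]), float(popt[1])
    k_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    resid = c - model(t, a_hat, k_hat)
    rss = float(np.sum(resid**2))
    end_h = float(times.max())
    pct = percent_depletion(wells, fish_id, compound, end_h)
    nsd = k_significance_p(k_hat, k_se, len(t)) >= alpha
    t_half = half_life(k_hat) if (not nsd and k_hat > 0) else float("nan")
    return DepletionFit(
        fish_id=fish_id,
        compound=compound,
        a_ug_per_L=a_hat,
        k_h=k_hat,
        k_se_h=k_se,
        t_half_h=t_half,
        percent_depletion=pct,
        nsd=nsd,
        incubation_end_h=end_h,
        rss=rss,
        n_points=len(t),
    )


def k_significance_p(k_h: float, k_se_h: float, n_points: int) -> float:
    """One-sided p-value for k > 0 (Wald t-test with n−2 df).

    A zero standard error with k > 0 is treated as unambiguous depletion
    (p = 0); a non-finite standard error as no evidence (p = 1).
    """
    if k_h <= 0:
        return 1.0
    if not math.isfinite(k_se_h):
        return 1.0
    if k_se_h == 0.0:
        return 0.0
    df = max(n_points - 2, 1)
    return float(stats.t.sf(k_h / k_se_h, df))


def _welch_less_p(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Welch p for mean(x) < mean(y), with degenerate-variance guard."""
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        return 0.0 if float(np.mean(x)) < float(np.mean(y)) else 1.0
    res = stats.ttest_ind(x, y, equal_var=False, alternative="less")
    return float(res.pvalue)


def classify_nsd(
    fit: DepletionFit,
    wells: list[WellMeasurement],
    alpha: float = DEFAULT_ALPHA,
) -> bool:
    """Classify a fit as NSD ("no substrate depletion").

    True when the one-sided test of k > 0 fails at ``alpha``, OR when
    exposure-well loss does not exceed medium-control (cell-free) loss over the
    same window — a one-sided Welch test of exposure vs. medium-control
    endpoint concentrations.  ``wells`` is the full well list for the
    fish/compound; when it has no medium controls the k-significance criterion
    is used alone, with a logged warning.
    """
    k_fails = k_significance_p(fit.k_h, fit.k_se_h, fit.n_points) >= alpha

    med = _select(wells, fit.fish_id, fit.compound, "medium_control")
    if not med:
        logger.warning(
            "no medium controls for %s/%s: NSD from k-significance alone",
            fit.fish_id, fit.compound,
        )
        return k_fails

    end_h = fit.incubation_end_h
    exp_end = np.array(
        [
            w.concentration_ug_per_L
            for w in _select(wells, fit.fish_id, fit.compound, "exposure")
            if w.time_h == end_h
        ]
    )
    med_end = np.array(
        [w.concentration_ug_per_L for w in med if w.time_h == end_h]
    )
    if len(exp_end) == 0 or len(med_end) == 0:
        logger.warning(
            "no endpoint wells for medium-control comparison of %s/%s",
            fit.fish_id, fit.compound,
        )
        return k_fails
    beyond_abiotic = _welch_less_p(exp_end, med_end) < alpha
    return k_fails or not beyond_abiotic


def with_nsd(fit: DepletionFit, nsd: bool) -> DepletionFit:
    """Copy of ``fit`` with the NSD flag (and t½ marker) updated."""
    t_half = half_life(fit.k_h) if (not nsd and fit.k_h > 0) else float("nan")
    return dataclasses.replace(fit, nsd=nsd, t_half_h=t_half)
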