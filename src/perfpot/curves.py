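"""Potential curves with estimate intervals, in raw units.

Each retained posterior quadruplet defines one Moore curve; evaluating the
whole ensemble on an age grid and taking per-age median and quantiles gives
the potential curve and its envelope.  The envelope is an *estimate
interval*: uncertainty about the individual's potential curve, not a
prediction interval for single race results.  Peaks are computed draw-wise
(closed form per sampled curve) and summarized as median ± half-width of the
central 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import moore
from .preprocess import StandardizationSpec

__all__ = [
    "PotentialCurve",
    "age_grid",
    "curve_ensemble",
    "summarize_curve",
    "peak_summary",
    "POPULATION_LEVEL",
    "INDIVIDUAL_LEVEL",
]

# Default quantile pairs for envelopes: population plots use the central 95%
# band, individual potential curves the central 90% band.
POPULATION_LEVEL = (0.025, 0.975)
INDIVIDUAL_LEVEL = (0.05, 0.95)
GRID_STEP_YEARS = 0.1


@dataclass(frozen=True)
class PotentialCurve:
    """Median curve and quantile envelope on a raw-age grid, with peak."""

    ages: np.ndarray  # raw years
    median: np.ndarray  # raw points
    lower: np.ndarray
    upper: np.ndarray
    level: tuple[float, float]
    peak_age: float  # years
    peak_age_half_interval: float
    peak_score: float  # points
    peak_score_half_interval: float

    def __post_init__(self) -> None:
        if not (np.all(self.lower <= self.median + 1e-12) and np.all(self.median <= self.upper + 1e-12)):
            raise ValueError("envelope must satisfy lower ≤ median ≤ upper at every age")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "median": self.median, "lower": self.lower, "upper": self.upper}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def peak_report(self) -> dict:
        return {
            "peak_age": self.peak_age,
            "peak_age_half_interval": self.peak_age_half_interval,
            "peak_score": self.peak_score,
            "peak_score_half_interval": self.peak_score_half_interval,
            "level": list(self.level),
        }


def age_grid(age_range: tuple[float, float] = (10.0, 25.0), step: float = GRID_STEP_YEARS) -> np.ndarray:
    """Raw-age grid at 0.1-year steps (inclusive of both ends)."""
    lo, hi = age_range
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def curve_ensemble(
    draws: np.ndarray,
    spec: StandardizationSpec,
    grid: np.ndarray,
) -> np.ndarray:
    """Evaluate every quadruplet on a raw-age grid, in raw points.

    ``draws`` is ``(n_draws, 4)``; the result is ``(n_draws, len(grid))``:
    one destandardized curve per retained draw.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[1] != 4 or draws.shape[0] == 0:
        raise ValueError("draws must be a nonempty (n, 4) array")
    t = spec.age_to_model(np.asarray(grid, dtype=float))
    std_curves = moore.evaluate(draws, t)
    return np.asarray(spec.score_to_raw(std_curves))


def summarize_curve(
    curves: np.ndarray,
    grid: np.ndarray,
    spec: StandardizationSpec,
    draws: np.ndarray,
    level: tuple[float, float] = INDIVIDUAL_LEVEL,
) -> PotentialCurve:
    """Per-age median and quantile envelope of an ensemble of raw curves.

    ``curves`` is the ``(n_draws, n_ages)`` output of :func:`curve_ensemble`;
    ``draws`` the matching quadruplets, used for the draw-wise peak summary.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need at least two curves to summarize")
    lo, hi = level
    if not (0 <= lo < hi <= 1):
        raise ValueError("level must be an increasing pair of probabilities in [0, 1]")
    median = np.median(curves, axis=0)
    lower = np.quantile(curves, lo, axis=0)
    upper = np.quantile(curves, hi, axis=0)
    pk = peak_summary(draws, spec)
    return PotentialCurve(
        ages=np.asarray(grid, dtype=float),
        median=median,
        lower=lower,
        upper=upper,
        level=level,
        **pk,
    )


def peak_summary(
    draws: np.ndarray,
    spec: StandardizationSpec,
    max_excluded_fraction: float = 0.5,
) -> dict:
    """Draw-wise peak age and score, summarized as median ± half-interval.

    Each quadruplet's peak is the closed-form extremum of its own curve,
    destandardized to raw years and points.  The ``±`` is the half-width of
    the central 95% interval of the per-draw peaks.  Draws without an
    interior peak are excluded; more than ``max_excluded_fraction`` of them
    is an error.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[1] != 4 or draws.shape[0] == 0:
        raise ValueError("draws must be a nonempty (n, 4) array")
    t_star = moore.peak_ages(draws)
    valid = np.isfinite(t_star)
    n_excluded = int((~valid).sum())
    if n_excluded > max_excluded_fraction * len(t_star):
        raise ValueError(
            f"{n_excluded}/{len(t_star)} draws have no interior peak; ensemble unusable"
        )
    t_ok = t_star[valid]
    q = draws[valid]
    p_star = (
        q[:, 0] * np.exp(-q[:, 1] * t_ok) + q[:, 2] * np.exp(q[:, 3] * t_ok)
    )
    ages = np.asarray(spec.age_to_raw(t_ok), dtype=float)
    scores = np.asarray(spec.score_to_raw(p_star), dtype=float)

    def _mid_half(v):
        med = float(np.median(v))
        lo, hi = np.quantile(v, [0.025, 0.975])
        return med, float((hi - lo) / 2.0)

    peak_age, peak_age_half = _mid_half(ages)
    peak_score, peak_score_half = _mid_half(scores)
    return {
        "peak_age": peak_age,
        "peak_age_half_interval": peak_age_half,
        "peak_score": peak_score,
        "peak_score_half_interval": peak_score_half,
    }


def plot_curve(curve: PotentialCurve, ax=None, observations: pd.DataFrame | None = None):
    """Median potential curve with its quantile envelope (lower = better)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(curve.ages, curve.lower, curve.upper, color="gold", alpha=0.5,
                    label=f"quantiles {curve.level[0]}–{curve.level[1]}")
    ax.plot(curve.ages, curve.median, color="tab:blue", label="median estimate")
    if observations is not None:
        ax.scatter(observations["age"], observations["score"], s=12, color="black", zorder=3,
                   label="best per age")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("points (lower is better)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def potential_curve(
    draws: np.ndarray,
    spec: StandardizationSpec,
    age_range: tuple[float, float] = (10.0, 25.0),
    level: tuple[float, float] = INDIVIDUAL_LEVEL,
) -> PotentialCurve:
    """Convenience: grid + ensemble + summary in one call."""
    grid = age_grid(age_range)
    curves = curve_ensemble(draws, spec, grid)
    return summarize_curve(curves, grid, spec, draws, level=level)
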