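"""Synthetic cohorts with known ground truth.

Generates long-format performance records with the statistical structure the
pipeline assumes: each individual follows a Moore curve whose quadruplet is
drawn around a population truth (or from a mixture of progression
typologies), observed several times per age year with Gaussian residual noise
plus one-sided counter-performance noise (occasional atypically *bad*
results, which only worsen the score and are meant to be neutralized by the
best-per-age filter).

Curves are generated on the model scale (standardized age, standardized and
shifted score) and destandardized with a fixed plausible transform so the
raw-unit plumbing is exercised: ages span 10–25 years and the population peak
lands near 141 points, a realistic race-points scale where lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .moore import MooreParams, evaluate, peak
from .preprocess import PerformanceRecord, StandardizationSpec

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "POPULATION_CENTER",
    "DEFAULT_STANDARDIZATION",
    "generate",
    "four_typology_preset",
    "write_csv",
]

# Population-level quadruplet used as the default generative truth
# (standardized scale, minimized orientation).
POPULATION_CENTER = MooreParams(a=0.5206276, b=2.3244675, c=0.8705898, d=0.1825503)

# Fixed plausible destandardization: ages 10-25 centered at 17.5 (sd 4.6),
# score scale chosen so the population peak lands near 141 points.
DEFAULT_STANDARDIZATION = StandardizationSpec(
    age_mean=17.5, age_sd=4.6, score_mean=97.83, score_sd=40.0, positivity_shift=0.0
)


@dataclass(frozen=True)
class TypologyMixture:
    """Mixture of progression typologies on the log-quadruplet scale."""

    weights: tuple[float, ...]
    means: tuple[tuple[float, float, float, float], ...]  # log-scale quadruplet means
    sds: tuple[tuple[float, float, float, float], ...]  # log-scale diagonal sds

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("typology weights must sum to 1")
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ValueError("weights, means and sds must have equal length")
        for k, mu in enumerate(self.means):
            q = np.exp(mu)
            try:
                MooreParams(*q)
            except ValueError as exc:
                raise ValueError(f"typology component {k} yields an invalid curve: {exc}") from exc


@dataclass(frozen=True)
class CohortSpec:
    """Generative conditions for one synthetic cohort.

    Random effects act additively on the log-quadruplet scale (so every
    individual curve stays U-shaped); ``counter_performance`` is a
    ``(probability, exponential scale)`` pair adding one-sided worse-score
    noise on the standardized scale.
    """

    n_individuals: int = 60
    age_range: tuple[int, int] = (10, 25)
    results_per_age: int = 3
    fixed_truth: MooreParams = POPULATION_CENTER
    random_effect_sds: tuple[float, float, float, float] = (0.1, 0.1, 0.1, 0.1)
    residual_sd: float = 0.1
    counter_performance: tuple[float, float] = (0.3, 0.5)
    typology_mixture: TypologyMixture | None = None
    standardization: StandardizationSpec = DEFAULT_STANDARDIZATION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if self.age_range[1] < self.age_range[0]:
            raise ValueError("empty age range")
        if self.residual_sd < 0 or min(self.random_effect_sds) < 0:
            raise ValueError("noise scales must be non-negative")
        p, scale = self.counter_performance
        if not (0 <= p <= 1) or scale < 0:
            raise ValueError("counter_performance must be (probability in [0,1], scale ≥ 0)")
        if not (self.fixed_truth.a > 0 and self.fixed_truth.c > 0):
            raise ValueError("fixed_truth amplitudes must be positive for a U-shaped curve")


@dataclass
class GroundTruth:
    """What the generator knows: per-individual curves, labels and peaks."""

    params: pd.DataFrame  # individual_id, cluster, a, b, c, d, peak_age, peak_score
    fixed: MooreParams
    standardization: StandardizationSpec
    spec: CohortSpec = field(repr=False, default=None)

    def cluster_labels(self) -> np.ndarray:
        return self.params["cluster"].to_numpy()

    def quadruplets(self) -> np.ndarray:
        return self.params[["a", "b", "c", "d"]].to_numpy()


def _draw_quadruplets(spec: CohortSpec, rng: np.random.Generator):
    n = spec.n_individuals
    if spec.typology_mixture is None:
        log_center = np.log(spec.fixed_truth.as_array())
        sds = np.asarray(spec.random_effect_sds)
        logq = log_center[None, :] + sds[None, :] * rng.standard_normal((n, 4))
        labels = np.full(n, -1)
    else:
        mix = spec.typology_mixture
        labels = rng.choice(len(mix.weights), size=n, p=np.asarray(mix.weights))
        means = np.asarray(mix.means)
        sds = np.asarray(mix.sds)
        logq = means[labels] + sds[labels] * rng.standard_normal((n, 4))
    return np.exp(logq), labels


def generate(spec: CohortSpec) -> tuple[list[PerformanceRecord], GroundTruth]:
    """Draw one cohort; returns raw records plus the generating truth."""
    rng = np.random.default_rng(spec.seed)
    quads, labels = _draw_quadruplets(spec, rng)
    std = spec.standardization

    lo, hi = spec.age_range
    ages = np.arange(lo, hi + 1)
    n_per = spec.results_per_age
    p_cp, cp_scale = spec.counter_performance

    records: list[PerformanceRecord] = []
    rows = []
    for i in range(spec.n_individuals):
        iid = f"ind{i:04d}"
        params_i = MooreParams(*quads[i])
        t_std = std.age_to_model(ages)
        curve = np.asarray(evaluate(params_i, t_std), dtype=float)
        for j, age in enumerate(ages):
            noise = spec.residual_sd * rng.standard_normal(n_per)
            # exponential variates are always drawn so the stream stays aligned
            # across counter-performance settings (same seed → same base noise)
            worse = np.where(
                rng.uniform(size=n_per) < p_cp,
                cp_scale * rng.exponential(1.0, size=n_per),
                0.0,
            )
            scores_std = curve[j] + noise + worse
            for s in scores_std:
                records.append(
                    PerformanceRecord(
                        individual_id=iid,
                        age=float(age),
                        score=float(std.score_to_raw(s)),
                    )
                )
        t_star, p_star = peak(params_i)
        rows.append(
            {
                "individual_id": iid,
                "cluster": int(labels[i]),
                "a": quads[i, 0],
                "b": quads[i, 1],
                "c": quads[i, 2],
                "d": quads[i, 3],
                "peak_age": float(std.age_to_raw(t_star)),
                "peak_score": float(std.score_to_raw(p_star)),
            }
        )

    truth = GroundTruth(
        params=pd.DataFrame(rows),
        fixed=spec.fixed_truth,
        standardization=std,
        spec=spec,
    )
    return records, truth


def four_typology_preset(
    n_individuals: int = 400,
    seed: int = 0,
    within_sd: float = 0.03,
) -> CohortSpec:
    """Cohort spec with four progression typologies of highly unequal size.

    The four components mirror the archetypes the clustering stage is meant
    to recover: a dominant average cluster; a high-young-level group with a
    flat (low) progression slope; a low-young-level group with a strong
    progression slope; and an overall lower-performance group.  Components
    are tight on the log-parameter scale so their slope densities are well
    separated.
    """
    base = np.log(POPULATION_CENTER.as_array())
    deltas = np.array(
        [
            [0.0, 0.0, 0.0, 0.0],  # average
            [-0.6, -0.35, 0.0, 0.0],  # better young level, low progression
            [0.5, 0.12, 0.0, 0.0],  # lower young level, strong progression
            [0.0, 0.0, 0.35, 0.05],  # lower performance overall
        ]
    )
    means = tuple(tuple(base + d) for d in deltas)
    sds = tuple((within_sd,) * 4 for _ in range(4))
    mixture = TypologyMixture(weights=(0.76, 0.08, 0.08, 0.08), means=means, sds=sds)
    return CohortSpec(
        n_individuals=n_individuals,
        typology_mixture=mixture,
        residual_sd=0.1,
        counter_performance=(0.3, 0.5),
        seed=seed,
    )


def write_csv(records: list[PerformanceRecord], path: str | Path) -> None:
    """Write records in the CSV dialect the preprocessing reader expects."""
    pd.DataFrame(
        {
            "id": [r.individual_id for r in records],
            "age": [r.age for r in records],
            "points": [r.score for r in records],
        }
    ).to_csv(path, index=False)
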