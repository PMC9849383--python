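"""Probabilistic cluster membership with uncertainty.

The mixture is fitted on posterior-median quadruplets, but each individual
has a whole ensemble of retained quadruplets; pushing every draw through the
mixture's posterior component probabilities and averaging yields a mean
membership profile per individual, with per-cluster quantile intervals
propagating the curve-fit uncertainty into the typology assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hierarchical import PosteriorEnsemble
from .mixtures import ClusterModel

__all__ = ["MembershipProfile", "draw_responsibilities", "profile", "profile_table"]


@dataclass(frozen=True)
class MembershipProfile:
    """Mean membership probabilities and intervals for one individual."""

    individual_id: str
    mean: np.ndarray  # (K,) simplex
    lower: np.ndarray  # (K,)
    upper: np.ndarray  # (K,)
    level: float

    def __post_init__(self) -> None:
        if abs(float(self.mean.sum()) - 1.0) > 1e-9:
            raise ValueError("mean membership probabilities must sum to 1")
        if not (np.all(self.lower <= self.mean + 1e-12) and np.all(self.mean <= self.upper + 1e-12)):
            raise ValueError("need lower ≤ mean ≤ upper per cluster")

    @property
    def best_cluster(self) -> int:
        return int(np.argmax(self.mean))

    def to_frame(self) -> pd.DataFrame:
        k = len(self.mean)
        return pd.DataFrame(
            {
                "individual_id": [self.individual_id] * k,
                "cluster": np.arange(k),
                "mean_prob": self.mean,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def draw_responsibilities(model: ClusterModel, quadruplet: np.ndarray) -> np.ndarray:
    """Posterior component probabilities of the mixture at one quadruplet."""
    q = np.asarray(quadruplet, dtype=float).reshape(1, 4)
    if not np.all(np.isfinite(q)):
        raise ValueError("quadruplet must be finite")
    return model.responsibilities(q)[0]


def profile(
    model: ClusterModel,
    draws: np.ndarray,
    individual_id: str = "",
    level: float = 0.95,
) -> MembershipProfile:
    """Mean and central quantile interval of per-draw membership simplices."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need at least two draws")
    resp = model.responsibilities(draws)  # (n_draws, K)
    alpha = (1.0 - level) / 2.0
    mean = resp.mean(axis=0)
    mean = mean / mean.sum()  # guard the simplex against rounding drift
    return MembershipProfile(
        individual_id=individual_id,
        mean=mean,
        lower=np.minimum(np.quantile(resp, alpha, axis=0), mean),
        upper=np.maximum(np.quantile(resp, 1.0 - alpha, axis=0), mean),
        level=level,
    )


def plot_profile(prof: MembershipProfile, ax=None):
    """Bar chart of mean membership probabilities with interval whiskers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    k = np.arange(len(prof.mean))
    err = np.vstack([prof.mean - prof.lower, prof.upper - prof.mean])
    ax.bar(k, prof.mean, color="tab:blue", alpha=0.8)
    ax.errorbar(k, prof.mean, yerr=err, fmt="none", ecolor="black", capsize=3)
    ax.set_xticks(k, [f"cluster {i + 1}" for i in k])
    ax.set_ylabel("membership probability")
    ax.set_ylim(0, 1)
    ax.set_title(prof.individual_id)
    return ax


def profile_table(
    model: ClusterModel,
    ensemble: PosteriorEnsemble,
    level: float = 0.95,
) -> pd.DataFrame:
    """Long-format membership table for every individual in the ensemble."""
    frames = [
        profile(model, ensemble.individual_draws(iid), iid, level).to_frame()
        for iid in ensemble.individual_ids
    ]
    return pd.concat(frames, ignore_index=True)
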