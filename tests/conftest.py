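"""Shared fixtures: small synthetic cohorts and a reusable posterior fit."""

from __future__ import annotations

import numpy as np
import pytest

from perfpot.hierarchical import PosteriorEnsemble, SamplerConfig, fit_hierarchical
from perfpot.moore import MooreParams
from perfpot.preprocess import best_per_age, standardize
from perfpot.simulate import CohortSpec, generate

# Population quadruplet used as generative truth throughout the tests
# (standardized scale, minimized orientation).
CENTER = MooreParams(a=0.5206276, b=2.3244675, c=0.8705898, d=0.1825503)


@pytest.fixture(scope="session")
def small_cohort():
    """12 individuals, 3 results per age with counter-performances."""
    spec = CohortSpec(n_individuals=12, seed=42)
    records, truth = generate(spec)
    return records, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Correctly specified sampling regime: one unbiased result per age."""
    spec = CohortSpec(n_individuals=15, results_per_age=1, counter_performance=(0.0, 0.0), seed=7)
    records, truth = generate(spec)
    return records, truth


@pytest.fixture(scope="session")
def clean_table(clean_cohort):
    records, truth = clean_cohort
    return standardize(best_per_age(records), truth.standardization)


@pytest.fixture(scope="session")
def small_ensemble(clean_table) -> PosteriorEnsemble:
    """One reduced-size posterior fit shared by downstream-module tests."""
    return fit_hierarchical(
        clean_table,
        config=SamplerConfig(chains=2, draws=60, warmup=120, seed=11),
    )


def synthetic_ensemble(draws: np.ndarray, ids: list[str], individual: np.ndarray | None = None) -> PosteriorEnsemble:
    """Build a PosteriorEnsemble directly from given draw arrays (1 chain)."""
    n = draws.shape[0]
    if individual is None:
        individual = np.repeat(draws[:, None, :], len(ids), axis=1)
    return PosteriorEnsemble(
        individual_ids=ids,
        fixed=draws,
        individual=individual,
        sigma_res=np.full(n, 0.1),
        re_scales=np.full((n, 4), 0.05),
        n_chains=1,
        n_draws_per_chain=n,
    )
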