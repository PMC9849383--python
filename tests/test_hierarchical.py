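"""Hierarchical Bayesian fit: prefit, gradient, sampling contracts, R²."""

import numpy as np
import pandas as pd
import pytest

from perfpot.hierarchical import (
    PosteriorEnsemble,
    PriorSpec,
    SamplerConfig,
    _HierarchicalModel,
    _prepare_table,
    fit_hierarchical,
    ols_prefit,
    r_squared,
    summarize_fixed,
)
from perfpot.moore import MooreParams, evaluate
from perfpot.preprocess import best_per_age, standardize
from perfpot.simulate import CohortSpec, generate

from .conftest import CENTER, synthetic_ensemble


def _noise_free_table(n_ind=6, ages=16):
    t = np.tile(np.linspace(-1.6, 1.6, ages), n_ind)
    ids = np.repeat([f"i{k}" for k in range(n_ind)], ages)
    y = np.asarray(evaluate(np.array([CENTER.quadruplet]), t))[0]
    return pd.DataFrame({"individual_id": ids, "age_std": t, "score_std": y})


class TestOlsPrefit:
    def test_recovers_noise_free_truth(self):
        fit = ols_prefit(_noise_free_table())
        assert np.allclose(fit.as_array(), CENTER.as_array(), atol=1e-3)

    def test_beats_random_parameter_draws(self):
        table = _noise_free_table()
        t, y = table["age_std"].to_numpy(), table["score_std"].to_numpy()
        fit = ols_prefit(table)
        rss_fit = np.sum((np.asarray(evaluate(np.array([fit.quadruplet]), t))[0] - y) ** 2)
        rng = np.random.default_rng(0)
        for _ in range(100):
            q = np.abs(rng.normal(0.5, 0.5, 4)) + 0.01
            rss_rand = np.sum((np.asarray(evaluate(q[None, :], t))[0] - y) ** 2)
            assert rss_fit <= rss_rand + 1e-12

    def test_constant_data_degenerate_warning(self):
        table = pd.DataFrame(
            {"individual_id": ["x"] * 10, "age_std": np.linspace(-1, 1, 10), "score_std": 1.0}
        )
        with pytest.warns(UserWarning, match="degenerate"):
            ols_prefit(table)

    def test_underdetermined_rejected(self):
        table = _noise_free_table().head(2)
        with pytest.raises(ValueError, match="≥ 8 records"):
            ols_prefit(table)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, clean_table):
        ids, idx, t, y = _prepare_table(clean_table)
        model = _HierarchicalModel(idx, t, y, len(ids), PriorSpec(ols_center=ols_prefit(clean_table)))
        rng = np.random.default_rng(1)
        x = model.initial_point(rng)
        _, g = model.logp_and_grad(x)
        for k in rng.choice(model.dim, 40, replace=False):
            xp, xm = x.copy(), x.copy()
            xp[k] += 1e-6
            xm[k] -= 1e-6
            fd = (model.logp_and_grad(xp)[0] - model.logp_and_grad(xm)[0]) / 2e-6
            assert g[k] == pytest.approx(fd, rel=1e-4, abs=1e-5)


class TestFitContracts:
    def test_draw_counts_and_positivity(self, small_ensemble):
        assert small_ensemble.n_draws_total == 2 * 60
        assert small_ensemble.fixed.shape == (120, 4)
        assert small_ensemble.individual.shape[0] == 120
        assert (small_ensemble.fixed > 0).all()
        assert (small_ensemble.individual > 0).all()

    def test_same_seed_bitwise_identical(self, clean_table):
        cfg = SamplerConfig(chains=2, draws=25, warmup=60, seed=3)
        e1 = fit_hierarchical(clean_table, config=cfg)
        e2 = fit_hierarchical(clean_table, config=cfg)
        assert np.array_equal(e1.fixed, e2.fixed)
        assert np.array_equal(e1.individual, e2.individual)
        assert e1.diagnostics == e2.diagnostics

    def test_diagnostics_present(self, small_ensemble):
        per_param = small_ensemble.diagnostics["per_parameter"]
        assert set(per_param) == {"a", "b", "c", "d", "sigma_res"}
        for stats in per_param.values():
            assert stats["ess"] > 0

    def test_save_load_roundtrip(self, small_ensemble, tmp_path):
        small_ensemble.save(tmp_path / "post")
        back = PosteriorEnsemble.load(tmp_path / "post")
        assert back.individual_ids == small_ensemble.individual_ids
        assert np.allclose(back.fixed, small_ensemble.fixed)
        assert np.allclose(back.individual, small_ensemble.individual)

    def test_zero_random_effect_variance_shrinks_scales(self):
        """Pooled-data limit: random-effect scales collapse toward zero.

        For the amplitude and decline-rate scales (strongly identified per
        individual) the posterior upper bound falls below a tenth of the
        residual scale; for the weakly identified growth-term parameters the
        bound is limited by per-individual measurement uncertainty, so the
        check there is relative to a matched heterogeneous cohort.
        """
        def upper_scales(re_sd, seed):
            spec = CohortSpec(
                n_individuals=30, results_per_age=1, counter_performance=(0.0, 0.0),
                random_effect_sds=(re_sd,) * 4, residual_sd=0.1, seed=5,
            )
            records, truth = generate(spec)
            table = standardize(best_per_age(records), truth.standardization)
            ens = fit_hierarchical(table, config=SamplerConfig(chains=2, draws=75, warmup=150, seed=seed))
            return np.quantile(ens.re_scales, 0.95, axis=0)

        pooled = upper_scales(0.0, seed=9)
        heterogeneous = upper_scales(0.1, seed=9)
        assert np.all(pooled[:2] < 0.1 * 0.1)  # a, b: below 0.1 × residual sd
        assert np.all(pooled < 0.6 * heterogeneous)


class TestPriorInfluence:
    def test_posterior_approaches_ols_as_priors_widen(self):
        """With an off-center prior, widening its scale hands the estimate
        back to the data (whose pooled optimum is the OLS prefit)."""
        table = _noise_free_table(n_ind=4)
        ols = ols_prefit(table)
        offset_center = MooreParams(*(np.array(ols.quadruplet) * np.exp(0.4)))
        gaps = []
        for scale in (0.05, 2.0):
            priors = PriorSpec(ols_center=offset_center, prior_scales=(scale,) * 4)
            ens = fit_hierarchical(
                table, priors=priors, config=SamplerConfig(chains=2, draws=50, warmup=100, seed=21)
            )
            med = np.median(ens.fixed, axis=0)
            gaps.append(np.abs(np.log(med) - np.log(ols.as_array())).max())
        assert gaps[1] < gaps[0]


class TestSummaries:
    def test_identical_draws_zero_error(self):
        draws = np.tile(CENTER.as_array(), (10, 1))
        ens = synthetic_ensemble(draws, ["i0"])
        s = summarize_fixed(ens)
        assert np.allclose(s["Est.Error"], 0.0)
        assert np.allclose(s["Estimate"], s["Q2.5"])
        assert list(s.index) == ["a_Intercept", "b_Intercept", "c_Intercept", "d_Intercept"]
        assert list(s.columns) == ["Estimate", "Est.Error", "Q2.5", "Q97.5"]

    def test_known_distribution_quantiles(self):
        rng = np.random.default_rng(0)
        draws = np.tile(CENTER.as_array(), (800, 1))
        injected = rng.standard_normal(800)
        draws[:, 0] = injected + 5.0  # keep positivity while preserving shape
        ens = synthetic_ensemble(draws, ["i0"])
        s = summarize_fixed(ens)
        assert s.loc["a_Intercept", "Q2.5"] == pytest.approx(5.0 - 1.96, abs=0.15)
        assert s.loc["a_Intercept", "Q97.5"] == pytest.approx(5.0 + 1.96, abs=0.15)
        assert s.loc["a_Intercept", "Est.Error"] == pytest.approx(1.0, abs=0.1)


class TestRSquared:
    def test_perfect_predictions(self):
        table = _noise_free_table()
        assert r_squared(CENTER, table) == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_formula(self, clean_table):
        fit = ols_prefit(clean_table)
        t = clean_table["age_std"].to_numpy()
        y = clean_table["score_std"].to_numpy()
        pred = np.asarray(evaluate(np.array([fit.quadruplet]), t))[0]
        expected = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r_squared(fit, table=clean_table) == pytest.approx(expected, abs=1e-12)

    def test_adjusted_penalizes(self, clean_table):
        fit = ols_prefit(clean_table)
        assert r_squared(fit, clean_table, adjusted=True) < r_squared(fit, clean_table)

    def test_hierarchical_beats_pooled_on_heterogeneous_cohort(self, clean_table, small_ensemble):
        r2_h = r_squared(small_ensemble, clean_table)
        r2_f = r_squared(ols_prefit(clean_table), clean_table)
        assert r2_h > r2_f
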