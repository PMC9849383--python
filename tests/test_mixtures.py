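"""Gaussian mixture family, slope densities and the overlap score."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from perfpot.mixtures import (
    ALL_PARAMETERIZATIONS,
    DegenerateFitError,
    _pair_overlap,
    fit_gpcm,
    fit_mixture_family,
    median_params,
    member_slopes,
    n_free_params,
    overlap_coefficient,
    overlap_score,
    select_model,
    slope_density,
)
from perfpot.preprocess import StandardizationSpec

from .conftest import CENTER, synthetic_ensemble

SPEC = StandardizationSpec(age_mean=17.5, age_sd=4.6, score_mean=97.83, score_sd=40.0, positivity_shift=0.0)


def _blobs(seed=0, n1=120, n2=80, spread2=0.5):
    rng = np.random.default_rng(seed)
    x = np.vstack([
        rng.normal([0.5, 2.0, 0.9, 0.2], 0.08, (n1, 4)),
        rng.normal([1.5, 1.0, 0.4, 0.6], spread2 * 0.2, (n2, 4)),
    ])
    labels = np.array([0] * n1 + [1] * n2)
    return x, labels


class TestMedianParams:
    def test_identical_draws(self):
        draws = np.tile(CENTER.as_array(), (9, 1))
        ens = synthetic_ensemble(draws, ["a", "b"])
        out = median_params(ens)
        assert np.allclose(out.to_numpy(), CENTER.as_array())
        assert list(out.index) == ["a", "b"]

    def test_odd_count_median(self):
        draws = np.array([[1, 1, 1, 1], [2, 2, 2, 2], [3, 3, 3, 3]], dtype=float)
        ens = synthetic_ensemble(draws, ["x"])
        assert np.allclose(median_params(ens).to_numpy(), 2.0)

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            draws = rng.uniform(0.1, 3.0, (11, 4))
            ens = synthetic_ensemble(draws, ["x"], individual=draws[:, None, :])
            naive = np.array([sorted(draws[:, k])[5] for k in range(4)])
            assert np.allclose(median_params(ens).to_numpy()[0], naive)


class TestGpcmFit:
    def test_single_component_is_pooled_moments(self):
        x, _ = _blobs()
        fit = fit_gpcm(x, 1, "VVV", seed=0)
        assert np.allclose(fit.means[0], x.mean(0), atol=1e-8)
        assert np.allclose(fit.covariances[0], np.cov(x.T, bias=True) + 1e-6 * np.eye(4), atol=1e-6)

    def test_separated_blobs_recovered(self):
        x, labels = _blobs()
        fit = fit_gpcm(x, 2, "VVV", seed=0)
        assert adjusted_rand_score(labels, fit.predict(x)) >= 0.95

    @pytest.mark.parametrize("model,sk_type", [
        ("VII", "spherical"), ("VVI", "diag"), ("EEE", "tied"), ("VVV", "full"),
    ])
    def test_agrees_with_reference_em(self, model, sk_type):
        x, _ = _blobs(seed=2)
        mine = fit_gpcm(x, 2, model, seed=1)
        ref = GaussianMixture(2, covariance_type=sk_type, n_init=5, random_state=1,
                              reg_covar=1e-6, tol=1e-8).fit(x)
        assert mine.log_likelihood == pytest.approx(ref.score(x) * len(x), abs=1e-4)

    @pytest.mark.parametrize("model", ALL_PARAMETERIZATIONS)
    def test_constrained_models_nested_under_vvv(self, model):
        x, _ = _blobs(seed=3)
        full = fit_gpcm(x, 2, "VVV", n_restarts=4, seed=2)
        fit = fit_gpcm(x, 2, model, n_restarts=4, seed=2)
        assert fit.log_likelihood <= full.log_likelihood + 1e-6
        assert len(fit.loglik_trace) == fit.n_iter
        # EM ascent: the log likelihood never decreases materially
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-6 * np.abs(fit.loglik_trace[:-1]))

    @pytest.mark.parametrize("model", ALL_PARAMETERIZATIONS)
    def test_constraint_structure_holds(self, model):
        x, _ = _blobs(seed=4)
        fit = fit_gpcm(x, 2, model, n_restarts=3, seed=3)
        covs = fit.covariances
        d = covs.shape[-1]
        vols = np.linalg.det(covs) ** (1 / d)
        offdiag = covs - np.stack([np.diag(np.diag(c)) for c in covs])
        if model[0] == "E":  # equal volume
            assert np.allclose(vols, vols[0], rtol=1e-4)
        if model[1] == "I":  # spherical
            for c, v in zip(covs, vols):
                assert np.allclose(c, v * np.eye(d), rtol=1e-4, atol=1e-8)
        elif model[2] == "I":  # axis-aligned
            assert np.allclose(offdiag, 0.0, atol=1e-8)
        if model in ("EEE",):
            assert np.allclose(covs[0], covs[1], atol=1e-10)
        if model[1] == "E" and model[2] in ("E", "V") and model[1] != "I":  # equal shape
            shapes = np.sort(np.linalg.eigvalsh(covs), axis=1) / vols[:, None]
            assert np.allclose(shapes[0], shapes[1], rtol=1e-3)

    def test_equal_covariance_worse_on_anisotropic_blobs(self):
        x, _ = _blobs(seed=5, spread2=3.0)
        tied = fit_gpcm(x, 2, "EEE", seed=4)
        full = fit_gpcm(x, 2, "VVV", seed=4)
        assert tied.log_likelihood < full.log_likelihood

    def test_degenerate_duplicate_points(self):
        x = np.tile([[1.0, 2.0, 3.0, 4.0]], (40, 1))
        with pytest.raises(DegenerateFitError):
            fit_gpcm(x, 2, "VVV", n_restarts=2, seed=0)

    def test_family_skips_oversized_k(self):
        x, _ = _blobs(n1=12, n2=12)
        table = pd.DataFrame(x, columns=list("abcd"))
        cands = fit_mixture_family(table, k_range=range(2, 9), parameterizations=("VVV",), n_restarts=2, seed=0)
        assert all(c.n_components <= len(x) // 5 for c in cands)

    def test_free_parameter_counts(self):
        # spot checks of the volume/shape/orientation bookkeeping at d=4
        assert n_free_params("EII", 3, 4) == 2 + 12 + 1
        assert n_free_params("VVV", 2, 4) == 1 + 8 + 2 * 10
        assert n_free_params("EEE", 4, 4) == 3 + 16 + 10
        assert n_free_params("VVE", 2, 4) == 1 + 8 + (2 + 2 * 3 + 6)


class TestSlopeDensities:
    def test_identical_members_bandwidth_floor(self):
        quads = np.tile(CENTER.as_array(), (5, 1))
        dens = slope_density(quads, SPEC, age=15.0)
        assert dens.integral() == pytest.approx(1.0, abs=1e-3)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        quads = np.exp(np.log(CENTER.as_array()) + 0.1 * rng.standard_normal((40, 4)))
        for age in (10, 15, 20):
            assert slope_density(quads, SPEC, age=age).integral() == pytest.approx(1.0, abs=1e-3)

    def test_kde_mean_matches_sample_mean(self):
        rng = np.random.default_rng(1)
        quads = np.exp(np.log(CENTER.as_array()) + 0.1 * rng.standard_normal((200, 4)))
        slopes = member_slopes(quads, SPEC, 15.0)
        dens = slope_density(quads, SPEC, age=15.0)
        kde_mean = np.trapezoid(dens.grid * dens.density, dens.grid)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(kde_mean - slopes.mean()) < 3 * se

    def test_slopes_negative_during_progression(self):
        # lower-is-better scores fall with age before the peak
        slopes = member_slopes(CENTER.as_array()[None, :], SPEC, 12.0)
        assert slopes[0] < 0


class TestOverlap:
    def test_closed_form_equal_variance_normals(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            sigma = rng.uniform(0.5, 2.0)
            delta = rng.uniform(0.0, 4.0)
            grid = np.linspace(-10 * sigma, delta + 10 * sigma, 8001)
            ovl = overlap_coefficient(norm.pdf(grid, 0, sigma), norm.pdf(grid, delta, sigma), grid)
            assert ovl == pytest.approx(2 * norm.cdf(-delta / (2 * sigma)), abs=1e-3)

    def test_identical_and_disjoint_samples(self):
        rng = np.random.default_rng(3)
        s = rng.normal(0, 1, 300)
        assert _pair_overlap(s, s) == pytest.approx(1.0, abs=1e-2)
        assert _pair_overlap(s, s + 1000.0) == pytest.approx(0.0, abs=1e-6)

    def test_monte_carlo_agreement(self):
        # ∫min(f,g) = P(accepting the lower density under importance draws)
        rng = np.random.default_rng(4)
        for _ in range(10):
            mu = rng.uniform(0, 3)
            s1, s2 = rng.uniform(0.5, 1.5, 2)
            grid = np.linspace(-12, 15, 6001)
            f1, f2 = norm.pdf(grid, 0, s1), norm.pdf(grid, mu, s2)
            ovl = overlap_coefficient(f1, f2, grid)
            n_mc = 40_000
            half = rng.normal(0, s1, n_mc)
            mc = np.mean(np.minimum(norm.pdf(half, mu, s2) / norm.pdf(half, 0, s1), 1.0))
            se = np.std(np.minimum(norm.pdf(half, mu, s2) / norm.pdf(half, 0, s1), 1.0)) / np.sqrt(n_mc)
            assert abs(ovl - mc) < 3 * se + 1e-3

    def test_score_bounds_and_symmetry(self):
        rng = np.random.default_rng(5)
        x = np.vstack([
            np.exp(np.log(CENTER.as_array()) + 0.03 * rng.standard_normal((30, 4))),
            np.exp(np.log(CENTER.as_array()) + np.array([0.4, 0.2, 0, 0]) + 0.03 * rng.standard_normal((30, 4))),
        ])
        table = pd.DataFrame(x, columns=list("abcd"))
        fit = fit_gpcm(x, 2, "VVI", seed=0)
        score = overlap_score(fit, table, SPEC)
        assert 0.0 <= score <= 1.0
        relabeled = fit_gpcm(x[::-1], 2, "VVI", seed=1)
        score2 = overlap_score(relabeled, pd.DataFrame(x[::-1], columns=list("abcd")), SPEC)
        assert score == pytest.approx(score2, abs=0.05)

    def test_single_cluster_rejected(self):
        x, _ = _blobs()
        fit = fit_gpcm(x, 1, "VVV", seed=0)
        with pytest.raises(ValueError, match="single cluster"):
            overlap_score(fit, pd.DataFrame(x, columns=list("abcd")), SPEC)


class TestSelectModel:
    def test_single_candidate_returned(self):
        x, _ = _blobs()
        table = pd.DataFrame(x, columns=list("abcd"))
        fit = fit_gpcm(x, 2, "VVV", seed=0)
        best, scores = select_model([fit], table, SPEC)
        assert best is fit and len(scores) == 1

    def test_duplicate_winner_idempotent(self):
        x, _ = _blobs()
        table = pd.DataFrame(x, columns=list("abcd"))
        fit = fit_gpcm(x, 2, "VVV", seed=0)
        solo, _ = select_model([fit], table, SPEC)
        import copy

        dup, _ = select_model([fit, copy.deepcopy(fit)], table, SPEC)
        assert dup.overlap == pytest.approx(solo.overlap)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="no candidates"):
            select_model([], pd.DataFrame(columns=list("abcd")), SPEC)
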