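"""Bayesian hierarchical fit of the Moore curve to a cohort.

The population curve ``p(t) = a·e^{-b·t} + c·e^{d·t}`` gains an additive
random part per individual around each fixed parameter, so individual *i*
follows ``p_i(t) = (a+a_i)·e^{-(b+b_i)·t} + (c+c_i)·e^{(d+d_i)·t}``.  All four
effective parameters must stay positive for the curve to keep its U shape, so
sampling works on the log scale: ``log θ_i = φ + σ·z_i`` with standard-normal
``z_i`` (a non-centered parameterization), which makes every retained
quadruplet positive by construction.

Residuals are Gaussian on the standardized score scale.  Priors: Normal on
the log fixed parameters centered at the log of an ordinary-least-squares
prefit; half-Normal on the random-effect scales and the residual scale.  The
posterior is drawn with the in-package No-U-Turn Sampler; with the default
four chains of 200 retained iterations each individual ends up with 800
parameter quadruplets.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import least_squares

from .moore import MooreParams, evaluate
from .nuts import NutsConfig, sample_nuts

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "PosteriorEnsemble",
    "ols_prefit",
    "fit_hierarchical",
    "summarize_fixed",
    "r_squared",
]

DIVERGENCE_WARN_FRACTION = 0.02
RHAT_FLAG = 1.05


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters for the hierarchical fit.

    ``ols_center`` anchors the Normal priors of the log fixed parameters;
    ``prior_scales`` are their standard deviations on the log scale.
    ``random_effect_scale_prior`` and ``noise_prior`` are half-Normal scales
    for the per-parameter random-effect spreads (log scale) and the residual
    standard deviation (standardized score scale).
    """

    ols_center: MooreParams
    prior_scales: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    random_effect_scale_prior: float = 1.0
    noise_prior: float = 1.0

    def __post_init__(self) -> None:
        if min(self.prior_scales) <= 0 or self.random_effect_scale_prior <= 0 or self.noise_prior <= 0:
            raise ValueError("all prior scales must be strictly positive")


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    draws: int = 200
    warmup: int = 500
    seed: int = 0
    target_accept: float = 0.9
    max_treedepth: int = 10


@dataclass
class PosteriorEnsemble:
    """Retained posterior draws for the population and every individual.

    ``fixed`` holds the fixed-effect quadruplets, one row per retained draw
    (``n_chains × n_draws_per_chain`` rows); ``individual`` the effective
    per-individual quadruplets ``(a+a_i, …, d+d_i)`` with shape
    ``(n_draws, n_individuals, 4)``.
    """

    individual_ids: list[str]
    fixed: np.ndarray  # (n_draws_total, 4)
    individual: np.ndarray  # (n_draws_total, n_individuals, 4)
    sigma_res: np.ndarray  # (n_draws_total,)
    re_scales: np.ndarray  # (n_draws_total, 4), log-scale sds
    n_chains: int
    n_draws_per_chain: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = self.n_chains * self.n_draws_per_chain
        if self.fixed.shape != (expected, 4):
            raise ValueError("fixed draw count must equal n_chains × n_draws_per_chain")
        if self.individual.shape != (expected, len(self.individual_ids), 4):
            raise ValueError("individual draw array has wrong shape")
        if not (self.fixed > 0).all() or not (self.individual > 0).all():
            raise ValueError("every retained quadruplet must be strictly positive")

    @property
    def n_draws_total(self) -> int:
        return self.n_chains * self.n_draws_per_chain

    def individual_draws(self, individual_id: str) -> np.ndarray:
        """(n_draws_total, 4) effective quadruplets for one individual."""
        j = self.individual_ids.index(individual_id)
        return self.individual[:, j, :]

    def median_params(self) -> pd.DataFrame:
        """Component-wise posterior median quadruplet per individual."""
        med = np.median(self.individual, axis=0)
        return pd.DataFrame(med, columns=["a", "b", "c", "d"], index=self.individual_ids).rename_axis("individual_id")

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        chain = np.repeat(np.arange(self.n_chains), self.n_draws_per_chain)
        draw = np.tile(np.arange(self.n_draws_per_chain), self.n_chains)
        fixed = pd.DataFrame(self.fixed, columns=["a", "b", "c", "d"])
        fixed.insert(0, "draw", draw)
        fixed.insert(0, "chain", chain)
        fixed["sigma_res"] = self.sigma_res
        for k, name in enumerate(["a", "b", "c", "d"]):
            fixed[f"re_scale_{name}"] = self.re_scales[:, k]
        fixed.to_csv(directory / "fixed_draws.csv", index=False)

        n_tot, n_ind, _ = self.individual.shape
        long = pd.DataFrame(
            self.individual.reshape(n_tot * n_ind, 4), columns=["a", "b", "c", "d"]
        )
        long.insert(0, "draw_index", np.repeat(np.arange(n_tot), n_ind))
        long.insert(0, "individual_id", np.tile(np.array(self.individual_ids, dtype=object), n_tot))
        long.to_csv(directory / "individual_draws.csv", index=False)

        meta = {
            "n_chains": self.n_chains,
            "n_draws_per_chain": self.n_draws_per_chain,
            "individual_ids": self.individual_ids,
            "diagnostics": self.diagnostics,
        }
        (directory / "diagnostics.json").write_text(json.dumps(meta, indent=2, default=float))

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorEnsemble":
        directory = Path(directory)
        meta = json.loads((directory / "diagnostics.json").read_text())
        fixed = pd.read_csv(directory / "fixed_draws.csv")
        long = pd.read_csv(directory / "individual_draws.csv", dtype={"individual_id": str})
        ids = [str(i) for i in meta["individual_ids"]]
        n_tot = meta["n_chains"] * meta["n_draws_per_chain"]
        individual = long[["a", "b", "c", "d"]].to_numpy().reshape(n_tot, len(ids), 4)
        return cls(
            individual_ids=ids,
            fixed=fixed[["a", "b", "c", "d"]].to_numpy(),
            individual=individual,
            sigma_res=fixed["sigma_res"].to_numpy(),
            re_scales=fixed[[f"re_scale_{n}" for n in "abcd"]].to_numpy(),
            n_chains=meta["n_chains"],
            n_draws_per_chain=meta["n_draws_per_chain"],
            diagnostics=meta["diagnostics"],
        )


# ---------------------------------------------------------------------------
# OLS prefit (pooled fixed-effects curve)
# ---------------------------------------------------------------------------

def ols_prefit(table: pd.DataFrame, n_starts: int = 8, seed: int = 0) -> MooreParams:
    """Least-squares fit of the pooled curve on the standardized table.

    Parameters are optimized on the log scale (so the fitted quadruplet is
    positive) from several start points; the best converged fit wins.
    Requires at least 8 records spanning at least 4 distinct ages.
    """
    t = table["age_std"].to_numpy(dtype=float)
    y = table["score_std"].to_numpy(dtype=float)
    if len(t) < 8 or len(np.unique(np.round(t, 9))) < 4:
        raise ValueError("OLS prefit needs ≥ 8 records spanning ≥ 4 distinct ages")

    def resid(logq):
        with np.errstate(over="ignore", invalid="ignore"):
            a, b, c, d = np.exp(np.clip(logq, -30.0, 30.0))
            r = a * np.exp(-b * t) + c * np.exp(d * t) - y
        return np.nan_to_num(r, nan=1e9, posinf=1e9, neginf=-1e9)

    ymean = max(float(np.mean(y)), 1e-6)
    base = np.log([ymean / 2, 1.0, ymean / 2, 0.2])
    rng = np.random.default_rng(seed)
    starts = [base] + [base + rng.normal(0, 0.7, 4) for _ in range(n_starts - 1)]

    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, method="lm", max_nfev=2000)
        except Exception:  # pragma: no cover - lm rarely raises
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("OLS prefit failed to converge from any start point")

    a, b, c, d = np.exp(best.x)
    if a < 1e-6 or c < 1e-6:
        warnings.warn(
            "degenerate OLS prefit: an amplitude collapsed to the boundary "
            f"(a={a:.3g}, c={c:.3g}); data may lack curvature",
            stacklevel=2,
        )
        a, c = max(a, 1e-6), max(c, 1e-6)
    return MooreParams(a=float(a), b=float(b), c=float(c), d=float(d))


# ---------------------------------------------------------------------------
# Hierarchical log posterior (unconstrained parameterization)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _posterior_pass(x, idx, t, y, n_ind, m, phi0, phi_scale, h_re, h_res):
    """Fused log posterior and gradient (see _HierarchicalModel for layout)."""
    phi = x[0:4]
    sigma = np.exp(x[4:8])
    eta_res = x[8]
    s = np.exp(eta_res)
    inv_s2 = np.exp(-2.0 * eta_res)
    grad = np.zeros_like(x)

    theta = np.empty((n_ind, 4))
    for i in range(n_ind):
        base = 9 + 4 * i
        theta[i, 0] = np.exp(x[base])
        theta[i, 1] = np.exp(x[base + 1])
        theta[i, 2] = np.exp(x[base + 2])
        theta[i, 3] = np.exp(phi[3] + sigma[3] * x[base + 3])

    # likelihood: one pass over the records
    sse = 0.0
    gacc = np.zeros((n_ind, 4))
    for j in range(m):
        i = idx[j]
        tj = t[j]
        e1 = np.exp(-theta[i, 1] * tj)
        e2 = np.exp(theta[i, 3] * tj)
        term1 = theta[i, 0] * e1
        term2 = theta[i, 2] * e2
        r = y[j] - term1 - term2
        sse += r * r
        g = r * inv_s2
        gacc[i, 0] += g * e1
        gacc[i, 1] -= g * term1 * tj
        gacc[i, 2] += g * e2
        gacc[i, 3] += g * term2 * tj

    logp = -0.5 * sse * inv_s2 - m * eta_res
    # priors and gradient assembly
    for p in range(4):
        pd = (phi[p] - phi0[p]) / phi_scale[p]
        logp += -0.5 * pd * pd - 0.5 * (sigma[p] / h_re) ** 2 + x[4 + p]
        grad[p] = -pd / phi_scale[p]
        grad[4 + p] = -((sigma[p] / h_re) ** 2) + 1.0
    logp += -0.5 * (s / h_res) ** 2 + eta_res
    grad[8] = sse * inv_s2 - m - (s / h_res) ** 2 + 1.0

    for i in range(n_ind):
        base = 9 + 4 * i
        for p in range(3):  # centered coordinates: log θ_ip directly
            dlt = gacc[i, p] * theta[i, p]
            dev = (x[base + p] - phi[p]) / sigma[p]
            logp += -0.5 * dev * dev - x[4 + p]
            grad[p] += dev / sigma[p]
            grad[4 + p] += dev * dev - 1.0
            grad[base + p] = dlt - dev / sigma[p]
        z_d = x[base + 3]  # non-centered coordinate for d
        dlt = gacc[i, 3] * theta[i, 3]
        logp += -0.5 * z_d * z_d
        grad[3] += dlt
        grad[7] += dlt * z_d * sigma[3]
        grad[base + 3] = dlt * sigma[3] - z_d
    return logp, grad


class _HierarchicalModel:
    """Log posterior and analytic gradient on the unconstrained vector.

    Layout ``[φ(4), log σ_re(4), log σ_res(1), W(N×4 flattened)]``.  Random
    effects live on the log-parameter scale, ``log θ_ip ~ N(φ_p, σ_p²)``, so
    every effective quadruplet is positive.  The parameterization is mixed:
    for a, b, c — which the per-individual data identify strongly — the
    sampler works on ``W_ip = log θ_ip`` directly (centered form, good
    geometry when the likelihood dominates the hierarchical prior), while for
    the weakly identified rate d it works on the standardized offset
    ``W_id = z_id`` with ``log θ_id = φ_d + σ_d·z_id`` (non-centered form,
    which removes the funnel the centered form develops when a scale is
    dragged toward zero).  Overflow in the double exponentials far out in the
    tails is harmless: it yields a ``-inf`` log density that the sampler
    treats as a rejected (divergent) leapfrog state.
    """

    def __init__(self, idx, t, y, n_ind, priors: PriorSpec):
        self.idx = idx
        self.t = t
        self.y = y
        self.n_ind = n_ind
        self.m = len(y)
        self.phi0 = np.log(priors.ols_center.as_array())
        self.phi_scale = np.asarray(priors.prior_scales, dtype=float)
        self.h_re = priors.random_effect_scale_prior
        self.h_res = priors.noise_prior
        self.dim = 9 + 4 * n_ind

    def logp_and_grad(self, x):
        logp, grad = _posterior_pass(
            x, self.idx, self.t, self.y, self.n_ind, self.m,
            self.phi0, self.phi_scale, self.h_re, self.h_res,
        )
        if not (np.isfinite(logp) and np.all(np.isfinite(grad))):
            return -np.inf, np.zeros_like(x)
        return float(logp), grad

    def initial_point(self, rng, jitter=0.05):
        x0 = np.zeros(self.dim)
        x0[0:4] = self.phi0
        x0[4:8] = np.log(0.1)
        x0[8] = np.log(0.3)
        w0 = np.zeros((self.n_ind, 4))
        w0[:, :3] = self.phi0[:3]
        x0[9:] = w0.ravel()
        x0 += jitter * rng.standard_normal(self.dim)
        return x0


def _prepare_table(table: pd.DataFrame):
    ids = table["individual_id"].astype(str)
    unique_ids = list(dict.fromkeys(ids))  # stable order of first appearance
    code = {u: k for k, u in enumerate(unique_ids)}
    idx = np.array([code[i] for i in ids], dtype=np.intp)
    t = table["age_std"].to_numpy(dtype=float)
    y = table["score_std"].to_numpy(dtype=float)
    return unique_ids, idx, t, y


def fit_hierarchical(
    table: pd.DataFrame,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorEnsemble:
    """Sample the hierarchical posterior on a standardized best-per-age table.

    ``table`` needs columns ``individual_id``, ``age_std``, ``score_std``.
    Returns one ensemble with ``chains × draws`` retained quadruplets for the
    population and for every individual, plus convergence diagnostics
    (split R-hat, effective sample size, divergence counts).
    """
    config = config or SamplerConfig()
    if priors is None:
        priors = PriorSpec(ols_center=ols_prefit(table, seed=config.seed))
    unique_ids, idx, t, y = _prepare_table(table)
    model = _HierarchicalModel(idx, t, y, len(unique_ids), priors)

    nuts_cfg = NutsConfig(
        draws=config.draws,
        warmup=config.warmup,
        target_accept=config.target_accept,
        max_treedepth=config.max_treedepth,
    )
    seed_seq = np.random.SeedSequence(config.seed)
    chain_draws = []
    n_divergent = 0
    for chain, child in enumerate(seed_seq.spawn(config.chains)):
        rng = np.random.default_rng(child)
        x0 = model.initial_point(rng)
        result = sample_nuts(model.logp_and_grad, x0, nuts_cfg, rng)
        chain_draws.append(result.draws)
        n_divergent += result.n_divergent
        logger.info(
            "chain %d: step size %.4g, mean accept %.3f, %d divergent, %d max-depth",
            chain, result.step_size, result.accept_mean, result.n_divergent, result.n_max_depth,
        )

    frac_div = n_divergent / (config.chains * config.draws)
    if frac_div > DIVERGENCE_WARN_FRACTION:
        warnings.warn(
            f"{n_divergent} divergent transitions "
            f"({100 * frac_div:.1f}% of retained draws); estimates may be biased",
            stacklevel=2,
        )

    stacked = np.stack(chain_draws)  # (chains, draws, dim)
    phi = stacked[:, :, 0:4]
    eta_re = stacked[:, :, 4:8]
    eta_res = stacked[:, :, 8]
    w = stacked[:, :, 9:].reshape(config.chains, config.draws, len(unique_ids), 4)

    diagnostics = _diagnostics(phi, eta_re, eta_res, n_divergent, frac_div)

    flat = lambda arr: arr.reshape(-1, *arr.shape[2:])
    sigma = np.exp(flat(eta_re))
    fixed = np.exp(flat(phi))
    log_theta = flat(w).copy()  # centered coords are log θ; decode the non-centered d
    log_theta[:, :, 3] = flat(phi)[:, None, 3] + sigma[:, None, 3] * flat(w)[:, :, 3]
    individual = np.exp(log_theta)
    return PosteriorEnsemble(
        individual_ids=unique_ids,
        fixed=fixed,
        individual=individual,
        sigma_res=np.exp(flat(eta_res)),
        re_scales=sigma,
        n_chains=config.chains,
        n_draws_per_chain=config.draws,
        diagnostics=diagnostics,
    )


def _diagnostics(phi, eta_re, eta_res, n_divergent, frac_div) -> dict:
    import arviz as az

    names = ["a", "b", "c", "d"]
    per_param = {}
    flagged = []
    for k, name in enumerate(names):
        draws = np.exp(phi[:, :, k])
        rhat = float(az.rhat(draws)) if phi.shape[0] > 1 else float("nan")
        ess = float(az.ess(draws))
        per_param[name] = {"rhat": rhat, "ess": ess}
        if np.isfinite(rhat) and rhat > RHAT_FLAG:
            flagged.append(name)
    sig_res = np.exp(eta_res)
    per_param["sigma_res"] = {
        "rhat": float(az.rhat(sig_res)) if phi.shape[0] > 1 else float("nan"),
        "ess": float(az.ess(sig_res)),
    }
    if flagged:
        warnings.warn(f"R-hat above {RHAT_FLAG} for fixed parameters: {flagged}", stacklevel=3)
    return {
        "per_parameter": per_param,
        "rhat_flagged": flagged,
        "n_divergent": int(n_divergent),
        "divergent_fraction": float(frac_div),
    }


# ---------------------------------------------------------------------------
# Posterior summaries and goodness of fit
# ---------------------------------------------------------------------------

def summarize_fixed(ensemble: PosteriorEnsemble) -> pd.DataFrame:
    """Median, posterior sd and central 95% quantiles of the fixed effects.

    Rows ``a_Intercept`` … ``d_Intercept``; columns ``Estimate``,
    ``Est.Error``, ``Q2.5``, ``Q97.5``.
    """
    if ensemble.fixed.size == 0:
        raise ValueError("empty ensemble")
    rows = []
    for k, name in enumerate(["a", "b", "c", "d"]):
        col = ensemble.fixed[:, k]
        rows.append(
            {
                "Estimate": float(np.median(col)),
                "Est.Error": float(np.std(col, ddof=1)) if len(col) > 1 else 0.0,
                "Q2.5": float(np.quantile(col, 0.025)),
                "Q97.5": float(np.quantile(col, 0.975)),
            }
        )
    return pd.DataFrame(rows, index=[f"{n}_Intercept" for n in "abcd"])


def r_squared(
    model: PosteriorEnsemble | MooreParams,
    table: pd.DataFrame,
    adjusted: bool = False,
    n_params: int | None = None,
) -> float:
    """Coefficient of determination ``1 − SS_res / SS_tot`` on the table.

    With a :class:`PosteriorEnsemble`, each record is predicted from its own
    individual's posterior-median quadruplet (the random-effects fit); with a
    plain :class:`MooreParams`, from the single pooled curve.  The adjusted
    variant penalizes by the number of fitted parameters (four per curve by
    default).
    """
    t = table["age_std"].to_numpy(dtype=float)
    y = table["score_std"].to_numpy(dtype=float)
    if isinstance(model, PosteriorEnsemble):
        med = model.median_params()
        params = med.loc[table["individual_id"].astype(str)].to_numpy()
        a, b, c, d = params.T
        pred = a * np.exp(-b * t) + c * np.exp(d * t)
        default_p = 4 * len(model.individual_ids)
    else:
        pred = np.asarray(evaluate(model, t), dtype=float)
        default_p = 4
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total variance: R² undefined")
    r2 = 1.0 - ss_res / ss_tot
    if not adjusted:
        return r2
    p = n_params if n_params is not None else default_p
    n = len(y)
    if n - p - 1 <= 0:
        raise ValueError("too few records for the adjusted R² with this many parameters")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
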