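"""Progression-typology clustering of individual curve parameters.

Individuals are clustered on the posterior-median quadruplets (a, b, c, d)
with finite Gaussian mixtures fitted by expectation-maximization.  The
covariance matrices follow the volume/shape/orientation decomposition
``Σ_k = λ_k · D_k · A_k · D_kᵀ`` (λ volume, A shape — diagonal with unit
determinant —, D orientation), giving the classic family of 14 constrained
parameterizations named by which of the three factors are Equal across
clusters, Variable, the Identity, or axis-aligned:

    spherical:  EII VII
    diagonal:   EEI VEI EVI VVI
    general:    EEE VEE EVE VVE EEV VEV EVV VVV

Model selection uses an overlap score on the clusters' *progression slopes*:
for each scoring age (10–20 raw years) and each pair of clusters, the
overlap coefficient ``∫ min(f'_i, f'_j)`` of the kernel densities of the
members' curve derivatives; the mean over all (age, pair) terms is the
model's score, and lower is better — distinct typologies progress
differently.  The number of clusters is fixed once by BIC across all
candidates; the overlap score then arbitrates between the 14
parameterizations at that K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus

from . import moore
from .hierarchical import PosteriorEnsemble
from .preprocess import StandardizationSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ALL_PARAMETERIZATIONS",
    "ClusterModel",
    "SlopeDensity",
    "DegenerateFitError",
    "median_params",
    "fit_gpcm",
    "fit_mixture_family",
    "member_slopes",
    "slope_density",
    "overlap_coefficient",
    "overlap_score",
    "select_model",
]

ALL_PARAMETERIZATIONS = (
    "EII", "VII",
    "EEI", "VEI", "EVI", "VVI",
    "EEE", "VEE", "EVE", "VVE", "EEV", "VEV", "EVV", "VVV",
)

SCORING_AGES = tuple(range(10, 21))  # raw years, inclusive
COV_REG = 1e-6  # diagonal regularization after every M-step
EM_TOL = 1e-8
EM_MAX_ITER = 500
N_RESTARTS = 10
MIN_WEIGHT = 1e-6


class DegenerateFitError(RuntimeError):
    """EM collapsed: vanishing component weight or singular covariance."""


# ---------------------------------------------------------------------------
# Input: median quadruplets per individual
# ---------------------------------------------------------------------------

def median_params(ensemble: PosteriorEnsemble) -> pd.DataFrame:
    """Component-wise median of each individual's retained quadruplets."""
    return ensemble.median_params()


# ---------------------------------------------------------------------------
# Constrained covariance M-steps (volume/shape/orientation decomposition)
# ---------------------------------------------------------------------------

def _det_normalize(diag: np.ndarray) -> np.ndarray:
    """Scale a positive diagonal to unit determinant (unit geometric mean)."""
    diag = np.maximum(diag, 1e-300)
    return diag / np.exp(np.mean(np.log(diag)))


def _eigh_desc(mats: np.ndarray):
    vals, vecs = np.linalg.eigh(mats)
    return vals[..., ::-1], vecs[..., ::-1]


def _common_orientation(scatters, shapes_inv, weights, d_init, n_iter=12, tol=1e-10):
    """Minimize Σ_k w_k·tr(D A_k⁻¹ Dᵀ W_k) over orthogonal D (MM ascent).

    Writing W_k = ω_k·I − S_k with S_k ⪰ 0 turns the problem into maximizing
    a convex quadratic in D, minorized by its tangent plane; each step is an
    orthogonal Procrustes solve, so the objective descends monotonically.
    """
    omegas = [np.linalg.eigvalsh(w)[-1] for w in scatters]
    s_mats = [om * np.eye(w.shape[0]) - w for om, w in zip(omegas, scatters)]
    d_mat = d_init
    prev = np.inf
    for _ in range(n_iter):
        m = sum(
            wk * (s @ d_mat) * ainv[None, :]
            for wk, s, ainv in zip(weights, s_mats, shapes_inv)
        )
        u, _, vt = np.linalg.svd(m)
        d_mat = u @ vt
        obj = sum(
            wk * float(np.sum((d_mat * ainv[None, :]) * (w @ d_mat)))
            for wk, w, ainv in zip(weights, scatters, shapes_inv)
        )
        if abs(prev - obj) <= tol * (1 + abs(obj)):
            break
        prev = obj
    return d_mat


def _covariances_for(model: str, scatters: np.ndarray, n_k: np.ndarray, prev_cov: np.ndarray):
    """Constrained covariance update given per-cluster scatter matrices.

    ``scatters``: (K, d, d) responsibility-weighted scatter; ``n_k``: soft
    counts.  Returns (K, d, d) covariances obeying the parameterization.
    """
    k_comp, d, _ = scatters.shape
    n = float(n_k.sum())
    w_tot = scatters.sum(axis=0)
    diags = np.einsum("kii->ki", scatters)

    if model == "EII":
        lam = np.trace(w_tot) / (n * d)
        cov = np.tile(lam * np.eye(d), (k_comp, 1, 1))
    elif model == "VII":
        lam_k = np.einsum("kii->k", scatters) / (n_k * d)
        cov = lam_k[:, None, None] * np.eye(d)
    elif model == "EEI":
        cov = np.tile(np.diag(np.diag(w_tot) / n), (k_comp, 1, 1))
    elif model == "VEI":
        shape = _det_normalize(np.diag(w_tot))
        for _ in range(20):
            lam_k = (diags / shape[None, :]).sum(axis=1) / (n_k * d)
            shape = _det_normalize((diags / lam_k[:, None]).sum(axis=0))
        cov = lam_k[:, None, None] * np.diag(shape)[None, :, :]
    elif model == "EVI":
        dets = np.exp(np.mean(np.log(np.maximum(diags, 1e-300)), axis=1))  # |diag W_k|^{1/d}
        shapes = diags / dets[:, None]
        lam = dets.sum() / n
        cov = lam * np.stack([np.diag(s) for s in shapes])
    elif model == "VVI":
        cov = np.stack([np.diag(diags[k] / n_k[k]) for k in range(k_comp)])
    elif model == "EEE":
        cov = np.tile(w_tot / n, (k_comp, 1, 1))
    elif model == "VEE":
        lam_k = np.einsum("kii->k", scatters) / (n_k * d)
        for _ in range(20):
            c_mat = (scatters / lam_k[:, None, None]).sum(axis=0)
            c_mat /= np.exp(np.mean(np.log(np.maximum(np.linalg.eigvalsh(c_mat), 1e-300))))
            c_inv = np.linalg.inv(c_mat)
            lam_k = np.einsum("ij,kji->k", c_inv, scatters) / (n_k * d)
        cov = lam_k[:, None, None] * c_mat[None, :, :]
    elif model in ("EVE", "VVE"):
        cov = _shared_orientation_update(model, scatters, n_k, prev_cov)
    elif model == "EEV":
        omegas, d_mats = _eigh_desc(scatters)
        shape = _det_normalize(omegas.sum(axis=0))
        lam = float((omegas / shape[None, :]).sum()) / (n * d)
        cov = np.einsum("kij,j,klj->kil", d_mats, lam * shape, d_mats)
    elif model == "VEV":
        omegas, d_mats = _eigh_desc(scatters)
        lam_k = omegas.sum(axis=1) / (n_k * d)
        for _ in range(20):
            shape = _det_normalize((omegas / lam_k[:, None]).sum(axis=0))
            lam_k = (omegas / shape[None, :]).sum(axis=1) / (n_k * d)
        cov = np.einsum("kij,kj,klj->kil", d_mats, lam_k[:, None] * shape[None, :], d_mats)
    elif model == "EVV":
        dets = np.array([np.exp(np.mean(np.log(np.maximum(np.linalg.eigvalsh(w), 1e-300)))) for w in scatters])
        lam = dets.sum() / n
        cov = lam * scatters / dets[:, None, None]
    elif model == "VVV":
        cov = scatters / n_k[:, None, None]
    else:
        raise ValueError(f"unknown parameterization {model!r}")
    return cov + COV_REG * np.eye(d)


def _shared_orientation_update(model, scatters, n_k, prev_cov):
    k_comp, d, _ = scatters.shape
    n = float(n_k.sum())
    # warm-start orientation from the previous covariances' pooled eigenvectors
    _, d_mat = _eigh_desc(prev_cov.sum(axis=0))
    lam_k = np.einsum("kii->k", scatters) / (n_k * d)
    shapes = np.tile(np.ones(d), (k_comp, 1))
    prev_shapes = None
    # partial M-step: a few alternations suffice for a generalized-EM ascent
    for _ in range(6):
        weights = np.ones(k_comp) if model == "EVE" else 1.0 / np.maximum(lam_k, 1e-300)
        d_mat = _common_orientation(scatters, 1.0 / shapes, weights, d_mat)
        rotated = np.einsum("ji,kjl,li->ki", d_mat, scatters, d_mat)  # diag(Dᵀ W_k D)
        rotated = np.maximum(rotated, 1e-300)
        if model == "EVE":
            dets = np.exp(np.mean(np.log(rotated), axis=1))
            shapes = rotated / dets[:, None]
            lam = dets.sum() / n
            lam_k = np.full(k_comp, lam)
        else:  # VVE
            shapes = np.stack([_det_normalize(r) for r in rotated])
            lam_k = (rotated / shapes).sum(axis=1) / (n_k * d)
        if prev_shapes is not None and np.max(np.abs(shapes - prev_shapes)) < 1e-8:
            break
        prev_shapes = shapes.copy()
    return np.einsum("ij,kj,lj->kil", d_mat, lam_k[:, None] * shapes, d_mat)


def _n_cov_params(model: str, k: int, d: int) -> int:
    orient_full = d * (d - 1) // 2
    volume = 1 if model[0] == "E" else k
    if model[1] == "I":  # spherical: EII / VII
        return volume
    shape = (d - 1) if model[1] == "E" else k * (d - 1)
    if model[2] == "I":  # axis-aligned (diagonal family)
        return volume + shape
    orient = orient_full if model[2] == "E" else k * orient_full
    return volume + shape + orient


def n_free_params(model: str, k: int, d: int) -> int:
    """Free parameters of the mixture: weights + means + covariance."""
    return (k - 1) + k * d + _n_cov_params(model, k, d)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """A fitted Gaussian mixture under one covariance parameterization."""

    parameterization: str
    n_components: int
    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)
    log_likelihood: float
    n_params: int
    bic: float
    n_iter: int
    overlap: float | None = None
    member_ids: list[str] = field(default_factory=list)
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    def log_responsibilities(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        logw = _log_gaussian_components(x, self.means, self.covariances) + np.log(self.weights)[None, :]
        norm = _logsumexp(logw)
        return logw - norm[:, None]

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.log_responsibilities(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.log_responsibilities(x), axis=1)

    def card(self) -> dict:
        return {
            "parameterization": self.parameterization,
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_params": self.n_params,
            "bic": self.bic,
            "overlap_score": self.overlap,
        }


def _logsumexp(a: np.ndarray) -> np.ndarray:
    mx = a.max(axis=1)
    return mx + np.log(np.exp(a - mx[:, None]).sum(axis=1))


def _log_gaussian_components(x, means, covs) -> np.ndarray:
    n, d = x.shape
    try:
        chol = np.linalg.cholesky(covs)  # (k, d, d), batched
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError("singular component covariance") from exc
    logdet = 2.0 * np.log(np.einsum("kii->ki", chol)).sum(axis=1)  # (k,)
    prec_chol = np.linalg.inv(chol)  # lower-triangular inverses
    dev = x[:, None, :] - means[None, :, :]  # (n, k, d)
    sol = np.einsum("kij,nkj->nki", prec_chol, dev)
    maha = np.einsum("nki,nki->nk", sol, sol)
    return -0.5 * (maha + logdet[None, :] + d * np.log(2 * np.pi))


def fit_gpcm(
    x: np.ndarray,
    n_components: int,
    parameterization: str = "VVV",
    n_restarts: int = N_RESTARTS,
    seed: int = 0,
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
) -> ClusterModel:
    """EM fit of one (parameterization, K) candidate; best of several starts.

    Restarts use k-means++ seeding.  Raises :class:`DegenerateFitError` if
    every restart collapses (vanishing weight or singular covariance).
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    if parameterization not in ALL_PARAMETERIZATIONS:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    if n < n_components:
        raise ValueError("fewer points than components")

    rng = np.random.default_rng(seed)
    best = None
    last_err: Exception | None = None
    for restart in range(n_restarts):
        try:
            cand = _fit_once(x, n_components, parameterization, rng, max_iter, tol)
        except DegenerateFitError as err:
            last_err = err
            continue
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    if best is None:
        raise DegenerateFitError(
            f"all {n_restarts} EM restarts degenerate for {parameterization}, K={n_components}"
        ) from last_err
    return best


def _fit_once(x, k, model, rng, max_iter, tol):
    n, d = x.shape
    if k == 1:
        resp = np.ones((n, 1))
    else:
        _, indices = kmeans_plusplus(x, n_clusters=k, random_state=int(rng.integers(2**31 - 1)))
        centers = x[indices]
        dist = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        resp = np.zeros((n, k))
        resp[np.arange(n), np.argmin(dist, axis=1)] = 1.0
        resp = np.maximum(resp, 1e-10)
        resp /= resp.sum(axis=1, keepdims=True)

    cov = np.tile(np.cov(x.T) + COV_REG * np.eye(d), (k, 1, 1))
    loglik = -np.inf
    trace: list[float] = []
    for it in range(max_iter):
        # M-step
        n_k = resp.sum(axis=0)
        if np.any(n_k / n < MIN_WEIGHT):
            raise DegenerateFitError("component weight collapsed")
        weights = n_k / n
        means = (resp.T @ x) / n_k[:, None]
        dev = x[:, None, :] - means[None, :, :]  # (n, k, d)
        scatters = np.einsum("nk,nki,nkj->kij", resp, dev, dev)
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                cov = _covariances_for(model, scatters, n_k, cov)
        except np.linalg.LinAlgError as exc:
            raise DegenerateFitError(f"covariance update failed: {exc}") from exc
        if not np.all(np.isfinite(cov)):
            raise DegenerateFitError("covariance update produced non-finite values")
        # E-step
        logw = _log_gaussian_components(x, means, cov) + np.log(weights)[None, :]
        norm = _logsumexp(logw)
        new_loglik = float(norm.sum())
        resp = np.exp(logw - norm[:, None])
        trace.append(new_loglik)
        if new_loglik - loglik <= tol * (1 + abs(new_loglik)) and it > 0:
            loglik = new_loglik
            break
        loglik = new_loglik

    p = n_free_params(model, k, d)
    return ClusterModel(
        parameterization=model,
        n_components=k,
        weights=weights,
        means=means,
        covariances=cov,
        log_likelihood=loglik,
        n_params=p,
        bic=-2.0 * loglik + p * np.log(n),
        n_iter=it + 1,
        loglik_trace=trace,
    )


def fit_mixture_family(
    table: pd.DataFrame,
    k_range: range | tuple = range(2, 9),
    parameterizations: tuple[str, ...] = ALL_PARAMETERIZATIONS,
    n_restarts: int = N_RESTARTS,
    seed: int = 0,
) -> list[ClusterModel]:
    """Fit every (parameterization, K) candidate on the quadruplet table.

    ``table`` is indexed by individual id with columns a, b, c, d.  K values
    needing more than n/5 components are skipped; degenerate fits are
    dropped with a log entry.
    """
    x = table[["a", "b", "c", "d"]].to_numpy(dtype=float)
    ids = [str(i) for i in table.index]
    candidates = []
    for k in k_range:
        if len(x) < 5 * k:
            logger.info("skipping K=%d: fewer than %d individuals", k, 5 * k)
            continue
        for model in parameterizations:
            try:
                fit = fit_gpcm(x, k, model, n_restarts=n_restarts, seed=seed + 17 * k)
            except DegenerateFitError as err:
                logger.info("discarding %s K=%d: %s", model, k, err)
                continue
            fit.member_ids = ids
            candidates.append(fit)
    return candidates


# ---------------------------------------------------------------------------
# Slope densities and the overlap score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlopeDensity:
    """KDE of one cluster's progression slopes at one raw age."""

    cluster_id: int
    age: float
    grid: np.ndarray
    density: np.ndarray

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def member_slopes(quadruplets: np.ndarray, spec: StandardizationSpec, age: float) -> np.ndarray:
    """Curve derivative in raw units (points per year) at one raw age."""
    t = float(spec.age_to_model(age))
    slopes_std = np.asarray(moore.derivative(np.asarray(quadruplets, dtype=float), t))
    return slopes_std[:, 0] * spec.score_sd / spec.age_sd


def _silverman_bandwidth(values: np.ndarray) -> float:
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    scale = max(float(np.mean(np.abs(values))), 1e-12)
    bw = 0.9 * spread * n ** (-0.2) if spread > 0 else 0.0
    return max(bw, 1e-6 * scale)


def _kde(values: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    z = (grid[:, None] - values[None, :]) / bw
    return np.exp(-0.5 * z * z).sum(axis=1) / (len(values) * bw * np.sqrt(2 * np.pi))


def slope_density(
    quadruplets: np.ndarray,
    spec: StandardizationSpec,
    age: float,
    cluster_id: int = 0,
    grid: np.ndarray | None = None,
) -> SlopeDensity:
    """Gaussian KDE (Silverman bandwidth with a floor) of members' slopes."""
    slopes = member_slopes(quadruplets, spec, age)
    bw = _silverman_bandwidth(slopes)
    if grid is None:
        lo, hi = slopes.min() - 5 * bw, slopes.max() + 5 * bw
        grid = np.linspace(lo, hi, 512)
    return SlopeDensity(cluster_id=cluster_id, age=float(age), grid=grid, density=_kde(slopes, grid, bw))


def overlap_coefficient(f1: np.ndarray, f2: np.ndarray, grid: np.ndarray) -> float:
    """``∫ min(f1, f2)`` by the trapezoid rule on a shared grid."""
    return float(np.trapezoid(np.minimum(f1, f2), grid))


def _pair_overlap(slopes_i: np.ndarray, slopes_j: np.ndarray) -> float:
    bw_i = _silverman_bandwidth(slopes_i)
    bw_j = _silverman_bandwidth(slopes_j)
    pad = 5 * max(bw_i, bw_j)
    lo = min(slopes_i.min(), slopes_j.min()) - pad
    hi = max(slopes_i.max(), slopes_j.max()) + pad
    grid = np.linspace(lo, hi, 512)
    return overlap_coefficient(_kde(slopes_i, grid, bw_i), _kde(slopes_j, grid, bw_j), grid)


def overlap_score(
    model: ClusterModel,
    table: pd.DataFrame,
    spec: StandardizationSpec,
    scoring_ages: tuple = SCORING_AGES,
    min_members: int = 2,
) -> float:
    """Mean slope-density overlap over scoring ages and cluster pairs.

    Normalized by the number of (age, pair) terms so scores are comparable
    across different K; the result lies in [0, 1].  Raises on a single
    cluster (no pairs) or clusters with fewer than ``min_members`` members.
    """
    if model.n_components < 2:
        raise ValueError("overlap score undefined for a single cluster")
    x = table[["a", "b", "c", "d"]].to_numpy(dtype=float)
    labels = model.predict(x)
    groups = []
    for k in range(model.n_components):
        members = x[labels == k]
        if len(members) < min_members:
            raise DegenerateFitError(
                f"cluster {k} has {len(members)} member(s); need ≥ {min_members} for a slope density"
            )
        groups.append(members)

    total = 0.0
    n_terms = 0
    for age in scoring_ages:
        slopes = [member_slopes(g, spec, age) for g in groups]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                total += _pair_overlap(slopes[i], slopes[j])
                n_terms += 1
    return total / n_terms


def select_model(
    candidates: list[ClusterModel],
    table: pd.DataFrame,
    spec: StandardizationSpec,
    scoring_ages: tuple = SCORING_AGES,
) -> tuple[ClusterModel, pd.DataFrame]:
    """Choose the mixture: global BIC fixes the number of clusters, the
    overlap score arbitrates between the covariance parameterizations at
    that K.

    A raw overlap argmin across K is degenerate — merging slope-similar
    clusters or splitting a continuum both lower the mean pairwise overlap —
    so K comes from the likelihood side once, and the slope-separation score
    then does what it is for: choosing the cluster geometry.  Returns the
    winner (overlap filled in) and a score table over all finalists.  Ties
    on the overlap score break toward fewer free parameters, then smaller K.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    k_star = min(candidates, key=lambda c: c.bic).n_components
    by_param: dict[str, ClusterModel] = {}
    for cand in candidates:
        if cand.n_components == k_star:
            by_param[cand.parameterization] = cand

    rows = []
    finalists = []
    for cand in by_param.values():
        try:
            cand.overlap = overlap_score(cand, table, spec, scoring_ages)
        except (DegenerateFitError, ValueError) as err:
            logger.info("candidate %s K=%d not scorable: %s", cand.parameterization, cand.n_components, err)
            continue
        finalists.append(cand)
        rows.append(
            {
                "parameterization": cand.parameterization,
                "K": cand.n_components,
                "log_likelihood": cand.log_likelihood,
                "n_params": cand.n_params,
                "bic": cand.bic,
                "overlap_score": cand.overlap,
            }
        )
    if not finalists:
        raise ValueError("no scorable candidate (all degenerate or single-cluster)")
    finalists.sort(key=lambda c: (c.overlap, c.n_params, c.n_components))
    score_table = pd.DataFrame(rows).sort_values("overlap_score").reset_index(drop=True)
    return finalists[0], score_table
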