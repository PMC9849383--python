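"""No-U-Turn Sampler (NUTS) over a differentiable log density.

A self-contained implementation of adaptive Hamiltonian Monte Carlo with
dynamic trajectory lengths: multinomial sampling over the doubling binary
tree, the classic u-turn termination criterion, dual-averaging step-size
adaptation toward a target acceptance statistic, and metric (mass-matrix)
estimation over expanding warmup windows.  The metric is either diagonal or
block-diagonal; hierarchical regression posteriors have strong correlations
*within* each individual's small parameter block, which a block metric
absorbs at negligible cost per leapfrog step.

The target is supplied as a single callable ``logp_and_grad(x) -> (float,
ndarray)`` returning the log density and its gradient; everything here is
plain NumPy.  Chains are seeded through ``numpy.random.Generator``, so
results are exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["NutsConfig", "NutsResult", "sample_nuts"]

MAX_DELTA_H = 1000.0  # energy error beyond which a transition is divergent


@dataclass(frozen=True)
class NutsConfig:
    draws: int = 200
    warmup: int = 500
    target_accept: float = 0.9
    max_treedepth: int = 10
    blocks: tuple[tuple[int, int], ...] | None = None  # (start, stop) index ranges


@dataclass
class NutsResult:
    """Draws and sampler statistics for one chain."""

    draws: np.ndarray  # (n_draws, dim)
    step_size: float
    accept_mean: float
    n_divergent: int
    n_max_depth: int
    logp: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# Metric (kinetic energy)
# ---------------------------------------------------------------------------

class _DiagMetric:
    """Euclidean metric with a diagonal inverse mass (posterior variances)."""

    def __init__(self, dim: int):
        self.var = np.ones(dim)
        self.sqrt_mass = np.ones(dim)

    def update(self, window: np.ndarray) -> None:
        n = window.shape[0]
        var = np.var(window, axis=0, ddof=1)
        var = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
        self.var = np.maximum(var, 1e-10)
        self.sqrt_mass = 1.0 / np.sqrt(self.var)

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.var * p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ (self.var * p))

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(self.var.shape[0]) * self.sqrt_mass


class _BlockMetric:
    """Block-diagonal inverse mass; same-size blocks are batched together."""

    def __init__(self, dim: int, blocks: Sequence[tuple[int, int]]):
        covered = sorted(blocks)
        pos = 0
        for start, stop in covered:
            if start != pos:
                raise ValueError("blocks must tile the dimension contiguously")
            pos = stop
        if pos != dim:
            raise ValueError("blocks must cover every dimension")
        self.dim = dim
        self.groups: list[dict] = []
        by_size: dict[int, list[int]] = {}
        for start, stop in covered:
            by_size.setdefault(stop - start, []).append(start)
        for size, starts in sorted(by_size.items()):
            idx = np.array([[s + k for k in range(size)] for s in starts])  # (nb, size)
            nb = len(starts)
            self.groups.append(
                {
                    "idx": idx,
                    "cov": np.tile(np.eye(size), (nb, 1, 1)),
                    "chol_prec_t": np.tile(np.eye(size), (nb, 1, 1)),
                }
            )

    def update(self, window: np.ndarray) -> None:
        n = window.shape[0]
        shrink = n / (n + 5.0)
        ridge = 1e-3 * (5.0 / (n + 5.0)) + 1e-10
        for grp in self.groups:
            xb = window[:, grp["idx"]]  # (n, nb, size)
            mean = xb.mean(axis=0)
            dev = xb - mean
            cov = np.einsum("nbi,nbj->bij", dev, dev) / (n - 1)
            size = cov.shape[-1]
            cov = shrink * cov + ridge * np.eye(size)
            grp["cov"] = cov
            # momentum p ~ N(0, Σ^{-1}); with Σ = L Lᵀ this is p = L^{-ᵀ} ξ
            chol = np.linalg.cholesky(cov)
            grp["chol_prec_t"] = np.linalg.inv(np.transpose(chol, (0, 2, 1)))

    def velocity(self, p: np.ndarray) -> np.ndarray:
        v = np.empty_like(p)
        for grp in self.groups:
            v[grp["idx"]] = np.einsum("bij,bj->bi", grp["cov"], p[grp["idx"]])
        return v

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ self.velocity(p))

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        xi = rng.standard_normal(self.dim)
        p = np.empty(self.dim)
        for grp in self.groups:
            p[grp["idx"]] = np.einsum("bij,bj->bi", grp["chol_prec_t"], xi[grp["idx"]])
        return p


# ---------------------------------------------------------------------------
# Hamiltonian dynamics and tree building
# ---------------------------------------------------------------------------

class _Hamiltonian:
    def __init__(self, logp_and_grad, metric):
        self.logp_and_grad = logp_and_grad
        self.metric = metric

    def leapfrog(self, x, p, g, eps):
        p_half = p + 0.5 * eps * g
        x_new = x + eps * self.metric.velocity(p_half)
        logp_new, g_new = self.logp_and_grad(x_new)
        p_new = p_half + 0.5 * eps * g_new
        return x_new, p_new, g_new, logp_new


class _Tree:
    """State of one (sub)trajectory during doubling."""

    __slots__ = ("x_minus", "p_minus", "g_minus", "x_plus", "p_plus", "g_plus",
                 "x_prop", "g_prop", "logp_prop", "log_weight", "turning",
                 "divergent", "sum_alpha", "n_alpha")

    def __init__(self, x, p, g, logp, log_weight, alpha):
        self.x_minus = self.x_plus = self.x_prop = x
        self.p_minus = self.p_plus = p
        self.g_minus = self.g_plus = self.g_prop = g
        self.logp_prop = logp
        self.log_weight = log_weight
        self.turning = False
        self.divergent = False
        self.sum_alpha = alpha
        self.n_alpha = 1


def _is_turning(metric, x_minus, p_minus, x_plus, p_plus) -> bool:
    dx = x_plus - x_minus
    return (dx @ metric.velocity(p_minus)) < 0 or (dx @ metric.velocity(p_plus)) < 0


def _build_tree(ham, x, p, g, logp, direction, depth, eps, h0, rng) -> _Tree:
    if depth == 0:
        x1, p1, g1, logp1 = ham.leapfrog(x, p, g, direction * eps)
        if not np.isfinite(logp1):
            logp1 = -np.inf
        h1 = -logp1 + ham.metric.kinetic(p1)
        delta = h1 - h0
        tree = _Tree(x1, p1, g1, logp1, -delta if np.isfinite(delta) else -np.inf,
                     min(1.0, float(np.exp(min(0.0, -delta)))))
        tree.divergent = not np.isfinite(delta) or delta > MAX_DELTA_H
        return tree

    first = _build_tree(ham, x, p, g, logp, direction, depth - 1, eps, h0, rng)
    if first.divergent or first.turning:
        return first
    if direction == 1:
        second = _build_tree(ham, first.x_plus, first.p_plus, first.g_plus,
                             first.logp_prop, direction, depth - 1, eps, h0, rng)
        first.x_plus, first.p_plus, first.g_plus = second.x_plus, second.p_plus, second.g_plus
    else:
        second = _build_tree(ham, first.x_minus, first.p_minus, first.g_minus,
                             first.logp_prop, direction, depth - 1, eps, h0, rng)
        first.x_minus, first.p_minus, first.g_minus = second.x_minus, second.p_minus, second.g_minus

    first.sum_alpha += second.sum_alpha
    first.n_alpha += second.n_alpha
    first.divergent = second.divergent
    if second.divergent:
        return first

    total = np.logaddexp(first.log_weight, second.log_weight)
    # multinomial sampling within the subtree
    if np.log(rng.uniform()) < second.log_weight - total:
        first.x_prop, first.g_prop, first.logp_prop = second.x_prop, second.g_prop, second.logp_prop
    first.log_weight = total
    first.turning = second.turning or _is_turning(
        ham.metric, first.x_minus, first.p_minus, first.x_plus, first.p_plus
    )
    return first


def _nuts_step(ham, x, g, logp, eps, max_depth, rng):
    p0 = ham.metric.sample_momentum(rng)
    h0 = -logp + ham.metric.kinetic(p0)
    tree = _Tree(x, p0, g, logp, 0.0, 1.0)
    tree.sum_alpha, tree.n_alpha = 0.0, 0
    divergent = False
    depth = 0
    while depth < max_depth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(ham, tree.x_plus, tree.p_plus, tree.g_plus,
                              tree.logp_prop, 1, depth, eps, h0, rng)
        else:
            sub = _build_tree(ham, tree.x_minus, tree.p_minus, tree.g_minus,
                              tree.logp_prop, -1, depth, eps, h0, rng)
        tree.sum_alpha += sub.sum_alpha
        tree.n_alpha += sub.n_alpha
        if sub.divergent:
            divergent = True
            break
        if sub.turning:
            break
        # progressive (biased) sampling between the old tree and the new subtree
        if np.log(rng.uniform()) < sub.log_weight - tree.log_weight:
            tree.x_prop, tree.g_prop, tree.logp_prop = sub.x_prop, sub.g_prop, sub.logp_prop
        tree.log_weight = np.logaddexp(tree.log_weight, sub.log_weight)
        if direction == 1:
            tree.x_plus, tree.p_plus, tree.g_plus = sub.x_plus, sub.p_plus, sub.g_plus
        else:
            tree.x_minus, tree.p_minus, tree.g_minus = sub.x_minus, sub.p_minus, sub.g_minus
        if _is_turning(ham.metric, tree.x_minus, tree.p_minus, tree.x_plus, tree.p_plus):
            depth += 1
            break
        depth += 1
    alpha = tree.sum_alpha / max(tree.n_alpha, 1)
    return tree.x_prop, tree.g_prop, tree.logp_prop, alpha, divergent, depth >= max_depth


def _find_initial_step(ham, x, g, logp, rng) -> float:
    eps = 0.1
    p0 = ham.metric.sample_momentum(rng)
    h0 = -logp + ham.metric.kinetic(p0)
    x1, p1, _, logp1 = ham.leapfrog(x, p0, g, eps)
    h1 = -logp1 + ham.metric.kinetic(p1) if np.isfinite(logp1) else np.inf
    direction = 1 if (h0 - h1) > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        x1, p1, _, logp1 = ham.leapfrog(x, p0, g, eps)
        h1 = -logp1 + ham.metric.kinetic(p1) if np.isfinite(logp1) else np.inf
        accept = h0 - h1
        if (direction == 1 and accept <= np.log(0.5)) or (
            direction == -1 and accept >= np.log(0.5)
        ):
            break
    return eps


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target acceptance."""

    def __init__(self, eps0, target, gamma=0.05, t0=10.0, kappa=0.75):
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.restart(eps0)

    def restart(self, eps0):
        self.mu = np.log(10.0 * eps0)
        self.log_eps = np.log(eps0)
        self.log_eps_bar = np.log(eps0)
        self.h_bar = 0.0
        self.count = 0

    def update(self, alpha):
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - alpha)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m**-self.kappa
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar

    @property
    def eps(self):
        return float(np.exp(self.log_eps))

    @property
    def eps_final(self):
        return float(np.exp(self.log_eps_bar))


def _warmup_schedule(warmup: int) -> list[int]:
    """Iteration counts at which the metric is re-estimated."""
    if warmup < 100:
        return [warmup // 2]
    fast_init = max(25, int(0.15 * warmup))
    term = max(25, int(0.1 * warmup))
    points, start, width = [], fast_init, 25
    while start + width < warmup - term:
        points.append(start + width)
        start += width
        width *= 2
    points.append(warmup - term)
    return points


def sample_nuts(
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    config: NutsConfig,
    rng: np.random.Generator,
) -> NutsResult:
    """Run one NUTS chain: warmup with adaptation, then retained draws."""
    x = np.asarray(x0, dtype=float).copy()
    dim = x.shape[0]
    logp, g = logp_and_grad(x)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    metric = _BlockMetric(dim, config.blocks) if config.blocks else _DiagMetric(dim)
    ham = _Hamiltonian(logp_and_grad, metric)
    eps = _find_initial_step(ham, x, g, logp, rng)
    da = _DualAveraging(eps, config.target_accept)

    mass_updates = set(_warmup_schedule(config.warmup))
    window: list[np.ndarray] = []

    n_div = 0
    n_maxdepth = 0
    accepts = []
    draws = np.empty((config.draws, dim))
    logps = np.empty(config.draws)

    for it in range(config.warmup + config.draws):
        in_warmup = it < config.warmup
        step = da.eps if in_warmup else da.eps_final
        x, g, logp, alpha, divergent, hit_max = _nuts_step(
            ham, x, g, logp, step, config.max_treedepth, rng
        )
        if in_warmup:
            da.update(alpha)
            window.append(x.copy())
            if it + 1 in mass_updates and len(window) > 5:
                metric.update(np.asarray(window))
                window.clear()
                da.restart(da.eps)
        else:
            idx = it - config.warmup
            draws[idx] = x
            logps[idx] = logp
            accepts.append(alpha)
            n_div += int(divergent)
            n_maxdepth += int(hit_max)

    return NutsResult(
        draws=draws,
        step_size=da.eps_final,
        accept_mean=float(np.mean(accepts)) if accepts else float("nan"),
        n_divergent=n_div,
        n_max_depth=n_maxdepth,
        logp=logps,
    )
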