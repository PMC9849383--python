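"""Moore-type age-performance curves.

The Moore model describes the age-performance relationship as a sum of two
exponential laws: one term for the progression phase and one for the decline
phase, meeting at the performance peak.  Two orientations are supported:

* ``minimize`` — scores where lower is better (e.g. alpine-skiing race
  points).  The curve is the sign-adjusted form ``p(t) = a·e^{-b·t} + c·e^{d·t}``,
  U-shaped with an interior minimum.
* ``maximize`` — the classical form for maximized performances,
  ``p(t) = a·(1 - e^{-b·t}) + c·(1 - e^{d·t})``, an inverted-U with an
  interior maximum.

Both orientations share the same extremum location
``t* = ln(a·b / (c·d)) / (b + d)`` since the two forms differ by an affine
reflection.  All functions here operate on the *standardized* age scale; the
curves module destandardizes to raw years and points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = ["MooreParams", "IndividualParams", "evaluate", "derivative", "peak"]

Orientation = Literal["minimize", "maximize"]


@dataclass(frozen=True)
class MooreParams:
    """One quadruplet (a, b, c, d) defining a growth/decline curve.

    ``a`` and ``c`` are dimensionless amplitudes of the decline and growth
    terms; ``b`` and ``d`` are rates per standardized-age unit.  All four must
    be strictly positive for the curve to have a well-defined interior
    extremum.
    """

    a: float
    b: float
    c: float
    d: float
    orientation: Orientation = "minimize"

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.d > 0):
            raise ValueError(f"rates must be positive, got b={self.b}, d={self.d}")
        if self.orientation not in ("minimize", "maximize"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def quadruplet(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def as_array(self) -> np.ndarray:
        return np.array(self.quadruplet, dtype=float)


@dataclass(frozen=True)
class IndividualParams:
    """Fixed effects plus one individual's additive offsets.

    The effective quadruplet ``(a+a_i, b+b_i, c+c_i, d+d_i)`` must itself be a
    valid :class:`MooreParams` for every retained posterior draw.
    """

    base: MooreParams
    offsets: tuple[float, float, float, float]

    def effective(self) -> MooreParams:
        a_i, b_i, c_i, d_i = self.offsets
        return replace(
            self.base,
            a=self.base.a + a_i,
            b=self.base.b + b_i,
            c=self.base.c + c_i,
            d=self.base.d + d_i,
        )


def _split(params: MooreParams | np.ndarray) -> tuple:
    """(a, b, c, d, orientation); array input gives column vectors for broadcasting."""
    if isinstance(params, MooreParams):
        return (*params.quadruplet, params.orientation)
    arr = np.asarray(params, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("parameter array must have shape (n, 4)")
    a, b, c, d = (arr[:, k][:, None] for k in range(4))
    return a, b, c, d, "minimize"


def evaluate(params: MooreParams | np.ndarray, t: np.ndarray | float):
    """Curve value at standardized age(s) ``t``.

    ``params`` may be a single :class:`MooreParams` (result broadcasts with
    ``t``) or an ``(n, 4)`` array of quadruplets in the minimized orientation,
    giving an ``(n, len(t))`` matrix.
    """
    a, b, c, d, orientation = _split(params)
    t = np.asarray(t, dtype=float)
    decline = a * np.exp(-b * t)
    growth = c * np.exp(d * t)
    out = decline + growth if orientation == "minimize" else a + c - decline - growth
    return float(out) if out.ndim == 0 else out


def derivative(params: MooreParams | np.ndarray, t: np.ndarray | float):
    """Slope ``dp/dt`` at standardized age(s) ``t``.

    For the minimized form this is ``-a·b·e^{-b·t} + c·d·e^{d·t}``; the
    maximized form is its negation.
    """
    a, b, c, d, orientation = _split(params)
    t = np.asarray(t, dtype=float)
    slope = -a * b * np.exp(-b * t) + c * d * np.exp(d * t)
    if orientation == "maximize":
        slope = -slope
    return float(slope) if slope.ndim == 0 else slope


def peak(params: MooreParams) -> tuple[float, float]:
    """Location and value of the curve's interior extremum.

    Closed form ``t* = ln(a·b / (c·d)) / (b + d)``: the argmin of the
    minimized form and, identically, the argmax of the maximized form.
    Returns ``(t*, p(t*))`` on the standardized scale.
    """
    prod_decline = params.a * params.b
    prod_growth = params.c * params.d
    if not (prod_decline > 0 and prod_growth > 0):
        raise ValueError(
            "no interior peak: need a·b > 0 and c·d > 0, got "
            f"a·b={prod_decline}, c·d={prod_growth}"
        )
    t_star = np.log(prod_decline / prod_growth) / (params.b + params.d)
    return float(t_star), float(evaluate(params, t_star))


def peak_ages(quadruplets: np.ndarray) -> np.ndarray:
    """Vectorized ``t*`` for an ``(n, 4)`` array of positive quadruplets.

    Rows whose amplitude products are non-positive yield ``nan`` (no interior
    peak) rather than raising, so ensemble summaries can count exclusions.
    """
    q = np.asarray(quadruplets, dtype=float)
    a, b, c, d = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            (a * b > 0) & (c * d > 0) & (b + d > 0),
            np.log(a * b / (c * d)) / (b + d),
            np.nan,
        )
    return t
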