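"""Closed-form solutions of the four constant-pressure blocking filtration laws.

Under constant transmembrane pressure, flux decline by membrane fouling is
classically described by a single characteristic ODE,

    d2t/dv2 = k (dt/dv)^n,

where ``v`` is the cumulative filtrate volume per unit membrane area (m) and
the blocking index ``n`` selects the fouling mechanism:

=================  =====  =====================  ===============
model              n      blocking constant      units of k
=================  =====  =====================  ===============
cake filtration    0      k_c                    m^-2 s
intermediate       1      k_i                    m^-1
standard           1.5    k_s                    m^-1
complete           2      k_b                    s^-1
=================  =====  =====================  ===============

This module provides the closed-form v(t) and J(t) = dv/dt for each law and
an estimator of the blocking index from a measured curve via the log-log
derivative regression implied by the characteristic ODE.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .curves import FiltrationCurve

__all__ = [
    "BlockingModel",
    "ModelParams",
    "BLOCKING_INDEX",
    "CONSTANT_UNITS",
    "volume",
    "flux",
    "estimate_blocking_index",
    "NoBlockingSignal",
]


class BlockingModel(str, Enum):
    """The four constant-pressure blocking filtration laws."""

    CAKE = "cake"
    INTERMEDIATE = "intermediate"
    STANDARD = "standard"
    COMPLETE = "complete"

    @classmethod
    def coerce(cls, value: "BlockingModel | str") -> "BlockingModel":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            names = ", ".join(m.value for m in cls)
            raise ValueError(f"unknown blocking model {value!r}; expected one of {names}")


#: Blocking index n of each law in d2t/dv2 = k (dt/dv)^n.
BLOCKING_INDEX: dict[BlockingModel, float] = {
    BlockingModel.CAKE: 0.0,
    BlockingModel.INTERMEDIATE: 1.0,
    BlockingModel.STANDARD: 1.5,
    BlockingModel.COMPLETE: 2.0,
}

#: Units of the blocking constant k for each law.
CONSTANT_UNITS: dict[BlockingModel, str] = {
    BlockingModel.CAKE: "m^-2 s",
    BlockingModel.INTERMEDIATE: "m^-1",
    BlockingModel.STANDARD: "m^-1",
    BlockingModel.COMPLETE: "s^-1",
}


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one blocking law: initial flux and blocking constant.

    ``j0`` is the initial filtration rate J_0 (m/s, > 0); ``k`` is the
    blocking constant in the units of the chosen law (>= 0; k = 0 is the
    no-fouling limit where v(t) = J_0 t for every model).
    """

    j0: float
    k: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.j0) or self.j0 <= 0:
            raise ValueError(f"j0 must be finite and > 0, got {self.j0}")
        if not np.isfinite(self.k) or self.k < 0:
            raise ValueError(f"k must be finite and >= 0, got {self.k}")


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return t


def volume(model: BlockingModel | str, params: ModelParams, t) -> np.ndarray | float:
    """Cumulative filtrate volume per unit area v(t) (m) for one blocking law.

    All four closed forms vanish at t = 0 and reduce to ``j0 * t`` in the
    k -> 0 limit; that limit is taken analytically (no division by k).
    """
    model = BlockingModel.coerce(model)
    t = _check_time(t)
    j0, k = params.j0, params.k
    if model is BlockingModel.CAKE:
        # v = (sqrt(1 + 2 k j0^2 t) - 1) / (k j0), rationalized for small k
        x = 2.0 * k * j0 * j0 * t
        v = 2.0 * j0 * t / (1.0 + np.sqrt(1.0 + x))
    elif model is BlockingModel.INTERMEDIATE:
        v = np.log1p(k * j0 * t) / k if k > 0 else j0 * t
    elif model is BlockingModel.STANDARD:
        # v = 1 / (k/2 + 1/(j0 t)), written without the 1/t singularity
        v = j0 * t / (1.0 + 0.5 * k * j0 * t)
    else:  # COMPLETE
        v = j0 * (-np.expm1(-k * t)) / k if k > 0 else j0 * t
    return v


def flux(model: BlockingModel | str, params: ModelParams, t) -> np.ndarray | float:
    """Instantaneous filtration rate J(t) = dv/dt (m/s) for one blocking law.

    J(0) = j0 for every model; J is strictly decreasing in t when k > 0.
    """
    model = BlockingModel.coerce(model)
    t = _check_time(t)
    j0, k = params.j0, params.k
    if model is BlockingModel.CAKE:
        return j0 / np.sqrt(1.0 + 2.0 * k * j0 * j0 * t)
    if model is BlockingModel.INTERMEDIATE:
        return j0 / (1.0 + k * j0 * t)
    if model is BlockingModel.STANDARD:
        return j0 / (1.0 + 0.5 * k * j0 * t) ** 2
    return j0 * np.exp(-k * t)


class NoBlockingSignal(ValueError):
    """Raised when a curve carries no measurable curvature (linear v(t))."""


def estimate_blocking_index(
    curve: FiltrationCurve,
    *,
    grid_size: int | None = None,
    tail_trim: float = 0.10,
) -> float:
    """Estimate the blocking index n from a measured curve.

    The characteristic ODE ``d2t/dv2 = k (dt/dv)^n`` makes n the slope of
    ln(d2t/dv2) against ln(dt/dv).  Because both derivatives are taken with
    respect to v, the curve is first resampled onto a uniform v grid (linear
    interpolation of t against v), then differentiated twice by 3-point
    central differences; the two boundary points of each derivative are
    discarded, as is a short tail fraction of the v range where t(v)
    steepens and the finite-difference truncation error concentrates.

    Parameters
    ----------
    curve :
        Measured curve with at least 20 points and strictly increasing v.
    grid_size :
        Number of uniform v-grid nodes; by default scaled to the data so the
        grid is a few times coarser than the widest raw v spacing.
    tail_trim :
        Fraction of the v range discarded from the high-v end before the
        regression.

    Returns
    -------
    float
        The regression slope, an estimate of n.

    Raises
    ------
    NoBlockingSignal
        If dt/dv is constant to within numerical precision (k = 0 regime):
        the second derivative is pure noise and no index is defined.
    """
    t = curve.times
    v = curve.v
    if len(curve) < 20:
        raise ValueError("need at least 20 points to estimate the blocking index")
    if np.any(np.diff(v) <= 0):
        raise ValueError("v must be strictly increasing to estimate the blocking index")

    if grid_size is None:
        # Grid a few times coarser than the widest raw spacing keeps the
        # linear-interpolation error well below the central-difference signal.
        dv_max = float(np.max(np.diff(v)))
        span = float(v[-1] - v[0])
        grid_size = int(np.clip(span / (3.0 * dv_max), 20, 200))
    if grid_size < 7:
        raise ValueError("grid_size too small for the 3-point difference stencil")

    vg = np.linspace(v[0], v[-1], grid_size)
    tg = np.interp(vg, v, t)
    h = vg[1] - vg[0]

    u = (tg[2:] - tg[:-2]) / (2.0 * h)          # dt/dv on nodes 1..m-2
    w = (tg[2:] - 2.0 * tg[1:-1] + tg[:-2]) / h**2  # d2t/dv2, same nodes
    vc = vg[1:-1]
    # discard the two boundary points of each derivative
    u, w, vc = u[2:-2], w[2:-2], vc[2:-2]

    # Flat dt/dv means no curvature to regress on.
    u_rel_span = (np.max(u) - np.min(u)) / np.mean(u)
    if u_rel_span < 1e-6:
        raise NoBlockingSignal(
            "no blocking signal: dt/dv is constant (v(t) is linear, k = 0)"
        )

    keep = vc <= v[-1] - tail_trim * (v[-1] - v[0])
    u, w = u[keep], w[keep]
    good = (u > 0) & (w > 0)
    if np.count_nonzero(good) < 5:
        raise NoBlockingSignal("no blocking signal: second derivative not positive")
    res = stats.linregress(np.log(u[good]), np.log(w[good]))
    return float(res.slope)
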