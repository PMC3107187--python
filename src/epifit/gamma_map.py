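"""Unimodal gamma-shaped phenotype-to-fitness curve.

The curve is

    f(z) = shift + height * g(z) / g(z_mode),   g(z) = z**(shape-1) * exp(-z/scale)

with mode ``z_mode = (shape - 1) * scale``, so the peak fitness is exactly
``shift + height`` and ``f(0) = shift``.  This is a curve, not a
probability density: the normalization makes ``height`` the peak height
above the floor.  The phenotype scale is arbitrary — rescaling ``scale``
and all phenotypes by a common factor leaves the curve unchanged — so
fitting fixes ``scale = 1`` by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq

from .errors import InfeasibleFitnessError

#: absolute fitness tolerance used by :func:`invert`
INVERT_TOL = 1e-10


@dataclass(frozen=True)
class GammaMapParams:
    """Curve parameters: shape > 1, scale > 0, height > 0, shift real."""

    shape: float
    scale: float
    height: float
    shift: float = 0.0

    def __post_init__(self):
        if not self.shape > 1.0:
            raise ValueError(f"shape must be > 1 (interior optimum), got {self.shape}")
        if not self.scale > 0.0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if not self.height > 0.0:
            raise ValueError(f"height must be > 0, got {self.height}")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "GammaMapParams":
        return cls(**{k: d[k] for k in ("shape", "scale", "height", "shift")})


def mode(params: GammaMapParams) -> float:
    """Phenotype at which the curve peaks, ``(shape - 1) * scale``."""
    return (params.shape - 1.0) * params.scale


def evaluate(params: GammaMapParams, z):
    """Fitness at phenotype(s) ``z >= 0``; peaks at ``shift + height``.

    Accepts scalars or arrays (vectorized).  Computed in a normalized form
    ``(z/z*)**(shape-1) * exp((z* - z)/scale)`` that is stable for large z.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("phenotype z must be nonnegative")
    zstar = mode(params)
    with np.errstate(divide="ignore"):
        # z = 0 gives ratio 0 for shape > 1
        ratio = np.where(
            z > 0,
            np.exp(
                (params.shape - 1.0) * np.log(np.where(z > 0, z, 1.0) / zstar)
                + (zstar - z) / params.scale
            ),
            0.0,
        )
    out = params.shift + params.height * ratio
    return float(out) if out.ndim == 0 else out


def invert(params: GammaMapParams, w: float) -> tuple[float, float]:
    """Both phenotypes with fitness ``w``: one on each side of the peak.

    Returns ``(z_low, z_high)`` with ``z_low <= z_mode <= z_high``; the
    peak fitness returns the double root ``(z_mode, z_mode)``.

    Raises
    ------
    InfeasibleFitnessError
        If ``w`` exceeds the peak ``shift + height`` or does not exceed
        the floor ``shift``.
    """
    peak = params.shift + params.height
    if w > peak:
        raise InfeasibleFitnessError(
            f"fitness {w} exceeds the curve peak {peak}"
        )
    if w <= params.shift:
        raise InfeasibleFitnessError(
            f"fitness {w} does not exceed the curve floor {params.shift}"
        )
    zstar = mode(params)
    if w == peak:
        return (zstar, zstar)

    # solve phi(z) = log[(f(z) - shift) / (w - shift)] = 0; phi is smooth
    # through the spike at z -> 0 that sharp curves (shape near 1) develop
    target = math.log((w - params.shift) / params.height)
    am1 = params.shape - 1.0

    def phi(z):
        return am1 * math.log(z / zstar) + (zstar - z) / params.scale - target

    # rising limb, solved in log-phenotype space for conditioning
    def phi_log(u):
        return phi(math.exp(u))

    # start below the root (phi < 0 there) and bracket against the mode;
    # for shape very near 1 the low root can underflow double precision
    u_min = math.log(1e-290)
    u_lo = max(u_min, math.log(zstar) + (target - 1.0) / am1)
    while phi_log(u_lo) > 0:
        if u_lo <= u_min:
            raise InfeasibleFitnessError(
                f"low-branch phenotype for fitness {w} underflows (shape too close to 1)"
            )
        u_lo = max(u_min, u_lo - max(1.0, 2.0 * abs(target) / am1))
    z_low = math.exp(brentq(phi_log, u_lo, math.log(zstar), xtol=1e-14, rtol=8.9e-16))
    # falling limb: grow the upper bracket geometrically until phi < 0
    hi = 2.0 * zstar
    while phi(hi) > 0:
        hi *= 2.0
    z_high = brentq(phi, zstar, hi, xtol=1e-14, rtol=8.9e-16)
    for z in (z_low, z_high):
        if abs(evaluate(params, z) - w) > max(INVERT_TOL, 1e-6 * abs(w - params.shift)):
            raise InfeasibleFitnessError(f"root refinement failed at w={w}")
    return (float(z_low), float(z_high))
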