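"""Simulated deviation-from-additivity distributions and AIC comparison.

Two generative models are simulated over the same 18-pair design:

* the fitted gamma map with additive latent phenotypes — single-mutant
  fitnesses drawn uniformly between the observed extremes are inverted
  through the curve (random side of the optimum), doubles take the sum of
  phenotypes, and normal assay error is added; and
* a two-dimensional geometric model with a Gaussian phenotype-fitness
  map — mutant phenotype points are drawn uniformly inside the fitness
  contour of the smallest observed effect, doubles arise by vector
  addition of displacements from the wild type.

Observed deviations are scored against each model by histogram-density
likelihood; models are compared by AIC = 2k - 2 lnL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .gamma_map import GammaMapParams, evaluate, invert
from .synthetic_data import DEFAULT_PAIRS

K_GAMMA = 14  # 9 imputed phenotypes + 4 curve parameters + 1 error parameter
K_GEOMETRIC = 2


@dataclass(frozen=True)
class EffectDistributionConfig:
    """Distribution of single-mutant fitness values.

    Generalized Pareto with shape ``kappa``; ``kappa = -1`` is the uniform
    distribution on ``[lower, upper]``.  Bounds are the smallest and
    largest observed single-mutant fitnesses.
    """

    lower: float
    upper: float
    kappa: float = -1.0

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ConfigurationError("lower bound must be below upper bound")
        if self.kappa >= 0:
            raise ConfigurationError(
                "kappa >= 0 has unbounded support; a finite upper bound "
                "requires kappa < 0"
            )

    def draw(self, m: int, rng: np.random.Generator) -> np.ndarray:
        """``m`` iid draws; uniform when ``kappa = -1``."""
        span = self.upper - self.lower
        if self.kappa == -1.0:
            return self.lower + rng.uniform(0.0, span, size=m)
        # GPD with negative shape has support [0, -sigma/kappa]; choose the
        # scale so the support matches [0, span]
        sigma = -self.kappa * span
        u = rng.uniform(0.0, 1.0, size=m)
        draws = sigma / self.kappa * (np.power(1.0 - u, -self.kappa) - 1.0)
        return self.lower + draws


def pair_index(pairs: Sequence[str] = DEFAULT_PAIRS) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (into the sorted singles) for a two-letter pair pattern."""
    singles = sorted({c for p in pairs for c in p})
    col = {g: i for i, g in enumerate(singles)}
    ia = np.array([col[p[0]] for p in pairs])
    ib = np.array([col[p[1]] for p in pairs])
    return ia, ib


@dataclass(frozen=True)
class EpsilonDistribution:
    """Simulated deviations from additivity, one row per replicate."""

    model: str
    epsilons: np.ndarray  # (reps, n_pairs)
    pair_labels: tuple[str, ...]
    n_redraws: int = 0

    @property
    def reps(self) -> int:
        return self.epsilons.shape[0]

    def pooled(self) -> np.ndarray:
        return self.epsilons.ravel()


def simulate_gamma_epsilons(
    params: GammaMapParams,
    wt_fitness: float,
    error_sd: float,
    config: EffectDistributionConfig,
    pairs: Sequence[str] = DEFAULT_PAIRS,
    reps: int = 1000,
    seed: int = 0,
) -> EpsilonDistribution:
    """Deviations from additivity under the fitted gamma map.

    Per replicate: draw 9 single-mutant fitnesses from ``config``
    (redrawing values above the curve peak), invert each to a phenotype on
    a fair-coin side of the optimum, form the 18 doubles by phenotype
    addition, map back to fitness with normal error of SD ``error_sd``,
    and compute epsilon on the effect scale.
    """
    rng = np.random.default_rng(seed)
    peak = params.shift + params.height
    if config.upper > peak:
        # feasible draws exist only below the peak; redraw policy handles the
        # tail, but a bound entirely above the peak is a config error
        if config.lower >= peak:
            raise ConfigurationError("effect distribution lies above the curve peak")
    ia, ib = pair_index(pairs)
    m = len({c for p in pairs for c in p})
    eps = np.empty((reps, len(pairs)))
    n_redraws = 0
    n_drawn = 0
    for r in range(reps):
        w = config.draw(m, rng)
        n_drawn += m
        bad = w >= peak
        while bad.any():
            n_redraws += int(bad.sum())
            n_drawn += int(bad.sum())
            w[bad] = config.draw(int(bad.sum()), rng)
            bad = w >= peak
            if n_redraws > 0.5 * max(n_drawn, 1) and n_drawn > 100:
                raise ConfigurationError(
                    "more than half of the drawn fitnesses exceed the curve peak"
                )
        z = np.empty(m)
        high = rng.random(m) < 0.5
        for i in range(m):
            z_lo, z_hi = invert(params, float(w[i]))
            z[i] = z_hi if high[i] else z_lo
        w_double = evaluate(params, z[ia] + z[ib])
        if error_sd > 0:
            w_double = w_double + rng.normal(0.0, error_sd, size=len(pairs))
        s_single = w - wt_fitness
        s_double = w_double - wt_fitness
        eps[r] = s_double - s_single[ia] - s_single[ib]
    return EpsilonDistribution("gamma", eps, tuple(pairs), n_redraws)


@dataclass(frozen=True)
class GeometricModelConfig:
    """Two-dimensional geometric model with a Gaussian fitness map.

    The wild type sits one phenotypic unit from the optimum.  The map
    ``w(p) = floor + (w_max - floor) * exp(-c * |p|**2)`` satisfies
    ``w(0) = w_max`` and ``w(1) = w_wt`` exactly via
    ``c = ln[(w_max - floor) / (w_wt - floor)]`` and tends to ``floor`` far
    from the optimum.
    """

    w_max: float
    w_wt: float
    floor: float
    n_dim: int = 2

    def __post_init__(self):
        if not self.floor < self.w_wt < self.w_max:
            raise ConfigurationError("need floor < w_wt < w_max")

    @property
    def decay(self) -> float:
        return math.log((self.w_max - self.floor) / (self.w_wt - self.floor))

    def fitness(self, points: np.ndarray) -> np.ndarray:
        """Fitness at phenotype points of shape (..., n_dim)."""
        r2 = np.sum(np.asarray(points, dtype=float) ** 2, axis=-1)
        return self.floor + (self.w_max - self.floor) * np.exp(-self.decay * r2)

    def contour_radius(self, w: float) -> float:
        """Distance from the optimum at which fitness equals ``w``."""
        if not self.floor < w <= self.w_max:
            raise ConfigurationError(f"fitness {w} outside (floor, w_max]")
        return math.sqrt(
            math.log((self.w_max - self.floor) / (w - self.floor)) / self.decay
        )


def simulate_geometric_epsilons(
    config: GeometricModelConfig,
    w_lowest_single: float,
    pairs: Sequence[str] = DEFAULT_PAIRS,
    reps: int = 1000,
    seed: int = 0,
) -> EpsilonDistribution:
    """Deviations from additivity under the geometric model.

    Per replicate: place the wild type at distance 1 from the optimum,
    draw 9 mutant phenotype points uniformly inside the circle where
    fitness equals the smallest observed single-mutant fitness, form
    doubles by adding displacement vectors, and compute epsilon on the
    effect scale.
    """
    if w_lowest_single > config.w_max:
        raise ConfigurationError("smallest-effect fitness exceeds the peak")
    rng = np.random.default_rng(seed)
    radius = config.contour_radius(w_lowest_single)
    ia, ib = pair_index(pairs)
    m = len({c for p in pairs for c in p})
    wt = np.zeros(config.n_dim)
    wt[0] = 1.0
    w_wt = float(config.fitness(wt))
    eps = np.empty((reps, len(pairs)))
    for r in range(reps):
        points = _uniform_in_ball(m, radius, config.n_dim, rng)
        disp = points - wt
        doubles = wt + disp[ia] + disp[ib]
        s_single = config.fitness(points) - w_wt
        s_double = config.fitness(doubles) - w_wt
        eps[r] = s_double - s_single[ia] - s_single[ib]
    return EpsilonDistribution("geometric", eps, tuple(pairs))


def _uniform_in_ball(
    m: int, radius: float, n_dim: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection sampling from the bounding box of the ball."""
    out = np.empty((m, n_dim))
    got = 0
    while got < m:
        cand = rng.uniform(-radius, radius, size=(2 * (m - got) + 8, n_dim))
        keep = cand[np.sum(cand**2, axis=1) <= radius**2]
        take = min(len(keep), m - got)
        out[got : got + take] = keep[:take]
        got += take
    return out


@dataclass(frozen=True)
class HistogramLoglik:
    loglik: float
    n_floored: int
    bin_width: float
    bin_edges: np.ndarray = field(repr=False, default=None)


def histogram_loglik(
    distribution: EpsilonDistribution, observed: Sequence[float]
) -> HistogramLoglik:
    """Log-likelihood of observed epsilons under the simulated density.

    The pooled simulated values are binned (Freedman-Diaconis) into a
    histogram density; each observed value contributes the log of its
    bin's density.  Empty bins and values outside the histogram range use
    a floor density of ``1 / (n_simulated * bin_width)`` (one phantom
    count), and each such event is counted.
    """
    pooled = distribution.pooled()
    if pooled.size < 1000:
        raise ValueError("need at least 1000 pooled simulated values")
    edges = np.histogram_bin_edges(pooled, bins="fd")
    counts, edges = np.histogram(pooled, bins=edges)
    width = float(edges[1] - edges[0])
    total = pooled.size
    density = counts / (total * width)
    floor = 1.0 / (total * width)
    lnl = 0.0
    n_floored = 0
    for x in observed:
        idx = np.searchsorted(edges, x, side="right") - 1
        if x == edges[-1]:  # exactly at the rightmost edge: last bin
            idx = len(counts) - 1
        if 0 <= idx < len(counts) and density[idx] > 0:
            lnl += math.log(density[idx])
        else:
            lnl += math.log(floor)
            n_floored += 1
    return HistogramLoglik(lnl, n_floored, width, edges)


@dataclass(frozen=True)
class ModelComparisonResult:
    lnl_gamma: float
    lnl_geometric: float
    k_gamma: int
    k_geometric: int
    aic_gamma: float
    aic_geometric: float
    delta_aic: float  # aic_gamma - aic_geometric
    verdict: str


def aic_compare(
    lnl_gamma: float,
    lnl_geometric: float,
    k_gamma: int = K_GAMMA,
    k_geometric: int = K_GEOMETRIC,
) -> ModelComparisonResult:
    """AIC = 2k - 2 lnL for both models, with a qualitative verdict."""
    if not (math.isfinite(lnl_gamma) and math.isfinite(lnl_geometric)):
        raise ValueError("log-likelihoods must be finite")
    aic_g = 2.0 * k_gamma - 2.0 * lnl_gamma
    aic_m = 2.0 * k_geometric - 2.0 * lnl_geometric
    delta = aic_g - aic_m
    if abs(delta) < 2.0:
        verdict = "models explain the data about equally well"
    elif delta < 0:
        verdict = "gamma model preferred"
    else:
        verdict = "geometric model preferred"
    return ModelComparisonResult(
        lnl_gamma, lnl_geometric, k_gamma, k_geometric, aic_g, aic_m, delta, verdict
    )


def wild_type_phenotype(params: GammaMapParams, wt_fitness: float) -> float:
    """Fitted wild-type position on the curve (low branch of the optimum)."""
    z_lo, _ = invert(params, wt_fitness)
    return z_lo


def mean_epsilon_se(distribution: EpsilonDistribution) -> tuple[float, float]:
    """Monte-Carlo mean of pooled epsilons and its standard error."""
    pooled = distribution.pooled()
    return float(pooled.mean()), float(pooled.std(ddof=1) / math.sqrt(pooled.size))


# re-exported for callers configuring simulations
__all__ = [
    "K_GAMMA",
    "K_GEOMETRIC",
    "EffectDistributionConfig",
    "EpsilonDistribution",
    "GeometricModelConfig",
    "HistogramLoglik",
    "ModelComparisonResult",
    "aic_compare",
    "histogram_loglik",
    "mean_epsilon_se",
    "pair_index",
    "simulate_gamma_epsilons",
    "simulate_geometric_epsilons",
    "wild_type_phenotype",
]
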