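"""Fit the gamma-shaped fitness map by iterative phenotype imputation + NLS.

Single-mutant phenotypes are latent.  Each outer iteration (i) inverts the
current curve at every single-mutant fitness, giving two candidate
phenotypes per single (one on each side of the peak), (ii) picks the branch
combination minimizing the squared double-mutant residuals under phenotype
additivity ``z_ij = z_i + z_j``, then (iii) refits the curve parameters by
bounded nonlinear least squares with the phenotypes held fixed.  Iteration
stops when neither parameters nor phenotypes change.

The curve floor (``shift``) is not optimized: it is fixed beforehand to the
largest integer strictly below every observed fitness, and fitting operates
on shifted fitnesses.  The phenotype scale is arbitrary (a rescaling of
``scale`` absorbs it), so ``scale`` is frozen at 1 unless ``free_scale``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares, minimize

from .assay_io import EffectTable
from .errors import InfeasibleFitnessError, InsufficientDataError
from .gamma_map import GammaMapParams, evaluate, invert, mode

N_CURVE_PARAMS = 3  # shape, height and (frozen or free) scale; shift is fixed

F_DIST_CAVEAT = (
    "p-value from the F distribution; the reference distribution is "
    "approximate because the model is nonlinear in its parameters"
)


@dataclass(frozen=True)
class FitInput:
    """Mean-level fitness data for one wild type, singles and doubles."""

    wild_type_label: str
    wt_fitness: float
    single_fitness: dict[str, float]
    double_fitness: dict[str, float]
    pairs: dict[str, tuple[str, str]]

    def __post_init__(self):
        if len(self.single_fitness) < 2:
            raise InsufficientDataError("need at least 2 single mutants")
        for d, (a, b) in self.pairs.items():
            if a not in self.single_fitness or b not in self.single_fitness:
                raise ValueError(f"double {d} references unknown singles ({a}, {b})")
            if d not in self.double_fitness:
                raise ValueError(f"double {d} has no fitness value")

    @property
    def single_labels(self) -> list[str]:
        return sorted(self.single_fitness)

    @property
    def double_labels(self) -> list[str]:
        return sorted(self.double_fitness)

    @property
    def n_genotypes(self) -> int:
        """Singles + doubles entering the least squares (wild type excluded)."""
        return len(self.single_fitness) + len(self.double_fitness)

    @classmethod
    def from_effect_table(cls, effects: EffectTable, wt_fitness: float | None = None) -> "FitInput":
        wt = effects.wild_type_label
        if wt_fitness is None:
            wt_fitness = effects.mean_fitness[wt]
        mean = effects.mean_fitness or {
            g: wt_fitness + s for g, s in effects.effects.items()
        }
        return cls(
            wild_type_label=wt,
            wt_fitness=wt_fitness,
            single_fitness={g: mean[g] for g in effects.singles},
            double_fitness={g: mean[g] for g in effects.doubles},
            pairs=dict(effects.pairs),
        )

    def drop_double(self, label: str) -> "FitInput":
        """Copy without one double mutant (for leave-one-out)."""
        if label not in self.double_fitness:
            raise KeyError(label)
        return replace(
            self,
            double_fitness={k: v for k, v in self.double_fitness.items() if k != label},
            pairs={k: v for k, v in self.pairs.items() if k != label},
        )


def estimate_shift(fitnesses: Sequence[float]) -> int:
    """Largest integer strictly less than every observed fitness."""
    if len(fitnesses) == 0:
        raise InsufficientDataError("no fitness values")
    lowest = min(fitnesses)
    floor = math.floor(lowest)
    return int(floor) - 1 if floor == lowest else int(floor)


@dataclass(frozen=True)
class PhenotypeAssignment:
    """Imputed single-mutant phenotypes with their branch choices.

    ``branch[g]`` is ``"low"`` or ``"high"`` (side of the peak), or
    ``"peak"`` when the single's fitness met or exceeded the peak and its
    phenotype was clamped to the mode.
    """

    z: dict[str, float]
    branch: dict[str, str]
    clamped: frozenset[str] = field(default_factory=frozenset)

    def double_phenotype(self, a: str, b: str) -> float:
        return self.z[a] + self.z[b]


def impute_phenotypes(
    params: GammaMapParams,
    single_fitness: Mapping[str, float],
    pairs: Mapping[str, tuple[str, str]],
    double_fitness: Mapping[str, float],
    branch: Mapping[str, str] | None = None,
) -> PhenotypeAssignment:
    """Choose each single's side of the peak to best explain the doubles.

    All ``2**m`` branch combinations are enumerated and scored by the sum
    of squared double-mutant residuals; ties break toward the low branch,
    lexicographically by label.  Singles whose fitness is not below the
    peak are clamped to the mode (single candidate, flagged).  A ``branch``
    mapping (label -> ``"low"``/``"high"``) pins the side for those singles
    instead of enumerating them.
    """
    labels = sorted(single_fitness)
    peak = params.shift + params.height
    zstar = mode(params)
    candidates: dict[str, tuple[float, float]] = {}
    clamped = set()
    for g in labels:
        w = single_fitness[g]
        if w >= peak:
            candidates[g] = (zstar, zstar)
            if w > peak:
                clamped.add(g)
        else:
            roots = invert(params, w)
            if branch is not None and branch.get(g) in ("low", "high"):
                z_pinned = roots[0] if branch[g] == "low" else roots[1]
                roots = (z_pinned, z_pinned)
            candidates[g] = roots

    free = [g for g in labels if candidates[g][0] != candidates[g][1]]
    n_free = len(free)
    combos = np.array(list(itertools.product((0, 1), repeat=n_free)), dtype=int)
    if combos.size == 0:
        combos = np.zeros((1, 0), dtype=int)

    # phenotype matrix: one row per combo, one column per single
    zmat = np.empty((combos.shape[0], len(labels)))
    cand = np.array([candidates[g] for g in labels])  # (m, 2)
    free_idx = {g: i for i, g in enumerate(free)}
    for j, g in enumerate(labels):
        if g in free_idx:
            zmat[:, j] = cand[j, combos[:, free_idx[g]]]
        else:
            zmat[:, j] = cand[j, 0]

    col = {g: j for j, g in enumerate(labels)}
    dbl_labels = sorted(pairs)
    if dbl_labels:
        ia = np.array([col[pairs[d][0]] for d in dbl_labels])
        ib = np.array([col[pairs[d][1]] for d in dbl_labels])
        w_obs = np.array([double_fitness[d] for d in dbl_labels])
        pred = evaluate(params, zmat[:, ia] + zmat[:, ib])
        sse = ((w_obs - pred) ** 2).sum(axis=1)
    else:
        sse = np.zeros(combos.shape[0])
    best = int(np.argmin(sse))  # first minimum = all-low-preferring tie-break

    z = {g: float(zmat[best, col[g]]) for g in labels}
    branch_out = {}
    for g in labels:
        if single_fitness[g] >= peak:
            branch_out[g] = "peak"
        elif branch is not None and branch.get(g) in ("low", "high"):
            branch_out[g] = branch[g]
        else:
            branch_out[g] = "high" if combos[best, free_idx[g]] else "low"
    return PhenotypeAssignment(z, branch_out, frozenset(clamped))


def _sse(params: GammaMapParams, assignment: PhenotypeAssignment, data: FitInput) -> float:
    pred_s = np.array(
        [evaluate(params, assignment.z[g]) for g in data.single_labels]
    )
    obs_s = np.array([data.single_fitness[g] for g in data.single_labels])
    pred_d = np.array(
        [
            evaluate(params, assignment.double_phenotype(*data.pairs[d]))
            for d in data.double_labels
        ]
    )
    obs_d = np.array([data.double_fitness[d] for d in data.double_labels])
    return float(((obs_s - pred_s) ** 2).sum() + ((obs_d - pred_d) ** 2).sum())


def fit_params_given_phenotypes(
    assignment: PhenotypeAssignment,
    data: FitInput,
    params0: GammaMapParams,
    free_scale: bool = False,
) -> GammaMapParams:
    """Minimize the squared residuals over the curve parameters.

    Shape and height (and scale, if ``free_scale``) are optimized with the
    phenotypes and shift held fixed.  The returned parameters never have a
    larger SSE than the entry parameters (descent contract).
    """
    labels = data.single_labels
    dbls = data.double_labels
    z_single = np.array([assignment.z[g] for g in labels])
    z_double = np.array([assignment.double_phenotype(*data.pairs[d]) for d in dbls])
    z_all = np.concatenate([z_single, z_double])
    w_all = np.concatenate(
        [
            [data.single_fitness[g] for g in labels],
            [data.double_fitness[d] for d in dbls],
        ]
    ).astype(float)
    shift = params0.shift

    def make(theta) -> GammaMapParams:
        if free_scale:
            a, h, lam = theta
        else:
            (a, h), lam = theta, params0.scale
        return GammaMapParams(shape=a, scale=lam, height=h, shift=shift)

    def residuals(theta):
        return w_all - evaluate(make(theta), z_all)

    if free_scale:
        x0 = [params0.shape, params0.height, params0.scale]
        lb, ub = [1.0 + 1e-6, 1e-9, 1e-9], [np.inf] * 3
    else:
        x0 = [params0.shape, params0.height]
        lb, ub = [1.0 + 1e-6, 1e-9], [np.inf] * 2
    sol = least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
    fitted = make(sol.x)
    if _sse(fitted, assignment, data) > _sse(params0, assignment, data):
        return params0
    return fitted


def _profile_refine(
    params: GammaMapParams,
    data: FitInput,
    free_scale: bool = False,
    branch: Mapping[str, str] | None = None,
) -> tuple[GammaMapParams, bool]:
    """Minimize the profiled objective over the curve parameters.

    The imputation step makes the phenotypes an exact function of the
    curve (inversion plus branch choice), so the fixed point the
    alternating scheme seeks is equivalently a minimum of the
    double-mutant SSE *profiled* over phenotypes.  That profiled function
    of (shape, height[, scale]) is minimized directly (Nelder-Mead; the
    objective is only piecewise smooth because the branch choice is
    discrete), which is far more robust than the raw alternation.

    The peak is constrained above every single-mutant fitness so all
    inversions exist during the search.
    """
    w_single = np.array([data.single_fitness[g] for g in data.single_labels])
    w_max = float(w_single.max())

    def objective(theta):
        if free_scale:
            a, h, lam = theta
        else:
            (a, h), lam = theta, params.scale
        if a <= 1.0 + 1e-6 or lam <= 0 or h + params.shift <= w_max * (1 + 1e-9):
            return 1e8
        p = GammaMapParams(shape=a, scale=lam, height=h, shift=params.shift)
        try:
            asn = impute_phenotypes(
                p, data.single_fitness, data.pairs, data.double_fitness, branch=branch
            )
        except InfeasibleFitnessError:  # pragma: no cover - guarded above
            return 1e8
        return _sse(p, asn, data)

    x0 = [params.shape, params.height] + ([params.scale] if free_scale else [])
    sol = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-12, maxiter=4000),
    )
    if free_scale:
        a, h, lam = sol.x
    else:
        (a, h), lam = sol.x, params.scale
    if sol.fun >= 1e8 or sol.fun > objective(x0):
        return params, False
    return GammaMapParams(shape=float(a), scale=float(lam), height=float(h), shift=params.shift), bool(sol.success)


@dataclass(frozen=True)
class FitDiagnostics:
    sse: float
    sst: float
    ssm: float
    r_squared: float
    f_stat: float
    p_value: float
    df_sst: int
    df_sse: int
    df_ssm: int
    note: str = F_DIST_CAVEAT


def diagnostics(
    observed: Mapping[str, float], predicted: Mapping[str, float], n_singles: int
) -> FitDiagnostics:
    """SSE/SST/SSM decomposition against the grand-mean null.

    The null model treats every mutant fitness as an independent draw
    around a common mean, so SST is taken about the grand mean of the N
    fitted genotypes.  Fitted-quantity accounting: ``n_singles`` imputed
    phenotypes plus 3 curve parameters (shift is fixed by the integer
    rule), giving ``df_SSE = N - n_singles - 3``.
    """
    labels = sorted(observed)
    obs = np.array([observed[g] for g in labels], dtype=float)
    pred = np.array([predicted[g] for g in labels], dtype=float)
    n = len(obs)
    sse = float(((obs - pred) ** 2).sum())
    sst = float(((obs - obs.mean()) ** 2).sum())
    ssm = sst - sse
    r2 = math.nan if sst == 0.0 else 1.0 - sse / sst
    df_sst = n - 1
    df_sse = n - n_singles - N_CURVE_PARAMS
    df_ssm = df_sst - df_sse
    if df_sse > 0 and df_ssm > 0 and sse > 0:
        f_stat = (ssm / df_ssm) / (sse / df_sse)
        p = float(stats.f.sf(f_stat, df_ssm, df_sse))
    else:
        f_stat, p = math.inf, 0.0
    return FitDiagnostics(sse, sst, ssm, r2, f_stat, p, df_sst, df_sse, df_ssm)


@dataclass(frozen=True)
class FitResult:
    params: GammaMapParams
    assignment: PhenotypeAssignment
    sigma2: float
    observed: dict[str, float]
    predicted: dict[str, float]
    diagnostics: FitDiagnostics
    n_iter: int
    converged: bool
    sse_trace: tuple[float, ...]

    @property
    def residuals(self) -> dict[str, float]:
        return {g: self.observed[g] - self.predicted[g] for g in self.observed}


def default_init(shifted_max: float) -> GammaMapParams:
    """Feasible starting point: peak 5% above the highest shifted fitness."""
    return GammaMapParams(shape=2.0, scale=1.0, height=shifted_max * 1.05, shift=0.0)


def fit(
    data: FitInput,
    init: GammaMapParams | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    free_scale: bool = False,
    shift: int | None = None,
    branch: Mapping[str, str] | None = None,
) -> FitResult:
    """Alternate phenotype imputation and curve refitting to convergence.

    The alternating scheme (impute, refit, repeat) provides a warm start;
    because the imputation step pins singles to exact curve inversions,
    the scheme can oscillate, so the run finishes with a direct
    minimization of the profiled objective (see ``_profile_refine``) from
    the best alternating iterate.

    Parameters
    ----------
    data : FitInput
        Mean fitness per single and double mutant plus the wild-type mean.
    init : GammaMapParams, optional
        Starting curve (on the shifted scale, i.e. ``shift == 0``).
    shift : int, optional
        Fix the fitness shift externally (used by leave-one-out so every
        reduced fit shares the full-data shift); default re-estimates it
        from ``data``.
    tol : float
        Convergence threshold on the largest change in (shape, height,
        scale) and in any imputed phenotype between outer iterations.
    branch : mapping, optional
        Pin each single's side of the peak (``"low"``/``"high"``) instead
        of enumerating; used by leave-one-out to hold the full-data
        imputation structure fixed across reduced fits.

    Returns
    -------
    FitResult
        Parameters are reported on the observed scale (``params.shift`` is
        the integer shift) and predictions are un-shifted.
    """
    all_fitness = (
        [data.wt_fitness]
        + list(data.single_fitness.values())
        + list(data.double_fitness.values())
    )
    beta = estimate_shift(all_fitness) if shift is None else int(shift)
    shifted = replace(
        data,
        wt_fitness=data.wt_fitness - beta,
        single_fitness={g: w - beta for g, w in data.single_fitness.items()},
        double_fitness={g: w - beta for g, w in data.double_fitness.items()},
    )
    max_w = max(
        list(shifted.single_fitness.values()) + list(shifted.double_fitness.values())
    )
    params = init if init is not None else default_init(max_w)

    assignment = impute_phenotypes(
        params,
        shifted.single_fitness,
        shifted.pairs,
        shifted.double_fitness,
        branch=branch,
    )
    best_params = params
    best_sse = _sse(params, assignment, shifted)
    trace = [best_sse]
    stable = False
    stall = 0
    n_iter = 0
    peak_floor = max(shifted.single_fitness.values())
    for n_iter in range(1, max_iter + 1):
        new_params = fit_params_given_phenotypes(
            assignment, shifted, params, free_scale=free_scale
        )
        try:
            new_assignment = impute_phenotypes(
                new_params,
                shifted.single_fitness,
                shifted.pairs,
                shifted.double_fitness,
                branch=branch,
            )
        except InfeasibleFitnessError:
            # the parameter step wandered into a curve the singles cannot
            # be inverted through; fall back to the best iterate
            break
        sse = _sse(new_params, new_assignment, shifted)
        dparam = max(
            abs(new_params.shape - params.shape),
            abs(new_params.height - params.height),
            abs(new_params.scale - params.scale),
        )
        dz = max(
            abs(new_assignment.z[g] - assignment.z[g]) for g in assignment.z
        )
        if sse < best_sse - 1e-12 and new_params.height > peak_floor:
            best_params, best_sse = new_params, sse
            stall = 0
        else:
            # the impute step constrains singles to exact inversion, so the
            # total SSE may oscillate; keep the best iterate and bail out
            # once no progress is being made
            stall += 1
        trace.append(best_sse)
        params, assignment = new_params, new_assignment
        if dparam < tol and dz < tol:
            stable = True
            break
        if stall >= 10:
            break

    # finish by minimizing the profiled objective directly from the best
    # alternating iterate (robust against oscillation of the raw scheme)
    params, refined = _profile_refine(
        best_params, shifted, free_scale=free_scale, branch=branch
    )
    assignment = impute_phenotypes(
        params,
        shifted.single_fitness,
        shifted.pairs,
        shifted.double_fitness,
        branch=branch,
    )
    converged = refined or stable
    trace.append(_sse(params, assignment, shifted))
    final = GammaMapParams(
        shape=params.shape, scale=params.scale, height=params.height, shift=float(beta)
    )
    predicted = {
        g: evaluate(final, assignment.z[g]) for g in data.single_labels
    }
    predicted.update(
        {
            d: evaluate(final, assignment.double_phenotype(*data.pairs[d]))
            for d in data.double_labels
        }
    )
    observed = dict(data.single_fitness) | dict(data.double_fitness)
    diag = diagnostics(observed, predicted, n_singles=len(data.single_fitness))
    sigma2 = diag.sse / diag.df_sse if diag.df_sse > 0 else math.nan
    return FitResult(
        params=final,
        assignment=assignment,
        sigma2=sigma2,
        observed=observed,
        predicted=predicted,
        diagnostics=diag,
        n_iter=n_iter,
        converged=converged,
        sse_trace=tuple(trace),
    )
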