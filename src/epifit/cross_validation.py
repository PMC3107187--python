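"""Leave-one-double-out prediction of double-mutant fitness."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import pandas as pd
from scipy import stats

from .gamma_fit import FitInput, estimate_shift, fit
from .gamma_map import evaluate


def t_critical(df: int, level: float = 0.05) -> float:
    """Two-sided critical value of the t distribution (default 5%)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.t.ppf(1.0 - level / 2.0, df))


@dataclass(frozen=True)
class LooRecord:
    """Held-out prediction for one double mutant.

    ``n_sd`` is |observed - predicted| in units of the reduced fit's
    residual SD; ``significant`` compares it with the two-sided 5% t
    critical value at the reduced fit's residual df.
    """

    removed: str
    predicted: float
    observed: float
    df: int
    sigma: float
    n_sd: float
    significant: bool
    converged: bool


def loo_predict(
    data: FitInput,
    level: float = 0.05,
    free_scale: bool = False,
    **fit_kwargs,
) -> list[LooRecord]:
    """Remove each double in turn, refit, and predict the removed value.

    Every reduced fit shares the full-data integer shift so predictions
    are on a common scale, and holds the full-data imputation structure
    (each single's side of the peak) fixed: the latent-phenotype problem
    is multimodal, and letting the discrete branch choice flip between
    reduced fits produces predictions that reflect basin hopping rather
    than the model.  Continuous quantities (curve parameters, hence the
    phenotype values) are re-estimated per analysis.  The prediction for
    the removed double ``ij`` is the fitted curve at ``z_i + z_j`` from
    the reduced fit; the residual SD is ``sqrt(SSE / df_SSE)`` of the
    reduced fit.
    """
    all_fitness = (
        [data.wt_fitness]
        + list(data.single_fitness.values())
        + list(data.double_fitness.values())
    )
    shift = estimate_shift(all_fitness)
    full = fit(data, shift=shift, free_scale=free_scale, **fit_kwargs)
    branch = {
        g: b for g, b in full.assignment.branch.items() if b in ("low", "high")
    }
    records = []
    for removed in data.double_labels:
        reduced = data.drop_double(removed)
        res = fit(
            reduced, shift=shift, free_scale=free_scale, branch=branch, **fit_kwargs
        )
        a, b = data.pairs[removed]
        predicted = float(
            evaluate(res.params, res.assignment.double_phenotype(a, b))
        )
        observed = data.double_fitness[removed]
        sigma = math.sqrt(res.sigma2)
        err = abs(observed - predicted)
        if sigma < 1e-7:
            # numerically perfect reduced fit (noise-free data): the ratio
            # is 0/0, so score by the absolute prediction error instead
            n_sd = 0.0 if err < 1e-6 else math.inf
        else:
            n_sd = err / sigma
        df = res.diagnostics.df_sse
        records.append(
            LooRecord(
                removed=removed,
                predicted=predicted,
                observed=observed,
                df=df,
                sigma=sigma,
                n_sd=n_sd,
                significant=n_sd > t_critical(df, level),
                converged=res.converged,
            )
        )
    return records


def loo_frame(records: Sequence[LooRecord]) -> pd.DataFrame:
    """Tidy table: removed, predicted, observed, df, sigma, n_sd, flag."""
    return pd.DataFrame([vars(r) for r in records])
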