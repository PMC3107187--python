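"""Deviation-from-additivity statistics and significance-test batteries.

Fitness is a growth rate (log scale), so the additive expectation for a
double mutant is the *sum* of its single-mutant effects.  The deviation

    epsilon = s_ij - (s_i + s_j)

is negative for antagonistic, positive for synergistic, and zero for
additive interactions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assay_io import AssayReplicate, EffectTable
from .errors import InsufficientDataError

N_TESTS_DEFAULT = 18


def epsilon(s_ij: float, s_i: float, s_j: float) -> float:
    """Deviation from additivity, ``s_ij - s_i - s_j``."""
    return s_ij - s_i - s_j


def additive_expectation(s_i: float, s_j: float) -> float:
    """Expected double-mutant effect when single effects sum."""
    return s_i + s_j


@dataclass(frozen=True)
class EpsilonRecord:
    """Per-pair decomposition of the double-mutant effect.

    ``delta_into_first`` is the effect of adding the second mutation into
    the background already carrying the first (``s_ij - s_i``);
    ``delta_into_second`` is the converse (``s_ij - s_j``).
    """

    pair: str
    s_i: float
    s_j: float
    s_ij: float
    additive_expectation: float
    epsilon: float
    delta_into_first: float
    delta_into_second: float


def epsilon_table(effects: EffectTable) -> list[EpsilonRecord]:
    """One :class:`EpsilonRecord` per double, sorted by pair label."""
    records = []
    for pair in effects.doubles:
        first, second = effects.pairs[pair]
        s_i = effects.effects[first]
        s_j = effects.effects[second]
        s_ij = effects.effects[pair]
        records.append(
            EpsilonRecord(
                pair=pair,
                s_i=s_i,
                s_j=s_j,
                s_ij=s_ij,
                additive_expectation=additive_expectation(s_i, s_j),
                epsilon=epsilon(s_ij, s_i, s_j),
                delta_into_first=s_ij - s_i,
                delta_into_second=s_ij - s_j,
            )
        )
    return records


@dataclass(frozen=True)
class MeanEpsilonTest:
    mean: float
    t: float
    p: float | None
    n: int
    degenerate: bool = False


def mean_epsilon_test(records: Sequence[EpsilonRecord]) -> MeanEpsilonTest:
    """One-sample t test of mean epsilon = 0 across pairs.

    With zero spread in the epsilons the t statistic is degenerate; the
    result is flagged and no p-value is fabricated.
    """
    if len(records) < 2:
        raise InsufficientDataError("need at least 2 epsilon records")
    eps = np.array([r.epsilon for r in records], dtype=float)
    mean = float(eps.mean())
    sd = float(eps.std(ddof=1))
    n = len(eps)
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        return MeanEpsilonTest(mean, t, None, n, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return MeanEpsilonTest(mean, t, float(p), n)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_one_sided(
    group_a: Sequence[float], group_b: Sequence[float], alternative: str = "less"
) -> WelchResult:
    """One-sided Welch two-sample t test of mean(a) vs mean(b).

    ``alternative="less"`` tests mean(a) < mean(b); ``"greater"`` tests
    mean(a) > mean(b).  When both sample variances are exactly zero the
    means are compared directly and the result is flagged degenerate with
    p in {0, 0.5, 1}.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        diff = a.mean() - b.mean()
        if diff == 0.0:
            return WelchResult(0.0, math.inf, 0.5, degenerate=True)
        t = math.copysign(math.inf, diff)
        hit = (diff < 0) if alternative == "less" else (diff > 0)
        return WelchResult(t, math.inf, 0.0 if hit else 1.0, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def bonferroni(p: float, m: int = N_TESTS_DEFAULT) -> float:
    """Bonferroni-adjusted p-value, ``min(1, m * p)``."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return min(1.0, m * p)


class EpistasisCategory(str, Enum):
    """Mean-based category of a double mutant relative to its singles and wt.

    Boundaries use strict inequalities; an exact tie falls to the weaker
    (less extreme) claim.  ``BELOW_ONE_SINGLE`` is the boundary category
    for a double tied exactly with its lower single.
    """

    EXCEEDS_BOTH_SINGLES = "exceeds_both_singles"
    BETWEEN_SINGLES = "between_singles"
    BELOW_ONE_SINGLE = "below_one_single"
    BELOW_BOTH_SINGLES = "below_both_singles"
    BELOW_WILD_TYPE = "below_wild_type"


def categorize(s_i: float, s_j: float, s_ij: float) -> EpistasisCategory:
    """Classify a double mutant's mean effect against its singles and wt."""
    lo, hi = min(s_i, s_j), max(s_i, s_j)
    if s_ij < 0:
        return EpistasisCategory.BELOW_WILD_TYPE
    if s_ij < lo:
        return EpistasisCategory.BELOW_BOTH_SINGLES
    if s_ij == lo:
        return EpistasisCategory.BELOW_ONE_SINGLE
    if s_ij > hi:
        return EpistasisCategory.EXCEEDS_BOTH_SINGLES
    return EpistasisCategory.BETWEEN_SINGLES


@dataclass(frozen=True)
class EpistasisCall:
    """Category plus the four one-sided Welch hypotheses for one double.

    p-value keys: ``lt_max_single`` (double < better single, conditional
    decompensation), ``lt_min_single`` (double < worse single,
    unconditional decompensation), ``lt_wild_type``, ``gt_max_single``
    (recombinant advantage).  ``None`` when replicate data were missing.
    """

    pair: str
    category: EpistasisCategory
    p_values: dict[str, float | None]
    p_adjusted: dict[str, float | None]


_HYPOTHESES = ("lt_max_single", "lt_min_single", "lt_wild_type", "gt_max_single")


def decompensation_battery(
    effects: EffectTable,
    replicates: Sequence[AssayReplicate] | None = None,
    n_tests: int = N_TESTS_DEFAULT,
) -> list[EpistasisCall]:
    """Mean-based categories and, when replicates are given, Welch batteries.

    Each double is tested one-sidedly against its better single, its worse
    single and the wild type (less), and against its better single
    (greater), with Bonferroni adjustment over ``n_tests`` comparisons.
    Doubles missing replicate-level data for any genotype in a comparison
    get ``None`` p-values for that comparison, with a warning.
    """
    groups: dict[str, list[float]] = {}
    if replicates is not None:
        for r in replicates:
            groups.setdefault(r.genotype, []).append(r.fitness)

    calls = []
    for pair in effects.doubles:
        first, second = effects.pairs[pair]
        s_i, s_j = effects.effects[first], effects.effects[second]
        s_ij = effects.effects[pair]
        category = categorize(s_i, s_j, s_ij)
        better = first if s_i >= s_j else second
        worse = second if better == first else first
        comparisons = {
            "lt_max_single": (better, "less"),
            "lt_min_single": (worse, "less"),
            "lt_wild_type": (effects.wild_type_label, "less"),
            "gt_max_single": (better, "greater"),
        }
        p_values: dict[str, float | None] = {}
        for name in _HYPOTHESES:
            other, alternative = comparisons[name]
            if (
                replicates is None
                or len(groups.get(pair, ())) < 2
                or len(groups.get(other, ())) < 2
            ):
                if replicates is not None:
                    warnings.warn(
                        f"missing replicates for {pair} vs {other}; test omitted",
                        stacklevel=2,
                    )
                p_values[name] = None
                continue
            p_values[name] = welch_one_sided(groups[pair], groups[other], alternative).p
        p_adjusted = {
            k: (None if p is None else bonferroni(p, n_tests)) for k, p in p_values.items()
        }
        calls.append(EpistasisCall(pair, category, p_values, p_adjusted))
    return calls


def epsilon_frame(records: Sequence[EpsilonRecord], calls: Sequence[EpistasisCall] | None = None) -> pd.DataFrame:
    """Tidy per-pair table of effects, epsilon, deltas and (optionally) calls."""
    df = pd.DataFrame([vars(r) for r in records])
    if calls is not None:
        by_pair = {c.pair: c for c in calls}
        df["category"] = df["pair"].map(lambda p: by_pair[p].category.value)
        for name in _HYPOTHESES:
            df[f"p_{name}"] = df["pair"].map(lambda p: by_pair[p].p_values[name])
            df[f"p_adj_{name}"] = df["pair"].map(lambda p: by_pair[p].p_adjusted[name])
    return df
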