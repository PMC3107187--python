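import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from epifit.epistasis_stats import (
    EpistasisCategory,
    additive_expectation,
    bonferroni,
    categorize,
    decompensation_battery,
    epsilon,
    epsilon_table,
    mean_epsilon_test,
    welch_one_sided,
)
from epifit.errors import InsufficientDataError
from epifit.synthetic_data import generate_from_means

finite = st.floats(min_value=-50, max_value=50, allow_nan=False)


class TestEpsilon:
    def test_ab(self):
        assert epsilon(3.47, 3.89, 4.15) == pytest.approx(-4.57)

    def test_ce(self):
        assert epsilon(-3.62, 4.18, 1.65) == pytest.approx(-9.45)

    def test_additive_case(self):
        assert epsilon(5.0, 2.0, 3.0) == 0.0

    @given(finite, finite)
    def test_epsilon_of_expectation_is_zero(self, a, b):
        assert epsilon(additive_expectation(a, b), a, b) == pytest.approx(0.0, abs=1e-9)

    @given(finite, finite, finite)
    def test_symmetric(self, s_ij, a, b):
        # equal up to float non-associativity of the two subtractions
        assert epsilon(s_ij, a, b) == pytest.approx(epsilon(s_ij, b, a), abs=1e-10)


def test_additive_expectation_values():
    assert additive_expectation(4.15, 5.84) == pytest.approx(9.99)
    assert additive_expectation(3.89, 3.44) == pytest.approx(7.33)
    assert additive_expectation(0.0, 0.0) == 0.0


class TestEpsilonTable:
    def test_fixture_all_negative(self, id11_effects):
        records = epsilon_table(id11_effects)
        assert len(records) == 18
        assert all(r.epsilon < 0 for r in records)

    def test_fixture_ei_delta(self, id11_effects):
        (ei,) = [r for r in epsilon_table(id11_effects) if r.pair == "EI"]
        # effect of adding I into the E background
        assert ei.delta_into_first == pytest.approx(-4.09)
        assert ei.delta_into_second == pytest.approx(-3.86)

    def test_delta_identity(self, id11_effects):
        for r in epsilon_table(id11_effects):
            assert r.delta_into_first - r.delta_into_second == pytest.approx(
                r.s_j - r.s_i
            )

    def test_single_pair(self):
        from epifit.assay_io import EffectTable

        table = EffectTable(
            "wt", {"wt": 0.0, "X": 1.0, "Y": 1.0, "XY": 1.0}, {"XY": ("X", "Y")}
        )
        (rec,) = epsilon_table(table)
        assert rec.epsilon == pytest.approx(-1.0)


class TestMeanEpsilonTest:
    def test_fixture_mean(self, id11_effects):
        # oracle: hand summation of the 18 tabulated deviations
        res = mean_epsilon_test(epsilon_table(id11_effects))
        assert res.mean == pytest.approx(-81.34 / 18, abs=1e-9)
        assert res.p < 1e-6
        assert res.t < 0

    def test_all_zero(self):
        recs = epsilon_table_from([0.0, 0.0, 0.0])
        res = mean_epsilon_test(recs)
        assert res.mean == 0.0
        assert res.t == 0.0
        assert res.degenerate

    def test_degenerate_sd_zero(self):
        res = mean_epsilon_test(epsilon_table_from([-1.0] * 4))
        assert res.degenerate
        assert res.p is None
        assert res.t == -math.inf

    def test_insufficient(self):
        with pytest.raises(InsufficientDataError):
            mean_epsilon_test(epsilon_table_from([-1.0]))


def epsilon_table_from(epsilons):
    """Minimal records carrying given epsilon values."""
    from epifit.epistasis_stats import EpsilonRecord

    return [
        EpsilonRecord(f"P{i}", 0.0, 0.0, e, 0.0, e, e, e) for i, e in enumerate(epsilons)
    ]


class TestWelch:
    def test_identical_groups(self):
        res = welch_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "less")
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(0.5)

    def test_frozen_oracle(self):
        # groups constructed to mean 7.32 (n=5, sd 0.5) vs 5.84 (n=6, sd 0.5);
        # Welch formula by hand: t = 1.48/0.3027650 = 4.8883, df = 8.6429
        a = _with_moments(7.32, 0.5, 5)
        b = _with_moments(5.84, 0.5, 6)
        res = welch_one_sided(a, b, "greater")
        assert res.t == pytest.approx(4.8883, abs=1e-3)
        assert res.df == pytest.approx(8.6429, abs=1e-3)
        assert res.p < 0.001

    def test_swap_symmetry(self):
        a = [1.0, 2.0, 3.5]
        b = [2.0, 4.0, 4.5]
        r1 = welch_one_sided(a, b, "less")
        r2 = welch_one_sided(b, a, "less")
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(1.0 - r2.p)

    def test_zero_variance_convention(self):
        res = welch_one_sided([1.0, 1.0], [2.0, 2.0], "less")
        assert res.degenerate
        assert res.p == 0.0
        res = welch_one_sided([1.0, 1.0], [2.0, 2.0], "greater")
        assert res.p == 1.0

    def test_too_small(self):
        with pytest.raises(InsufficientDataError):
            welch_one_sided([1.0], [1.0, 2.0], "less")


def _with_moments(mean, sd, n):
    x = np.arange(n, dtype=float)
    x = (x - x.mean()) / x.std(ddof=1)
    return x * sd + mean


class TestBonferroni:
    def test_values(self):
        assert bonferroni(0.001, 18) == pytest.approx(0.018)
        assert bonferroni(0.5, 18) == 1.0
        assert bonferroni(0.0, 18) == 0.0

    def test_m_validation(self):
        with pytest.raises(ValueError):
            bonferroni(0.1, 0)

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    def test_monotone(self, p1, p2):
        lo, hi = sorted((p1, p2))
        assert bonferroni(lo) <= bonferroni(hi)

    @given(st.floats(min_value=0, max_value=1))
    def test_adjusted_at_least_raw(self, p):
        assert bonferroni(p) >= p


class TestCategories:
    def test_between(self):
        assert categorize(1.0, 2.0, 1.5) is EpistasisCategory.BETWEEN_SINGLES

    def test_exceeds(self):
        assert categorize(3.89, 5.84, 7.32) is EpistasisCategory.EXCEEDS_BOTH_SINGLES

    def test_below_wild_type(self):
        assert categorize(4.18, 1.65, -3.62) is EpistasisCategory.BELOW_WILD_TYPE

    def test_below_both(self):
        assert categorize(2.0, 3.0, 1.0) is EpistasisCategory.BELOW_BOTH_SINGLES

    def test_ties_fall_to_weaker(self):
        assert categorize(1.0, 2.0, 2.0) is EpistasisCategory.BETWEEN_SINGLES
        assert categorize(1.0, 2.0, 1.0) is EpistasisCategory.BELOW_ONE_SINGLE
        assert categorize(1.0, 2.0, 0.0) is EpistasisCategory.BELOW_BOTH_SINGLES

    def test_fixture_counts(self, id11_effects):
        calls = decompensation_battery(id11_effects)
        by_cat = {}
        for c in calls:
            by_cat.setdefault(c.category, set()).add(c.pair)
        assert by_cat[EpistasisCategory.BELOW_WILD_TYPE] == {"CE", "EI"}
        assert by_cat[EpistasisCategory.EXCEEDS_BOTH_SINGLES] == {
            "AG", "AH", "BH", "CH", "DF",
        }


@pytest.fixture(scope="module")
def fixture_replicates(id11):
    means = {g: id11.wt_fitness + s for g, s in id11.single_effects.items()}
    means[id11.wild_type_label] = id11.wt_fitness
    means.update(id11.double_fitness)
    return generate_from_means(means, 0.3, id11.n_replicates, seed=11)


class TestBattery:
    def test_unconditional_decompensation(self, id11, id11_effects, fixture_replicates):
        calls = {c.pair: c for c in decompensation_battery(id11_effects, fixture_replicates)}
        # CE and EI fall below even the wild type
        for pair in ("CE", "EI"):
            assert calls[pair].p_adjusted["lt_wild_type"] < 0.05
            assert calls[pair].p_adjusted["lt_min_single"] < 0.05

    def test_recombinant_advantage_ag(self, id11_effects, fixture_replicates):
        calls = {c.pair: c for c in decompensation_battery(id11_effects, fixture_replicates)}
        assert calls["AG"].p_adjusted["gt_max_single"] < 0.05
        # an unremarkable pair shows no recombinant advantage
        assert calls["AB"].p_adjusted["gt_max_single"] > 0.05

    def test_mean_only_data_gives_no_pvalues(self, id11_effects):
        calls = decompensation_battery(id11_effects, replicates=None)
        assert all(p is None for c in calls for p in c.p_values.values())

    def test_missing_genotype_warns_not_fails(self, id11_effects, fixture_replicates):
        partial = [r for r in fixture_replicates if r.genotype != "G"]
        with pytest.warns(UserWarning, match="missing replicates"):
            calls = decompensation_battery(id11_effects, partial)
        by_pair = {c.pair: c for c in calls}
        assert by_pair["AG"].p_values["lt_max_single"] is None
        assert by_pair["AB"].p_values["lt_max_single"] is not None
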