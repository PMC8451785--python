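"""Unit and property tests for the survival/association statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cllburden.survival import (SurvivalData, UndefinedResultError,
                                association_test, cox_fit, harrell_c_index,
                                kaplan_meier, logrank_test, mann_whitney)
from oracles import (c_index_pair_oracle, c_index_rowwise_oracle,
                     chi2_statistic_oracle, logrank_oracle)


class TestHarrellC:
    def test_single_discordant_pair(self):
        # marker-positive patient fails first -> the only pair is discordant
        surv = SurvivalData(np.array([10.0, 2.0]), np.array([True, True]))
        res = harrell_c_index([0, 1], surv)
        assert (res.c, res.n_usable, res.n_discordant) == (0.0, 1, 1)
        assert res.n_concordant == 0 and res.n_tied_x == 0

    def test_constant_marker_is_exactly_half(self):
        surv = SurvivalData(np.array([1.0, 2.0, 3.0]), np.array([True] * 3))
        with pytest.warns(UserWarning, match="constant"):
            res = harrell_c_index([1, 1, 1], surv)
        assert res.c == 0.5
        assert res.n_tied_x == res.n_usable == 3

    def test_no_usable_pairs_raises(self):
        surv = SurvivalData(np.array([1.0, 2.0]), np.array([False, False]))
        with pytest.raises(UndefinedResultError):
            harrell_c_index([0, 1], surv)

    def test_tied_time_one_event_is_usable(self):
        # event at t precedes censoring at the same t
        surv = SurvivalData(np.array([3.0, 3.0]), np.array([True, False]))
        res = harrell_c_index([1, 0], surv)  # the failing patient is marked
        assert res.n_usable == 1 and res.c == 0.0

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pair_oracle_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        t = np.round(rng.exponential(1.0, n), 1)
        e = rng.random(n) >= rng.uniform(0.0, 0.4)
        x = rng.integers(0, 2, n)
        oc, ous, onc, ond, ont = c_index_pair_oracle(x, t, e)
        if ous == 0:
            with pytest.raises(UndefinedResultError):
                harrell_c_index(x, SurvivalData(t, e))
            return
        res = harrell_c_index(x, SurvivalData(t, e))
        assert (res.c, res.n_usable, res.n_concordant, res.n_discordant,
                res.n_tied_x) == (oc, ous, onc, ond, ont)

    def test_rowwise_oracle_agrees_with_pair_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            t = np.round(rng.exponential(1.0, n), 1)
            e = rng.random(n) >= 0.3
            x = rng.integers(0, 2, n)
            assert c_index_rowwise_oracle(x, t, e) == c_index_pair_oracle(x, t, e)

    def test_agrees_with_scikit_survival_on_tie_free_data(self):
        # independent library route; sksurv scores risk (higher = earlier
        # failure), the mirror of our protective-direction coding
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(8)
        for _ in range(10):
            n = 60
            t = rng.exponential(1.0, n)  # continuous -> no time ties
            e = rng.random(n) >= 0.3
            x = rng.integers(0, 2, n)
            if x.min() == x.max():
                continue
            res = harrell_c_index(x, SurvivalData(t, e))
            ref, *_ = concordance_index_censored(e, t, x.astype(float))
            assert res.c == pytest.approx(1.0 - ref, abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_flipping_marker_reflects_c_around_half(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        t = rng.exponential(1.0, n)
        e = rng.random(n) >= 0.3
        x = rng.integers(0, 2, n)
        if x.min() == x.max() or not e.any():
            return
        surv = SurvivalData(t, e)
        res = harrell_c_index(x, surv)
        flipped = harrell_c_index(1 - x, surv)
        assert flipped.c == pytest.approx(1.0 - res.c)
        assert flipped.n_usable == res.n_usable


class TestKaplanMeier:
    def test_all_events_distinct_times_drops_one_over_n(self):
        surv = SurvivalData(np.array([1.0, 2.0, 3.0, 4.0]), np.array([True] * 4))
        km = kaplan_meier(surv)
        steps = km.survival[np.isin(km.times, [1, 2, 3, 4])]
        assert np.allclose(steps, [0.75, 0.5, 0.25, 0.0])
        assert km.median == 2.0  # first time S <= 0.5

    def test_single_censored_observation_stays_at_one(self):
        km = kaplan_meier(SurvivalData(np.array([5.0]), np.array([False])))
        assert np.all(km.survival == 1.0)
        assert np.isnan(km.median)

    def test_exponential_median_approaches_closed_form(self):
        rng = np.random.default_rng(11)
        lam = 0.4
        t = rng.exponential(1 / lam, 4000)
        km = kaplan_meier(SurvivalData(t, np.ones(4000, bool)))
        assert km.median == pytest.approx(np.log(2) / lam, rel=0.08)


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.array([True, True, False, True] * 2)
        g = np.array([True] * 4 + [False] * 4)
        stat, p = logrank_test(g, SurvivalData(t, e))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_definition_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            na, nb = 25, 20
            ta = rng.exponential(1.0, na)
            tb = rng.exponential(0.6, nb)
            ea = rng.random(na) >= 0.2
            eb = rng.random(nb) >= 0.2
            g = np.r_[np.ones(na, bool), np.zeros(nb, bool)]
            surv = SurvivalData(np.r_[ta, tb], np.r_[ea, eb])
            stat, _ = logrank_test(g, surv)
            assert stat == pytest.approx(logrank_oracle(ta, ea, tb, eb), rel=1e-6)

    def test_requires_two_groups(self):
        surv = SurvivalData(np.array([1.0, 2.0]), np.array([True, True]))
        with pytest.raises(ValueError):
            logrank_test(np.array([True, True]), surv)


class TestCox:
    def test_recovers_planted_hazard_ratio(self):
        rng = np.random.default_rng(2)
        n = 5000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(np.log(2.0) * x))
        res = cox_fit(pd.DataFrame({"x": x}),
                      SurvivalData(t, np.ones(n, bool)))
        assert res.summary.loc["x", "hr"] == pytest.approx(2.0, rel=0.07)
        lo, hi = res.summary.loc["x", ["ci_low", "ci_high"]]
        assert lo < 2.0 < hi

    def test_duplicate_columns_raise_collinearity_error(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, 100).astype(float)
        t = rng.exponential(1.0, 100)
        with pytest.raises(ValueError, match="collinear"):
            cox_fit(pd.DataFrame({"a": x, "b": x}),
                    SurvivalData(t, np.ones(100, bool)))

    def test_constant_covariate_raises(self):
        t = np.arange(1.0, 21.0)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"a": np.ones(20)}),
                    SurvivalData(t, np.ones(20, bool)))


class TestAssociation:
    def test_balanced_table_has_no_association(self):
        name, stat, p = association_test([[20, 20], [20, 20]])
        assert name == "chi_square"
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_switches_to_fisher_on_small_expected_counts(self):
        name, _, _ = association_test([[1, 9], [8, 2]])
        assert name == "fisher_exact"

    def test_chi_square_matches_textbook_formula(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            tab = rng.integers(5, 60, (2, 2))
            expected = stats.contingency.expected_freq(tab)
            if (expected < 5).any():
                continue
            name, stat, _ = association_test(tab)
            assert name == "chi_square"
            assert stat == pytest.approx(chi2_statistic_oracle(tab), rel=1e-12)

    def test_rejects_negative_or_fractional_counts(self):
        with pytest.raises(ValueError):
            association_test([[1.5, 2], [3, 4]])


class TestMannWhitney:
    def test_identical_samples_not_significant(self):
        a = np.arange(1.0, 26.0)
        _, p = mann_whitney(a, a.copy())
        assert p > 0.9

    def test_complete_separation_gives_extreme_u(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        # U counts pairs where the first sample wins; full separation -> 0
        assert u == 0.0
        # smallest attainable two-sided exact p at n = 3 vs 3
        assert p == pytest.approx(0.1, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
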