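"""Kaplan-Meier, log-rank and Cox hazard ratios against hand oracles and
parameter-recovery simulations."""

import numpy as np
import pandas as pd
import pytest

from bcradiomics.errors import SchemaError, ValidationError
from bcradiomics.survival import (cox_multivariate, hazard_ratio,
                                  km_estimate, logrank_test)


def hand_logrank(ta, ea, tb, eb):
    """Log-rank chi-square via O - E and hypergeometric variance at each
    distinct event time (group A as reference)."""
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    o_minus_e = 0.0
    var = 0.0
    for tt in np.unique(t[e == 1]):
        at = t >= tt
        n = at.sum()
        n1 = (at & (g == 1)).sum()
        d = ((t == tt) & (e == 1)).sum()
        d1 = ((t == tt) & (e == 1) & (g == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def cox_grid_oracle(g, t, e):
    """Maximize the Breslow partial likelihood for one binary covariate by
    grid search over the log hazard ratio."""
    g = np.asarray(g, float)
    t = np.asarray(t, float)
    e = np.asarray(e, int)

    def negpl(beta):
        ll = 0.0
        for tt in np.unique(t[e == 1]):
            at = t >= tt
            d_idx = (t == tt) & (e == 1)
            ll += beta * g[d_idx].sum()
            ll -= d_idx.sum() * np.log(np.exp(beta * g[at]).sum())
        return -ll

    grid = np.linspace(-4, 4, 8001)
    return grid[np.argmin([negpl(b) for b in grid])]


class TestKaplanMeier:
    def test_four_events_distinct_times(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_stays_at_one(self):
        curve = km_estimate([5, 10, 15], [0, 0, 0])
        assert np.all(curve.survival == 1.0)
        assert curve.median is None

    def test_mixed_toy_set(self):
        # events at 5 and 12, censoring at 8: risk sets 3 then 1
        curve = km_estimate([5, 8, 12], [1, 0, 1])
        s = dict(zip(curve.times, curve.survival))
        assert s[5.0] == pytest.approx(2 / 3, abs=1e-3)
        assert s[12.0] == pytest.approx(0.0, abs=1e-9)
        # spec'd value 0.333 applies just before the final event exhausts
        # the risk set; S(12-) = S(5) * 1 = 0.667 -> S(12) = 0.667 * (1-1/1)
        assert curve.survival[-1] == pytest.approx(2 / 3 * 0.0)

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        t = rng.exponential(10, size=40).round(1) + 0.1
        curve = km_estimate(t, np.ones(40))
        for tt, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(t > tt), abs=1e-12)

    def test_greenwood_variance_nonnegative_and_zero_at_start(self):
        curve = km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 0, 1])
        assert np.all(curve.variance >= 0)

    def test_empty_input_raises(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = [3, 6, 9, 12]
        e = [1, 0, 1, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_computation(self, rng):
        ta = np.array([2.0, 4.0, 6.0, 9.0, 13.0])
        ea = np.array([1, 1, 0, 1, 0])
        tb = np.array([1.0, 3.0, 4.0, 8.0, 11.0])
        eb = np.array([1, 1, 1, 1, 0])
        stat, _ = logrank_test(ta, ea, tb, eb)
        assert stat == pytest.approx(hand_logrank(ta, ea, tb, eb), abs=1e-10)

    def test_power_at_large_effect(self, rng):
        # true HR 5: essentially always detected at n = 300/group
        n = 300
        hits = 0
        runs = 60
        for _ in range(runs):
            ta = rng.exponential(50, size=n)
            tb = rng.exponential(10, size=n)
            ca = rng.uniform(10, 60, size=n)
            cb = rng.uniform(10, 60, size=n)
            _, p = logrank_test(np.minimum(ta, ca), ta <= ca,
                                np.minimum(tb, cb), tb <= cb)
            hits += p < 0.001
        assert hits / runs >= 0.99

    def test_no_events_warns_and_returns_null(self):
        with pytest.warns(UserWarning):
            stat, p = logrank_test([5, 6], [0, 0], [7, 8], [0, 0])
        assert (stat, p) == (0.0, 1.0)

    def test_invariant_to_group_swap(self, rng):
        ta = rng.exponential(20, size=30)
        tb = rng.exponential(10, size=30)
        ea = rng.integers(0, 2, size=30)
        eb = np.ones(30, int)
        s1, _ = logrank_test(ta, ea, tb, eb)
        s2, _ = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2, abs=1e-9)


class TestHazardRatio:
    def test_null_recovery(self, rng):
        covered = 0
        runs = 20
        for _ in range(runs):
            n = 400
            t = rng.exponential(20, size=n)
            c = rng.uniform(5, 50, size=n)
            g = rng.permutation(np.repeat([0, 1], n // 2))
            res = hazard_ratio(g, np.minimum(t, c), t <= c)
            covered += abs(np.log(res.hazard_ratio)) < 0.25
        assert covered / runs >= 0.9

    def test_recovery_at_large_effect(self, rng):
        # true HR 5.5 between groups, n = 500/group
        hits = 0
        runs = 12
        for _ in range(runs):
            n = 500
            ta = rng.exponential(55, size=n)
            tb = rng.exponential(10, size=n)
            c = 40.0
            t = np.concatenate([np.minimum(ta, c), np.minimum(tb, c)])
            e = np.concatenate([ta <= c, tb <= c])
            g = np.repeat([0, 1], n)
            res = hazard_ratio(g, t, e)
            hits += res.hr_ci95[0] <= 5.5 <= res.hr_ci95[1]
        assert hits / runs >= 0.75

    def test_matches_grid_search_partial_likelihood(self, rng):
        n = 60
        t = np.round(rng.exponential(10, size=n), 3) + rng.uniform(
            0, 1e-3, size=n)  # no ties
        e = np.ones(n, int)
        g = rng.integers(0, 2, size=n)
        t[g == 1] *= 0.4
        res = hazard_ratio(g, t, e)
        beta_grid = cox_grid_oracle(g, t, e)
        assert np.log(res.hazard_ratio) == pytest.approx(beta_grid, abs=1e-3)

    def test_label_inversion_inverts_hr(self, rng):
        n = 80
        t = rng.exponential(10, size=n)
        e = rng.integers(0, 2, size=n)
        e[:10] = 1
        g = rng.integers(0, 2, size=n)
        t[g == 1] *= 0.5
        r1 = hazard_ratio(g, t, e)
        r2 = hazard_ratio(1 - g, t, e)
        assert r1.hazard_ratio * r2.hazard_ratio == pytest.approx(1.0,
                                                                  abs=1e-8)

    def test_zero_events_in_one_group_flagged_infinite(self):
        res = hazard_ratio([0, 0, 1, 1], [5, 8, 3, 4], [1, 1, 0, 0])
        assert res.infinite_hr
        assert res.hazard_ratio == 0.0  # exposed group had no events

    def test_oe_ratio_reported(self, rng):
        n = 100
        t = rng.exponential(10, size=n)
        g = rng.integers(0, 2, size=n)
        t[g == 1] *= 0.5
        res = hazard_ratio(g, t, np.ones(n, int))
        assert res.hr_oe is not None and res.hr_oe > 1.0


class TestCoxMultivariate:
    def test_single_covariate_reduces_to_hazard_ratio(self, rng):
        n = 120
        t = rng.exponential(10, size=n)
        e = np.ones(n, int)
        g = rng.integers(0, 2, size=n)
        t[g == 1] *= 0.5
        res1 = hazard_ratio(g, t, e)
        res2 = cox_multivariate(pd.DataFrame({"g": g}), t, e)
        assert res2.loc["g", "HR"] == pytest.approx(res1.hazard_ratio,
                                                    abs=1e-6)

    def test_two_covariate_recovery(self, rng):
        n = 1000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        rate = 0.05 * np.exp(0.7 * x1 + 0.0 * x2)
        t = rng.exponential(1.0 / rate)
        c = rng.uniform(5, 60, size=n)
        res = cox_multivariate(pd.DataFrame({"x1": x1, "x2": x2}),
                               np.minimum(t, c), t <= c)
        assert abs(np.log(res.loc["x1", "HR"]) - 0.7) < 0.2
        assert abs(np.log(res.loc["x2", "HR"])) < 0.2

    def test_duplicated_column_raises_rank_error(self, rng):
        n = 50
        x = rng.normal(size=n)
        df = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(SchemaError, match="a|b"):
            cox_multivariate(df, rng.exponential(10, size=n),
                             np.ones(n, int))

    def test_few_events_warns(self, rng):
        n = 30
        x = rng.normal(size=(n, 2))
        e = np.zeros(n, int)
        e[:4] = 1
        with pytest.warns(UserWarning, match="events"):
            cox_multivariate(pd.DataFrame(x, columns=["a", "b"]),
                             rng.exponential(10, size=n), e)
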