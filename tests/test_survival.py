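"""Kaplan-Meier estimation, log-rank, median splits and fixed-horizon Z-tests."""

import numpy as np
import pytest

from seedgcn.surv import (
    combined_group,
    dichotomize_by_median,
    km_estimate,
    logrank,
    os_rate_ztest,
    survival_at,
)

from oracles import spreadsheet_km

import pandas as pd


class TestDichotomize:
    def test_even_n_median(self):
        s = dichotomize_by_median([1, 2, 3, 4], list("abcd"))
        assert list(s) == ["low", "low", "high", "high"]

    def test_tie_at_median_goes_low(self):
        s = dichotomize_by_median([1, 2, 2, 3], list("abcd"))
        assert list(s) == ["low", "low", "low", "high"]

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            dichotomize_by_median([2, 2, 2])


class TestKaplanMeier:
    def test_hand_product_limit(self):
        c = km_estimate([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(c.s, [2 / 3, 0.0])
        assert survival_at(c, 2.5) == (pytest.approx(2 / 3), pytest.approx(c.var[0]))

    def test_all_censored_flat_curve(self):
        c = km_estimate([1, 2, 3], [0, 0, 0])
        assert c.times.size == 0
        assert survival_at(c, 10) == (1.0, 0.0)

    def test_single_event_drops_to_zero(self):
        c = km_estimate([5.0], [1])
        assert survival_at(c, 5.0) == (0.0, 0.0)
        assert survival_at(c, 4.9) == (1.0, 0.0)

    def test_censoring_tie_counted_at_risk(self):
        # censored exactly at the event time stays in the risk set for it
        c = km_estimate([2, 2, 3], [1, 0, 1])
        assert c.at_risk[0] == 3

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_spreadsheet_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        time = np.round(rng.exponential(3, n), 1) + 0.1
        event = rng.integers(0, 2, n)
        if event.sum() == 0:
            event[0] = 1
        c = km_estimate(time, event)
        ref = spreadsheet_km(time, event)
        assert len(ref) == c.times.size
        for i, (t, nn, d, s, v) in enumerate(ref):
            assert c.times[i] == t and c.at_risk[i] == nn and c.deaths[i] == d
            assert c.s[i] == pytest.approx(s, abs=1e-10)
            assert c.var[i] == pytest.approx(v, abs=1e-10)

    def test_monotone_nonincreasing_and_variance_nonnegative(self, rng):
        time = rng.exponential(3, 50)
        event = rng.integers(0, 2, 50)
        c = km_estimate(time, event)
        assert np.all(np.diff(c.s) <= 1e-12)
        assert np.all(c.var >= 0)
        assert np.all(np.diff(c.at_risk) < 0)


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 0]
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_strong_hazard_ratio_detected(self, rng):
        a = rng.exponential(1.0, 100)
        b = rng.exponential(5.0, 100)
        _, p = logrank(a, np.ones(100, int), b, np.ones(100, int))
        assert p < 1e-3

    def test_symmetry_and_time_rescaling(self, rng):
        a = rng.exponential(1.0, 40)
        b = rng.exponential(2.0, 40)
        ea = rng.integers(0, 2, 40)
        eb = rng.integers(0, 2, 40)
        if ea.sum() + eb.sum() == 0:
            ea[0] = 1
        c1, p1 = logrank(a, ea, b, eb)
        c2, p2 = logrank(b, eb, a, ea)
        assert c1 == pytest.approx(c2) and p1 == pytest.approx(p2)
        c3, _ = logrank(a * 12, ea, b * 12, eb)
        assert c3 == pytest.approx(c1)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank([1, 2], [0, 0], [3, 4], [0, 0])


class TestCombinedGroup:
    def test_definitions(self):
        idx = pd.Index(list("abcd"))
        seed = pd.Series(["high", "high", "low", "low"], index=idx)
        partner = pd.Series(["high", "low", "high", "low"], index=idx)
        g = combined_group(seed, partner)
        assert list(g) == ["HH", "others", "others", "others"]

    def test_independent_markers_quarter_fraction(self, rng):
        n = 20000
        idx = pd.Index(range(n))
        a = pd.Series(np.where(rng.uniform(size=n) > 0.5, "high", "low"), index=idx)
        b = pd.Series(np.where(rng.uniform(size=n) > 0.5, "high", "low"), index=idx)
        frac = (combined_group(a, b) == "HH").mean()
        assert frac == pytest.approx(0.25, abs=0.02)


class TestOsRateZtest:
    def test_identical_groups_z_zero(self):
        t = [1, 2, 4, 6, 8]
        e = [1, 0, 1, 0, 1]
        res = os_rate_ztest(t, e, t, e, horizon=5)
        assert res["z"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_worked_ten_patient_groups(self):
        # group A: deaths at 1 and 2 with 10 at risk -> S(3) = 0.9*8/9 = 0.8
        ta = [1, 2, 3.5, 4, 5, 6, 7, 8, 9, 10]
        ea = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]
        # group B: death at 1 of 10 -> S(3) = 0.9
        tb = [1, 3.5, 4, 5, 6, 7, 8, 9, 10, 11]
        eb = [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        sa = 0.9 * (8 / 9)
        va = sa ** 2 * (1 / (10 * 9) + 1 / (9 * 8))
        sb = 0.9
        vb = sb ** 2 * (1 / (10 * 9))
        z = (sa - sb) / np.sqrt(va + vb)
        res = os_rate_ztest(ta, ea, tb, eb, horizon=3)
        assert res["rate_a"] == pytest.approx(sa, abs=1e-10)
        assert res["rate_b"] == pytest.approx(sb, abs=1e-10)
        assert res["z"] == pytest.approx(z, abs=1e-10)

    def test_horizon_beyond_followup_rejected(self):
        with pytest.raises(ValueError, match="follow-up"):
            os_rate_ztest([1, 2], [1, 0], [1, 2, 3], [1, 0, 0], horizon=2.5)

    def test_no_events_before_horizon_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            os_rate_ztest([5, 6], [1, 0], [7, 8], [1, 0], horizon=3)


def test_km_matches_lifelines_reference(rng):
    """Cross-check the product-limit curve against an independent library fit."""
    from lifelines import KaplanMeierFitter
    time = rng.exponential(3, 80)
    event = rng.integers(0, 2, 80)
    c = km_estimate(time, event)
    kmf = KaplanMeierFitter().fit(time, event)
    for t in c.times:
        s_ref = float(kmf.survival_function_at_times(t).iloc[0])
        assert survival_at(c, t)[0] == pytest.approx(s_ref, abs=1e-10)
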