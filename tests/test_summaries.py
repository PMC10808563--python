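"""Effort-table arithmetic, monthly pooling, and the low-precipitation threshold."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from rainlag import summaries
from rainlag.datamodel import TrapEvent
from rainlag.lags import LAG_COLUMNS


def _threshold_matrix(cum20, counts):
    df = pd.DataFrame({"trap_id": [f"T{i}" for i in range(len(cum20))],
                       "female_count": counts})
    df["presence"] = df["female_count"] >= 1
    for c in LAG_COLUMNS:
        df[c] = 0.0
    df["lag1"] = np.asarray(cum20, float)
    df["cum10"] = df["lag1"]
    df["cum20"] = df["lag1"]
    return df


class TestSummarizeEffort:
    def test_group_row_arithmetic(self, published_effort_events):
        table = summaries.summarize_effort(published_effort_events)
        r2014 = table[(table["year"] == "2014") & (table["trap_type"] == "CO2")].iloc[0]
        assert r2014["n_surveys"] == 28131
        assert r2014["n_nonzero"] == 3951
        assert r2014["pct_nonzero"] == 14.0  # 3951/28131 = 14.045 -> 14.0
        assert r2014["n_mosquitoes"] == 39915
        assert r2014["n_females"] == 27208
        assert r2014["pct_females"] == 68.2
        r2016 = table[(table["year"] == "2016") & (table["trap_type"] == "CO2")].iloc[0]
        assert r2016["pct_females"] == 72.7

    def test_totals_row_additivity(self, published_effort_events):
        table = summaries.summarize_effort(published_effort_events)
        totals = table[table["year"] == "Totals"].iloc[0]
        groups = table[table["year"] != "Totals"]
        assert totals["n_surveys"] == groups["n_surveys"].sum() == 100757
        assert totals["n_nonzero"] == groups["n_nonzero"].sum() == 16667
        assert totals["n_mosquitoes"] == groups["n_mosquitoes"].sum() == 122257
        assert totals["n_females"] == groups["n_females"].sum() == 83749
        assert totals["pct_females"] == 68.5
        assert totals["pct_nonzero"] == 16.5
        assert totals["n_female_positive"] == 15882
        assert totals["pct_female_positive"] == 15.8

    def test_percentages_rederive_from_integers(self, published_effort_events):
        table = summaries.summarize_effort(published_effort_events)
        for _, row in table.iterrows():
            if row["n_mosquitoes"]:
                assert row["pct_females"] == summaries.round_half_away(
                    100 * row["n_females"] / row["n_mosquitoes"], 1)

    def test_empty_group_percent_nan(self):
        ev = TrapEvent("T1", -112.0, 33.3, "CO2", dt.date(2015, 3, 1), 0, 0)
        table = summaries.summarize_effort([ev])
        row = table.iloc[0]
        assert row["n_mosquitoes"] == 0
        assert np.isnan(row["pct_females"])


class TestMonthlyActivity:
    def _ev(self, month, females, year=2015):
        return TrapEvent("T1", -112.0, 33.3, "CO2",
                         dt.date(year, month, 10), females, 0)

    def test_single_month_population(self):
        acts = summaries.monthly_activity([self._ev(7, 4), self._ev(7, 0)])
        assert acts[7]["nonzero_counts"] == [4]
        assert acts[7]["n_zero"] == 1
        assert all(acts[m]["nonzero_counts"] == [] and acts[m]["n_zero"] == 0
                   for m in range(1, 13) if m != 7)

    def test_march_zeroes_separated(self):
        acts = summaries.monthly_activity(
            [self._ev(3, 0), self._ev(3, 3), self._ev(3, 10)])
        assert acts[3]["nonzero_counts"] == [3, 10]
        assert acts[3]["n_zero"] == 1

    def test_years_pool_into_calendar_month(self):
        acts = summaries.monthly_activity(
            [self._ev(12, 2, year=2014), self._ev(12, 5, year=2015)])
        assert acts[12]["nonzero_counts"] == [2, 5]


class TestLowPrecipThreshold:
    def test_planted_plateau_with_published_shape(self):
        """Constructed data: max count 175 for cum20 <= 0.02, jumping at 0.03."""
        rng = np.random.default_rng(0)
        n = 2000
        cum = rng.uniform(0, 0.5, n)
        counts = np.minimum(rng.poisson(20, n), 175)
        counts[np.argmin(cum)] = 175      # plateau value realized from the start
        above = cum > 0.025               # falls in the 0.03 grid step and beyond
        counts[above] = 190 + rng.poisson(10, int(above.sum()))
        df = _threshold_matrix(cum, counts)
        res = summaries.find_low_precip_threshold(df, tolerance=0.05)
        assert res.threshold == pytest.approx(0.02)
        assert res.max_count_below == 175
        assert 0 < res.pct_events_below < 100
        assert 0 < res.pct_females_below < 100

    def test_identical_counts_flat_everywhere(self):
        rng = np.random.default_rng(1)
        cum = rng.uniform(0, 0.5, 300)
        df = _threshold_matrix(cum, np.full(300, 7))
        res = summaries.find_low_precip_threshold(df, tolerance=0.0)
        assert res.threshold == pytest.approx(0.50)
        assert res.pct_events_below == pytest.approx(100.0)

    def test_event_order_invariance(self):
        rng = np.random.default_rng(2)
        cum = rng.uniform(0, 0.4, 500)
        counts = np.minimum(rng.poisson(6, 500), 12)
        counts[cum > 0.1] += np.round(100 * (cum[cum > 0.1] - 0.1)).astype(int)
        df = _threshold_matrix(cum, counts)
        res1 = summaries.find_low_precip_threshold(df)
        res2 = summaries.find_low_precip_threshold(
            df.sample(frac=1.0, random_state=9).reset_index(drop=True))
        assert res1.threshold == res2.threshold
        assert res1.pct_females_below == pytest.approx(res2.pct_females_below)

    def test_breakpoint_recovery_over_seeds(self):
        """Planted plateau break at t0: recovered within one grid step in
        >= 9/10 seeds."""
        t0 = 0.06
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 5000
            cum = rng.uniform(0, 0.5, n)
            counts = np.minimum(rng.poisson(6, n), 12)
            above = cum > t0
            counts[above] = 13 + rng.poisson(30 * (cum[above] - t0))
            df = _threshold_matrix(cum, counts)
            res = summaries.find_low_precip_threshold(df, tolerance=0.05)
            if abs(res.threshold - t0) <= 0.01 + 1e-9:
                hits += 1
        assert hits >= 9

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        cum = rng.uniform(0, 0.3, 400)
        counts = rng.poisson(3, 400)
        df = _threshold_matrix(cum, counts)
        fracs = [summaries.anthropogenic_fraction(df, t)
                 for t in (0.05, 0.1, 0.2, 0.3)]
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_no_events_below_grid_rejected(self):
        df = _threshold_matrix([1.0, 2.0, 3.0], [1, 2, 3])
        with pytest.raises(ValueError, match="below"):
            summaries.find_low_precip_threshold(df, candidate_grid=[0.01, 0.02])


class TestAnthropogenicFraction:
    def test_all_below(self):
        df = _threshold_matrix([0.0, 0.01], [3, 7])
        assert summaries.anthropogenic_fraction(df, 0.02) == 100.0

    def test_none_below(self):
        df = _threshold_matrix([0.5, 0.6], [3, 7])
        assert summaries.anthropogenic_fraction(df, 0.02) == 0.0

    def test_planted_ten_percent(self):
        """90 females in wet-window events, 10 in dry-window events -> 10%."""
        cum = np.concatenate([np.full(10, 0.01), np.full(90, 0.3)])
        counts = np.concatenate([np.ones(10, int), np.ones(90, int) * 1])
        df = _threshold_matrix(cum, counts)
        assert summaries.anthropogenic_fraction(df, 0.02) == pytest.approx(10.0)

    def test_zero_total_rejected(self):
        df = _threshold_matrix([0.1, 0.2], [0, 0])
        with pytest.raises(ValueError):
            summaries.anthropogenic_fraction(df, 0.02)
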