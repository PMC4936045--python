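"""Telemetry preparation: DOP filter, fix rates, end dates, truncation, clusters."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bearshield import (
    assign_end_dates,
    compute_fix_rate,
    detect_clusters,
    filter_dop,
    truncate_period,
    welch_t_test,
)
from bearshield.telemetry import BearYearRecord


def _fixes(dops, start="2008-05-01"):
    n = len(dops)
    return pd.DataFrame(
        {
            "timestamp": pd.date_range(start, periods=n, freq="30min"),
            "x": np.zeros(n),
            "y": np.zeros(n),
            "dop": np.asarray(dops, dtype=float),
        }
    )


class TestDopFilter:
    def test_boundary_value_removed(self):
        out = filter_dop(_fixes([2.0, 4.9, 5.0, 7.0]))
        assert out["dop"].tolist() == [2.0, 4.9]

    def test_all_good_is_identity(self):
        fixes = _fixes([1.0, 2.0, 3.0])
        pd.testing.assert_frame_equal(filter_dop(fixes), fixes)

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(0)
        dops = rng.uniform(0.5, 10.0, 10_000)
        out = filter_dop(_fixes(dops))
        assert len(out) == int(np.sum(dops < 5.0))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0.1, max_value=12.0), max_size=60))
    def test_idempotent(self, dops):
        once = filter_dop(_fixes(dops))
        twice = filter_dop(once)
        pd.testing.assert_frame_equal(once, twice)


class TestFixRate:
    def test_complete_schedule(self):
        day = (dt.date(2008, 5, 1), dt.date(2008, 5, 1))
        assert compute_fix_rate(_fixes(np.ones(48)), day) == 1.0

    def test_half_schedule(self):
        day = (dt.date(2008, 5, 1), dt.date(2008, 5, 1))
        assert compute_fix_rate(_fixes(np.ones(24)), day) == 0.5

    def test_random_deletion_binomial(self):
        rng = np.random.default_rng(1)
        n_expected = 30 * 48
        keep = rng.random(n_expected) < 0.6
        period = (dt.date(2008, 5, 1), dt.date(2008, 5, 30))
        rate = compute_fix_rate(_fixes(np.ones(int(keep.sum()))), period)
        se = np.sqrt(0.6 * 0.4 / n_expected)
        assert abs(rate - 0.6) < 3 * se

    def test_empty_period_raises(self):
        with pytest.raises(ValueError, match="empty"):
            compute_fix_rate(_fixes([1.0]), (dt.date(2008, 5, 2), dt.date(2008, 5, 1)))


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        a, b = [1.0, 2, 3, 4], [1.0, 2, 3, 4, 5, 6]
        t, df, p = welch_t_test(a, b)
        # independent closed-form oracle
        ma, mb = np.mean(a), np.mean(b)
        sa, sb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        t0 = (ma - mb) / np.sqrt(sa + sb)
        df0 = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
        from scipy import stats

        assert t == pytest.approx(t0, abs=1e-10)
        assert df == pytest.approx(df0, abs=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(abs(t0), df0), abs=1e-10)

    def test_antisymmetric_in_sample_order(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 9), rng.normal(0.5, 2, 14)
        t1, _, p1 = welch_t_test(a, b)
        t2, _, p2 = welch_t_test(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_agrees_with_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.3, 1.7, 20)
        t, df, p = welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


def _bear_year(fixes, fate="survived", loss=None, end=None):
    return BearYearRecord(
        bear_id="B1", year=2008, fixes=fixes, fate=fate, loss_date=loss, end_date=end
    )


class TestEndDates:
    SEASON = (dt.date(2008, 5, 1), dt.date(2008, 6, 16))

    def _records(self, n):
        return [_bear_year(_fixes([1.0])) for _ in range(n)]

    def test_single_event_degenerate(self):
        out = assign_end_dates(self._records(10), [dt.date(2008, 5, 8)], self.SEASON, seed=1)
        assert all(r.end_date == dt.date(2008, 5, 8) for r in out)

    def test_draws_respect_season_bounds(self):
        events = [dt.date(2008, 5, 8), dt.date(2008, 6, 16), dt.date(2008, 5, 20)]
        out = assign_end_dates(self._records(400), events, self.SEASON, seed=2)
        for r in out:
            assert self.SEASON[0] <= r.end_date <= self.SEASON[1]

    def test_mass_ratio_follows_event_weights(self):
        """3 events on 10 May vs 1 on 1 June -> ~3x the sampled mass nearby."""
        events = [dt.date(2008, 5, 10)] * 3 + [dt.date(2008, 6, 1)]
        out = assign_end_dates(self._records(2_500), events, self.SEASON, seed=3)
        days = np.array([(r.end_date - dt.date(2008, 5, 10)).days for r in out])
        near_first = np.sum(np.abs(days) <= 8)
        near_second = np.sum(np.abs(days - 22) <= 8)
        ratio = near_first / near_second
        assert 2.2 <= ratio <= 3.8

    def test_reproducible_with_seed(self):
        events = [dt.date(2008, 5, 10), dt.date(2008, 6, 1)]
        a = assign_end_dates(self._records(20), events, self.SEASON, seed=9)
        b = assign_end_dates(self._records(20), events, self.SEASON, seed=9)
        assert [r.end_date for r in a] == [r.end_date for r in b]

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="loss events"):
            assign_end_dates(self._records(1), [], self.SEASON, seed=0)


class TestTruncation:
    def test_lost_mother_window_ends_at_loss(self):
        fixes = _fixes(np.ones(48 * 20), start="2008-04-28")
        rec = _bear_year(fixes, fate="lost", loss=dt.date(2008, 5, 8))
        out = truncate_period(rec, truncation_date=dt.date(2008, 6, 16))
        dates = out.fixes["timestamp"].dt.date
        assert dates.min() >= dt.date(2008, 5, 1)
        assert dates.max() <= dt.date(2008, 5, 8)
        assert out.n_fixes <= rec.n_fixes

    def test_survivor_window_closed_at_end_date(self):
        fixes = _fixes(np.ones(48 * 50), start="2008-05-01")
        rec = _bear_year(fixes, end=dt.date(2008, 6, 16))
        out = truncate_period(rec, truncation_date=dt.date(2008, 6, 16))
        assert out.fixes["timestamp"].dt.date.max() == dt.date(2008, 6, 16)

    def test_april_only_fixes_all_removed(self):
        fixes = _fixes(np.ones(48), start="2008-04-10")
        rec = _bear_year(fixes, end=dt.date(2008, 6, 1))
        out = truncate_period(rec, truncation_date=dt.date(2008, 6, 16))
        assert out.n_fixes == 0

    def test_partial_loss_excluded_with_reason(self):
        rec = _bear_year(_fixes([1.0]), fate="partial_loss")
        with pytest.raises(ValueError, match="partial litter loss"):
            truncate_period(rec, truncation_date=dt.date(2008, 6, 16))


class TestClusters:
    def _record(self, xy):
        xy = np.asarray(xy, dtype=float)
        fixes = pd.DataFrame(
            {
                "timestamp": pd.date_range("2008-05-01", periods=len(xy), freq="30min"),
                "x": xy[:, 0],
                "y": xy[:, 1],
                "dop": 1.0,
            }
        )
        return _bear_year(fixes)

    def test_three_coincident_points_form_cluster(self):
        out = detect_clusters(self._record([[0, 0]] * 3))
        assert len(out) == 1 and out[0].size == 3

    def test_spread_points_form_none(self):
        out = detect_clusters(self._record([[0, 0], [20, 0], [40, 0], [60, 0]]))
        assert out == []

    def test_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(5)
        xy = np.cumsum(rng.normal(0, 12, size=(200, 2)), axis=0)
        got = detect_clusters(self._record(xy))

        # oracle: independent forward scan recomputing each window from scratch
        def window_ok(i, j):
            c = xy[i:j].mean(axis=0)
            return np.hypot(*(xy[i:j] - c).T).max() <= 15.0

        expected = []
        i = 0
        while i < len(xy):
            j = i + 1
            while j < len(xy) and window_ok(i, j + 1):
                j += 1
            if j - i >= 3:
                expected.append(tuple(range(i, j)))
                i = j
            else:
                i += 1
        assert [c.member_indices for c in got] == expected

    def test_first_fix_rule_variant(self):
        # drifting run: ok about the first fix, not about the centroid
        xy = [[0, 0], [14, 0], [14, 5], [14, -5]]
        got = detect_clusters(self._record(xy), about="first")
        assert len(got) == 1 and got[0].size == 4
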