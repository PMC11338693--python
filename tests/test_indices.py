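"""Abundance index, proximity clustering, group series and growth rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from martendyn import (
    GroupSeries,
    abundance_index,
    cluster_transects,
    eligible_series,
    group_mean_series,
    growth_rates,
)


class TestAbundanceIndex:
    @pytest.mark.parametrize(
        "tracks,length,days,expected",
        [
            (0, 3.0, 2.0, 0.0),
            (6, 3.0, 2.0, 1.0),
            (4, 2.93, 3.70, 4 / (2.93 * 3.70)),
        ],
    )
    def test_examples(self, tracks, length, days, expected):
        assert abundance_index(tracks, length, days) == pytest.approx(expected)

    @pytest.mark.parametrize("length,days", [(0.0, 2.0), (-1.0, 2.0), (3.0, 0.0)])
    def test_nonpositive_effort_rejected(self, length, days):
        with pytest.raises(ValueError):
            abundance_index(1, length, days)

    @given(
        tracks=st.integers(0, 1000),
        length=st.floats(0.1, 50.0),
        days=st.floats(0.5, 30.0),
        a=st.floats(0.5, 4.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_homogeneity_in_effort(self, tracks, length, days, a):
        # index scales exactly as 1/length and 1/days
        base = abundance_index(tracks, length, days)
        assert abundance_index(tracks, a * length, days) == pytest.approx(base / a)
        assert abundance_index(tracks, length, a * days) == pytest.approx(base / a)


def _records(coords, years=(2003,), tracks=1, length=1.0, days=1.0):
    rows = []
    for i, (x, y) in enumerate(coords):
        for yr in years:
            rows.append((f"T{i:03d}", yr, x, y, length, days, tracks))
    return pd.DataFrame(
        rows,
        columns=["transect_id", "year", "x_km", "y_km", "length_km", "days_since_snow", "tracks"],
    )


class TestClustering:
    def test_small_input_single_group(self):
        rec = _records([(i, i) for i in range(10)])
        assignment = cluster_transects(rec, target_group_size=10, seed=0)
        assert len(set(assignment.values())) == 1
        assert set(assignment) == set(rec["transect_id"])

    def test_two_separated_clumps_recovered(self):
        rng = np.random.default_rng(0)
        clump_a = [(x, y) for x, y in rng.normal(0, 0.5, (10, 2))]
        clump_b = [(x + 100, y) for x, y in rng.normal(0, 0.5, (10, 2))]
        rec = _records(clump_a + clump_b)
        assignment = cluster_transects(rec, target_group_size=10, seed=0)
        groups_a = {assignment[f"T{i:03d}"] for i in range(10)}
        groups_b = {assignment[f"T{i:03d}"] for i in range(10, 20)}
        assert len(groups_a) == 1 and len(groups_b) == 1 and groups_a != groups_b

    def test_repeat_with_same_seed_identical(self):
        rng = np.random.default_rng(1)
        rec = _records([tuple(p) for p in rng.uniform(0, 50, (60, 2))])
        a = cluster_transects(rec, 10, seed=7)
        b = cluster_transects(rec, 10, seed=7)
        assert a == b

    def test_fewer_than_target_warns(self):
        rec = _records([(i, 0) for i in range(4)])
        with pytest.warns(UserWarning, match="single group"):
            assignment = cluster_transects(rec, target_group_size=10, seed=0)
        assert len(set(assignment.values())) == 1


class TestGroupSeries:
    def test_single_transect_group_equals_own_index_series(self):
        rec = _records([(0, 0)], years=(2003, 2004, 2005), tracks=2, length=2.0, days=1.0)
        series = group_mean_series(rec, {"T000": "G1"})
        assert len(series) == 1
        assert np.allclose(series[0].mean_index, 1.0)

    def test_mean_of_two_members(self):
        rec = pd.DataFrame(
            {
                "transect_id": ["A", "B"],
                "year": [2003, 2003],
                "x_km": [0, 1],
                "y_km": [0, 0],
                "length_km": [1.0, 1.0],
                "days_since_snow": [1.0, 1.0],
                "tracks": [0.2, 0.4],
            }
        )
        series = group_mean_series(rec, {"A": "G", "B": "G"})
        assert series[0].mean_index[0] == pytest.approx(0.3)

    def test_gap_year_splits_into_runs(self):
        rec = _records([(0, 0)], years=(2007, 2008, 2010, 2011))
        series = group_mean_series(rec, {"T000": "G"})
        runs = series[0].runs()
        assert [list(r.years) for r in runs] == [[2007, 2008], [2010, 2011]]

    def test_grand_mean_of_equal_size_groups_equals_overall_mean(self):
        rng = np.random.default_rng(2)
        rec = _records([(i, 0) for i in range(8)], years=(2003,))
        rec["tracks"] = rng.integers(0, 10, len(rec))
        assignment = {f"T{i:03d}": f"G{i // 4}" for i in range(8)}
        series = group_mean_series(rec, assignment)
        grand = np.mean([s.mean_index[0] for s in series])
        overall = (rec["tracks"] / (rec["length_km"] * rec["days_since_snow"])).mean()
        assert grand == pytest.approx(overall)

    def test_uncovered_transect_rejected(self):
        rec = _records([(0, 0), (1, 1)])
        with pytest.raises(ValueError, match="does not cover"):
            group_mean_series(rec, {"T000": "G"})


class TestGrowthRates:
    def _series(self, values, years=None):
        values = np.asarray(values, dtype=float)
        years = np.arange(2003, 2003 + len(values)) if years is None else np.asarray(years)
        return GroupSeries("G", frozenset({"T"}), years, values)

    def test_no_change_zero_rate(self):
        out = growth_rates(self._series([2.0, 2.0]))
        assert out.growth_rate[1] == pytest.approx(0.0)

    def test_e_fold_increase_rate_one(self):
        out = growth_rates(self._series([1.0, np.e]))
        assert out.growth_rate[1] == pytest.approx(1.0)

    def test_half_min_zero_policy(self):
        # zeros shifted by half the smallest positive value (0.5 here)
        out = growth_rates(self._series([0.0, 1.0, 0.0]))
        assert out.growth_rate[1] == pytest.approx(np.log(3))
        assert out.growth_rate[2] == pytest.approx(-np.log(3))

    def test_all_zero_series_error_names_series(self):
        with pytest.raises(ValueError, match="all-zero"):
            growth_rates(self._series([0.0, 0.0]))

    def test_rate_not_defined_across_gap(self):
        out = growth_rates(self._series([1.0, 2.0, 3.0], years=[2003, 2004, 2006]))
        assert np.isfinite(out.growth_rate[1])
        assert np.isnan(out.growth_rate[2])

    def test_cumulative_sum_inverts_to_log_index(self):
        rng = np.random.default_rng(3)
        n = rng.uniform(0.1, 5.0, 12)
        out = growth_rates(self._series(n))
        recon = np.log(n[0]) + np.concatenate([[0.0], np.cumsum(out.growth_rate[1:])])
        assert np.allclose(recon, np.log(n))


class TestEligibleSeries:
    def _series(self, years):
        years = np.asarray(years)
        return GroupSeries("G", frozenset(), years, np.ones(len(years)))

    def test_run_of_three_excluded_run_of_four_included(self):
        # ">3 time-steps" is strict: exactly 3 observations do not qualify
        assert eligible_series([self._series([2003, 2004, 2005])], 3) == []
        out = eligible_series([self._series([2003, 2004, 2005, 2006])], 3)
        assert len(out) == 1

    def test_gap_split_before_filtering(self):
        s = self._series([2003, 2004, 2005, 2007, 2008, 2009, 2010])
        out = eligible_series([s], 3)
        assert len(out) == 1
        assert list(out[0].years) == [2007, 2008, 2009, 2010]

    def test_empty_input(self):
        assert eligible_series([], 3) == []
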