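"""Generator checks: dynamics, study-design moments, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal, stats

from martendyn import (
    SimConfig,
    build_world,
    municipality_index,
    simulate_marten_tracks,
    simulate_population_series,
    validate_against_traps,
    write_world,
)


class TestPopulationSeries:
    def test_zero_feedback_zero_noise_is_constant(self):
        x = simulate_population_series(1, (0.0, 0.0, 0.0), 0.0, 12, x0=1.0)
        assert np.allclose(x, 1.0)

    def test_negative_feedback_gives_negative_rate_autocorrelation(self):
        # direct density dependence makes the lag-1 autocorrelation of the
        # growth rate negative in expectation; at series length 30 the
        # Monte-Carlo sign check lands at 94/100, so assert a clear majority
        neg = 0
        for seed in range(100):
            x = simulate_population_series(1, (0.0, -0.6, 0.0), 0.2, 30, seed=seed)
            r = np.diff(x)
            rb = r - r.mean()
            if (rb[1:] * rb[:-1]).sum() / (rb**2).sum() < 0:
                neg += 1
        assert neg >= 90

    def test_second_order_dynamics_cycle_in_3_to_6_year_band(self):
        x = simulate_population_series(2, (0.0, -0.1, -0.6), 0.2, 200, seed=1)
        freqs, power = signal.periodogram(x - x.mean())
        peak = freqs[np.argmax(power[1:]) + 1]
        assert 1 / 6 <= peak <= 1 / 3

    def test_order1_requires_zero_b2(self):
        with pytest.raises(ValueError):
            simulate_population_series(1, (0.0, -0.5, 0.1), 0.1, 20)

    def test_unstable_roots_warn_but_run(self):
        with pytest.warns(UserWarning, match="diverge"):
            simulate_population_series(2, (0.0, 0.5, 0.8), 0.1, 20, seed=0)

    def test_deterministic_given_seed(self):
        a = simulate_population_series(2, (0.1, -0.2, -0.5), 0.3, 40, seed=9)
        b = simulate_population_series(2, (0.1, -0.2, -0.5), 0.3, 40, seed=9)
        assert np.array_equal(a, b)


class TestBuildWorld:
    def test_identical_config_identical_world(self, small_world):
        again = build_world(SimConfig(
            n_transects=150, n_municipalities=8, region_width_km=80.0,
            region_height_km=120.0, n_spruce_patches=120, n_agri_patches=90, seed=42,
        ))
        pd.testing.assert_frame_equal(small_world.transects, again.transects)
        assert np.array_equal(small_world.elevation.values, again.elevation.values)
        pd.testing.assert_frame_equal(small_world.rodent_surveys, again.rodent_surveys)

    def test_single_municipality_shares_one_rodent_series(self):
        cfg = SimConfig(n_transects=30, n_municipalities=1, n_spruce_patches=40,
                        n_agri_patches=30, seed=3)
        w = build_world(cfg)
        assert w.rodent_truth["municipality_id"].nunique() == 1
        assert w.transects["municipality_id"].nunique() == 1

    def test_effort_moments_match_survey_design(self, default_world):
        # unique transects carry the length draw; visits carry the days draw
        lengths = default_world.transects.drop_duplicates("transect_id")["length_km"]
        assert abs(lengths.mean() - 2.93) < 0.1
        assert abs(default_world.transects["days_since_snow"].mean() - 3.70) < 0.2

    def test_transects_inside_region(self, small_world):
        t = small_world.transects
        assert (t["x_km"] >= 0).all() and (t["x_km"] <= 80).all()
        assert (t["y_km"] >= 0).all() and (t["y_km"] <= 120).all()

    def test_every_year_present_for_every_municipality(self, small_world):
        counts = small_world.rodent_truth.groupby("municipality_id")["year"].count()
        assert (counts == len(small_world.config.rodent_years)).all()

    def test_amplitude_grows_with_elevation(self, default_world):
        # cycle amplitude scales with (1 + slope * z_elevation): variance of the
        # log-abundance series should rank-correlate with municipality elevation
        var = default_world.rodent_truth.groupby("municipality_id")["log_abundance"].var()
        elev = default_world.municipalities.set_index("municipality_id")["elevation_m"]
        rho = stats.spearmanr(var, elev.loc[var.index]).statistic
        assert rho > 0.3

    def test_degenerate_region_rejected(self):
        with pytest.raises(ValueError, match="positive area"):
            build_world(SimConfig(region_width_km=0.0))


class TestMartenTracks:
    def test_poisson_limit_offset_only_mean(self, small_world):
        # intercept 0, slopes 0, no year effects, Poisson limit: E[count] = length * days
        delta = np.zeros(7)
        counts, _ = simulate_marten_tracks(
            small_world, delta, np.inf, 1e-12, seed=1
        )
        expected = (
            small_world.transects["length_km"] * small_world.transects["days_since_snow"]
        )
        assert abs(counts.mean() / expected.mean() - 1) < 0.05

    def test_offset_contract_doubling_effort_quadruples_counts(self, small_world):
        import copy

        delta = np.zeros(7)
        base, _ = simulate_marten_tracks(small_world, delta, np.inf, 1e-12, seed=2)
        doubled = copy.copy(small_world)
        doubled.transects = small_world.transects.copy()
        doubled.transects["length_km"] *= 2
        doubled.transects["days_since_snow"] *= 2
        quad, _ = simulate_marten_tracks(doubled, delta, np.inf, 1e-12, seed=2)
        assert abs(quad.mean() / base.mean() - 4) < 0.2

    def test_negative_agri_slope_depresses_counts_across_quartiles(self):
        cfg = SimConfig(n_transects=500, n_municipalities=8, seed=6,
                        n_spruce_patches=150, n_agri_patches=120)
        w = build_world(cfg)
        delta = np.zeros(7)
        delta[6] = -0.5  # agri slope only
        counts, _ = simulate_marten_tracks(w, delta, np.inf, 1e-12, seed=6)
        df = w.transects.assign(c=counts)
        q = pd.qcut(df["z_agri_density"], 4, labels=False)
        means = df.groupby(q)["c"].mean()
        assert means.iloc[0] > means.iloc[-1]
        assert (np.diff(means) < 0).sum() >= 2  # overall decreasing trend

    def test_repeat_call_identical(self, small_world):
        a, _ = simulate_marten_tracks(small_world, np.zeros(7), 1.5, 0.2, seed=4)
        b, _ = simulate_marten_tracks(small_world, np.zeros(7), 1.5, 0.2, seed=4)
        assert np.array_equal(a, b)

    def test_bad_dispersion_rejected(self, small_world):
        with pytest.raises(ValueError):
            simulate_marten_tracks(small_world, np.zeros(7), -1.0, 0.2, seed=0)


class TestRodentSurveys:
    def test_zero_slope_detection_near_half(self, small_world):
        from martendyn import simulate_rodent_surveys

        surveys, _ = simulate_rodent_surveys(small_world, 200, 0.0, seed=1)
        prop = surveys["lines_with_detection"] / surveys["lines_total"]
        assert abs(prop.mean() - 0.5) < 0.02

    def test_steep_slope_saturates(self, small_world):
        from martendyn import simulate_rodent_surveys

        surveys, _ = simulate_rodent_surveys(small_world, 100, 50.0, seed=1)
        prop = surveys["lines_with_detection"] / surveys["lines_total"]
        assert ((prop > 0.95) | (prop < 0.05)).mean() > 0.9

    def test_index_tracks_snap_traps(self, default_world):
        ix = municipality_index(default_world.rodent_surveys)
        snap = default_world.snap_traps
        mid = snap["municipality_id"].iloc[0]
        series = ix[ix["municipality_id"] == mid].sort_values("year")
        r, _, _ = validate_against_traps(
            series["rodent_index"].to_numpy(),
            snap.sort_values("year")["catches_per_100_trapdays"].to_numpy(),
        )
        assert r > 0.6


def test_written_world_round_trips_and_is_reproducible(tmp_path, small_world):
    from martendyn import Raster

    d1 = tmp_path / "a"
    d2 = tmp_path / "b"
    write_world(small_world, d1)
    write_world(small_world, d2)
    for name in ("transects.csv", "rodent_surveys.csv", "truth.yaml", "elevation.asc"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
    dem = Raster.from_ascii(d1 / "elevation.asc")
    assert np.allclose(dem.values, small_world.elevation.values, atol=1e-6, rtol=1e-6)
    tr = pd.read_csv(d1 / "transects.csv")
    assert len(tr) == len(small_world.transects)
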