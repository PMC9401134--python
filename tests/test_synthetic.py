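"""Properties of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

from smokecast import fire
from smokecast.synthetic import (
    SimulationConfig,
    generate_dataset,
    generate_hotspots,
    generate_pm,
    generate_weather,
    simulation_days,
)


def daily_inland_speed(weather):
    inl = weather[weather["site"] == "inland"].pivot(
        index="timestamp", columns="variable", values="value"
    )
    inl.index = pd.to_datetime(inl.index)
    speed = np.hypot(inl["u"], inl["v"])
    label = inl.index.map(lambda t: (t - pd.Timedelta(hours=12)).date())
    return speed.groupby(label).mean()


def daily_vi(weather):
    west = weather[weather["site"] == "western"].pivot(
        index="timestamp", columns="variable", values="value"
    )
    west.index = pd.to_datetime(west.index)
    vi = np.hypot(west["u"], west["v"]) * west["pblh"]
    label = west.index.map(lambda t: (t - pd.Timedelta(hours=12)).date())
    return vi.groupby(label).mean()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_days": 1},
            {"n_days": 10, "gamma_shape": 0.0},
            {"n_days": 10, "vi_wind_corr_target": 1.0},
            {"n_days": 10, "hotspot_intensity": -1.0},
            {"n_days": 10, "missing_rate": 1.0},
        ],
    )
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_days_stay_in_burn_season(self):
        days = simulation_days(SimulationConfig(n_days=500, seed=0))
        assert all(3 <= d.month <= 9 for d in days)
        assert len(days) == 500


class TestWeather:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_days=30, seed=5)
        w1, w2 = generate_weather(cfg), generate_weather(cfg)
        pd.testing.assert_frame_equal(w1, w2)

    def test_physical_ranges(self):
        w = generate_weather(SimulationConfig(n_days=60, seed=2))
        west = w[(w["site"] == "western")]
        assert (west.loc[west["variable"] == "pblh", "value"] > 0).all()
        cloud = west.loc[west["variable"] == "cloud", "value"]
        assert cloud.between(0.0, 1.0).all()

    def test_complete_hourly_coverage(self):
        cfg = SimulationConfig(n_days=40, seed=3)
        w = generate_weather(cfg)
        counts = (
            w[(w["site"] == "western") & (w["variable"] == "u")]
            .assign(day=lambda d: (pd.to_datetime(d["timestamp"]) - pd.Timedelta(hours=12)).dt.date)
            .groupby("day")["value"]
            .count()
        )
        assert set(counts.loc[list(simulation_days(cfg))]) == {24}

    def test_vi_wind_correlation_hits_target(self):
        cfg = SimulationConfig(n_days=1000, seed=1, vi_wind_corr_target=0.7)
        w = generate_weather(cfg)
        vi, sp = daily_vi(w), daily_inland_speed(w)
        r = np.corrcoef(vi, sp.loc[vi.index])[0, 1]
        assert 0.6 <= r <= 0.8

    def test_vi_wind_independent_when_target_zero(self):
        cfg = SimulationConfig(n_days=1000, seed=1, vi_wind_corr_target=0.0)
        w = generate_weather(cfg)
        vi, sp = daily_vi(w), daily_inland_speed(w)
        r = np.corrcoef(vi, sp.loc[vi.index])[0, 1]
        assert abs(r) < 0.1


class TestHotspots:
    def test_zero_intensity_no_hotspots(self):
        hs = generate_hotspots(SimulationConfig(n_days=20, seed=0, hotspot_intensity=0.0))
        assert len(hs) == 0

    def test_active_days_pass_cluster_filter(self):
        """The fire-activity clustering (as oracle) must find a >=3 cluster
        on every day the generator meant to be active."""
        cfg = SimulationConfig(n_days=60, seed=4)
        hs = generate_hotspots(cfg)
        day_types = hs.attrs["day_types"]
        table = fire.fire_day_table(hs, cfg.reference_point).set_index("fire_day")
        for day, kind in day_types.items():
            if kind == "active":
                assert table.loc[day, "max_cluster_size"] >= 3
            elif kind == "isolated":
                if day in table.index:
                    assert not table.loc[day, "active"]

    def test_overpass_time_windows(self):
        hs = generate_hotspots(SimulationConfig(n_days=60, seed=4))
        ts = pd.to_datetime(hs["timestamp_local"])
        day = hs["daynight"] == "D"
        assert ts[day].dt.hour.isin([13, 14, 15]).all()
        assert ts[~day].dt.hour.isin([0, 1, 2]).all()

    def test_decoys_beyond_buffer(self):
        cfg = SimulationConfig(n_days=20, seed=0, decoys=True)
        hs = generate_hotspots(cfg)
        d = fire.haversine_km(cfg.reference_point[0], cfg.reference_point[1], hs["lon"], hs["lat"])
        assert (np.asarray(d) > 150.0).any()

    def test_within_buffer_otherwise(self):
        cfg = SimulationConfig(n_days=40, seed=8)
        hs = generate_hotspots(cfg)
        d = fire.haversine_km(cfg.reference_point[0], cfg.reference_point[1], hs["lon"], hs["lat"])
        assert (np.asarray(d) <= 150.0).all()


class TestPm:
    def _flat_predictors(self, n_days, seed=0):
        days = simulation_days(SimulationConfig(n_days=n_days, seed=seed))
        return pd.DataFrame(
            {
                "fire_day": days,
                "ventilation_index": 1000.0,
                "temperature": 15.0,
                "cloud": 0.5,
                "mslp_west": 1016.0,
                "mslp_tasman": 1013.0,
                "u_coast_aft": 0.0,
                "v_coast_aft": 0.0,
                "u_inland": 0.0,
                "v_inland": 0.0,
                "fire_west": 0.0,
                "fire_south": 0.0,
                "fire_north": 0.0,
            }
        )

    def test_long_run_mean_matches_intercept(self):
        cfg = SimulationConfig(
            n_days=2000, seed=0, effects={}, lag_coefficient=0.0, intercept=np.log(10.0)
        )
        pm, truth = generate_pm(cfg, self._flat_predictors(2000))
        mc_se = 10.0 / np.sqrt(cfg.gamma_shape * 2000)
        assert truth["daily_mean"].mean() == pytest.approx(10.0, abs=4 * mc_se)

    def test_large_shape_deterministic_limit(self):
        cfg = SimulationConfig(
            n_days=50, seed=0, effects={}, lag_coefficient=0.0, intercept=np.log(10.0),
            gamma_shape=1e8,
        )
        _, truth = generate_pm(cfg, self._flat_predictors(50))
        np.testing.assert_allclose(truth["daily_mean"], truth["mu"], rtol=1e-3)

    def test_lag_induces_autocorrelation(self):
        cfg = SimulationConfig(
            n_days=1000, seed=0, effects={}, lag_coefficient=0.05, intercept=np.log(10.0) - 0.5
        )
        _, truth = generate_pm(cfg, self._flat_predictors(1000))
        x = truth["daily_mean"].to_numpy()
        rho = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert rho > 0.1

    def test_rejects_non_chronological(self):
        cfg = SimulationConfig(n_days=10, seed=0)
        pred = self._flat_predictors(10).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError):
            generate_pm(cfg, pred)

    def test_all_values_positive(self, small_dataset):
        assert (small_dataset.pm_hourly["value"] > 0).all()

    def test_hourly_mean_preserves_daily_draw(self, small_dataset):
        ds = small_dataset
        pm = ds.pm_hourly.copy()
        pm["day"] = (pd.to_datetime(pm["timestamp"]) - pd.Timedelta(hours=12)).dt.date
        daily = pm.groupby("day")["value"].mean()
        truth = ds.truth.set_index("fire_day")["daily_mean"]
        np.testing.assert_allclose(daily.loc[truth.index], truth, rtol=1e-9)


class TestDataset:
    def test_full_dataset_determinism(self):
        cfg = SimulationConfig(n_days=25, seed=77)
        d1, d2 = generate_dataset(cfg), generate_dataset(cfg)
        pd.testing.assert_frame_equal(d1.weather, d2.weather)
        pd.testing.assert_frame_equal(d1.hotspots, d2.hotspots)
        pd.testing.assert_frame_equal(d1.pm_hourly, d2.pm_hourly)
        pd.testing.assert_frame_equal(d1.truth, d2.truth)

    def test_write_csvs_roundtrip(self, small_dataset, tmp_path):
        paths = small_dataset.write_csvs(tmp_path)
        hs = pd.read_csv(paths["hotspots"])
        assert {"latitude", "longitude", "acq_date", "acq_time", "daynight"} <= set(hs.columns)
        assert len(hs) == len(small_dataset.hotspots)
        back = fire.read_hotspot_csv(paths["hotspots"])
        np.testing.assert_allclose(
            np.sort(back["lon"]), np.sort(small_dataset.hotspots["lon"]), rtol=1e-9
        )
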