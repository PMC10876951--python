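import numpy as np
import pandas as pd
import pytest

from firescape import landcover as lc
from firescape.raster_core import Grid
from firescape.synthetic_scenario import (
    DEFAULT_CLASS_PROPORTIONS,
    SIM_YEARS,
    DisturbanceSpec,
    ScenarioConfig,
    generate_reference_sample,
    generate_scenario,
    generate_weather,
    nbr_trajectory,
)
from firescape.weather_anomaly import seasonal_series, zscore_series


def small_config(**kw):
    defaults = dict(grid_rows=50, grid_cols=50, seed=123, trajectory_noise_sd=0.0)
    defaults.update(kw)
    return ScenarioConfig(**defaults)


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        bad = dict(DEFAULT_CLASS_PROPORTIONS)
        bad[lc.FOREST] += 0.05
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(class_proportions=bad)

    def test_schedule_year_in_period(self):
        with pytest.raises(ValueError, match="outside"):
            small_config(
                disturbance_schedule=(DisturbanceSpec(1950, "SRF", 1, (0.3, 0.5)),)
            )

    def test_nsr_severity_rule(self):
        with pytest.raises(ValueError, match="NSR"):
            DisturbanceSpec(2000, "NSR", 1, severity=(0.2, 0.4))

    def test_srf_severity_rule(self):
        with pytest.raises(ValueError, match="SRF"):
            DisturbanceSpec(2000, "SRF", 1, severity=(0.15, 0.4))

    def test_unknown_agent(self):
        with pytest.raises(ValueError):
            DisturbanceSpec(2000, "XXX", 1)


class TestGenerateScenario:
    def test_no_events_landcover_constant(self):
        truth = generate_scenario(small_config())
        first = truth.landcover_by_year[SIM_YEARS[0]].values
        for year in SIM_YEARS:
            np.testing.assert_array_equal(truth.landcover_by_year[year].values, first)

    def test_single_srh_event_rectangular(self):
        cfg = small_config(
            disturbance_schedule=(
                DisturbanceSpec(2005, "SRH", 1, severity=(0.4, 0.5), size_px=(12, 12)),
            )
        )
        truth = generate_scenario(cfg)
        assert len(truth.events) == 1
        ev = truth.events[0]
        assert ev.year == 2005 and ev.agent == "SRH"
        rows = [p[0] for p in ev.pixels]
        cols = [p[1] for p in ev.pixels]
        bbox_area = (max(rows) - min(rows) + 1) * (max(cols) - min(cols) + 1)
        assert bbox_area == len(ev.pixels)  # exact rectangle
        # NBR drops at the event year on event pixels
        i2004 = SIM_YEARS.index(2004)
        i2005 = SIM_YEARS.index(2005)
        nbr = truth.index_stack.layers["nbr"]
        r, c = ev.pixels[0]
        assert nbr[i2004, r, c] - nbr[i2005, r, c] == pytest.approx(ev.d_nbr)

    def test_seed_determinism(self):
        cfg = small_config(
            trajectory_noise_sd=0.02,
            disturbance_schedule=(DisturbanceSpec(2000, "SRF", 2, (0.3, 0.6)),),
        )
        t1 = generate_scenario(cfg)
        t2 = generate_scenario(cfg)
        for year in SIM_YEARS:
            np.testing.assert_array_equal(
                t1.landcover_by_year[year].values, t2.landcover_by_year[year].values
            )
        assert t1.events == t2.events
        for name in t1.index_stack.layers:
            np.testing.assert_array_equal(
                t1.index_stack.layers[name], t2.index_stack.layers[name]
            )
        pd.testing.assert_frame_equal(t1.weather, t2.weather)

    def test_events_inside_contemporaneous_forest(self):
        cfg = small_config(
            disturbance_schedule=(
                DisturbanceSpec(1997, "SRF", 2, (0.3, 0.6)),
                DisturbanceSpec(2008, "SRH", 2, (0.35, 0.6)),
                DisturbanceSpec(2016, "NSR", 2, (0.1, 0.24)),
            )
        )
        truth = generate_scenario(cfg)
        mask_years = sorted(truth.forest_masks_5yr)
        for ev in truth.events:
            eligible = [y for y in mask_years if y <= ev.year]
            mask = truth.forest_masks_5yr[eligible[-1]].values
            assert all(mask[r, c] for r, c in ev.pixels)

    def test_severity_rules_in_generated_events(self):
        cfg = small_config(
            disturbance_schedule=(
                DisturbanceSpec(2000, "SRF", 3, (0.3, 0.7)),
                DisturbanceSpec(2010, "NSR", 3, (0.1, 0.24)),
            )
        )
        truth = generate_scenario(cfg)
        for ev in truth.events:
            if ev.agent == "SRF":
                assert ev.d_nbr >= 0.25
            if ev.agent == "NSR":
                assert ev.d_nbr < 0.25

    def test_event_footprints_disjoint(self):
        cfg = small_config(
            disturbance_schedule=(
                DisturbanceSpec(1995, "SRF", 3, (0.3, 0.6)),
                DisturbanceSpec(2005, "SRH", 3, (0.35, 0.6)),
            )
        )
        truth = generate_scenario(cfg)
        seen = set()
        for ev in truth.events:
            assert not (set(ev.pixels) & seen)
            seen |= set(ev.pixels)

    def test_disturbed_fraction_close_to_schedule(self):
        cfg = small_config(
            grid_rows=80,
            grid_cols=80,
            disturbance_schedule=(
                DisturbanceSpec(2000, "SRF", 4, (0.3, 0.6), size_px=(20, 20)),
            ),
        )
        truth = generate_scenario(cfg)
        forest_px = int(
            (truth.landcover_by_year[SIM_YEARS[0]].values == lc.FOREST).sum()
        )
        disturbed = sum(len(ev.pixels) for ev in truth.events)
        target = 4 * 20 / forest_px
        assert abs(disturbed / forest_px - target) <= 0.02

    def test_oversized_schedule_rejected(self):
        cfg = small_config(
            grid_rows=12,
            grid_cols=12,
            disturbance_schedule=(
                DisturbanceSpec(2000, "SRF", 60, (0.3, 0.6), size_px=(40, 60)),
            ),
        )
        with pytest.raises(ValueError):
            generate_scenario(cfg)

    def test_class_mosaic_matches_proportions(self):
        truth = generate_scenario(small_config(grid_rows=100, grid_cols=100))
        vals = truth.landcover_by_year[SIM_YEARS[0]].values
        for code, frac in DEFAULT_CLASS_PROPORTIONS.items():
            got = (vals == code).mean()
            assert got == pytest.approx(frac, abs=0.02)


class TestGenerateWeather:
    def test_zero_noise_seasonal_means_equal(self):
        cfg = small_config(weather_noise_sd=0.0)
        weather = generate_weather(cfg)
        seasonal = seasonal_series(weather)
        assert seasonal["mean_fwi"].nunique() == 1
        assert seasonal["mean_dc"].std() == pytest.approx(0.0)

    def test_anomaly_year_flagged_by_zscore(self):
        cfg = small_config(weather_anomaly_years=(2007,), weather_noise_sd=0.5)
        seasonal = seasonal_series(generate_weather(cfg))
        for col in ("mean_fwi", "mean_isi", "mean_dc"):
            flags = zscore_series(dict(zip(seasonal["year"], seasonal[col])), 2)
            z = {f.year: f.z for f in flags}
            assert z[2007] >= 2.0

    def test_determinism(self):
        cfg = small_config(weather_noise_sd=0.7)
        pd.testing.assert_frame_equal(generate_weather(cfg), generate_weather(cfg))

    def test_non_leap_calendar(self):
        weather = generate_weather(small_config())
        dates = pd.to_datetime(weather["date"])
        assert not ((dates.dt.month == 2) & (dates.dt.day == 29)).any()
        assert (dates.dt.year.value_counts() == 365).all()

    def test_indices_non_negative(self):
        weather = generate_weather(small_config(weather_noise_sd=3.0))
        assert (weather[["fwi", "isi", "dc"]] >= 0).all().all()


class TestReferenceSample:
    def grids(self, rng, shape=(20, 20)):
        truth = Grid(rng.integers(1, 4, shape), resolution_m=10.0, nodata=-1)
        return truth

    def test_identity_map_full_agreement(self, rng):
        truth = self.grids(rng)
        sample = generate_reference_sample(truth, truth, n=50, seed=1)
        assert (sample["mapped_class"] == sample["reference_class"]).all()

    def test_census_without_replacement(self, rng):
        truth = self.grids(rng, shape=(8, 8))
        sample = generate_reference_sample(truth, truth, n=64, seed=1)
        assert len(sample) == 64
        assert len(set(zip(sample["row"], sample["col"]))) == 64

    def test_n_too_large_rejected(self, rng):
        truth = self.grids(rng, shape=(4, 4))
        with pytest.raises(ValueError):
            generate_reference_sample(truth, truth, n=17, seed=1)

    def test_empty_stratum_reported(self, rng):
        truth = self.grids(rng)
        mapped = Grid(truth.values.copy(), resolution_m=10.0, nodata=-1)
        # register a class value that is absent from the map: recode one
        # class entirely away, then ask for stratification
        sample = generate_reference_sample(
            truth, mapped, n=30, seed=2, stratified=True
        )
        assert "empty_strata" in sample.attrs

    def test_stratified_covers_each_mapped_class(self, rng):
        truth = self.grids(rng)
        sample = generate_reference_sample(truth, truth, n=30, seed=3, stratified=True)
        assert set(sample["stratum"]) == set(np.unique(truth.values))

    def test_determinism(self, rng):
        truth = self.grids(rng)
        s1 = generate_reference_sample(truth, truth, n=40, seed=9)
        s2 = generate_reference_sample(truth, truth, n=40, seed=9)
        pd.testing.assert_frame_equal(s1, s2)


class TestNbrTrajectory:
    def test_no_event_before_year(self):
        years = np.arange(1986, 2023)
        out = nbr_trajectory(years, 0.7, 2005, 0.4)
        assert (out[years < 2005] == 0.7).all()
        assert out[years == 2005][0] == pytest.approx(0.3)

    def test_duration_spreads_drop(self):
        years = np.arange(1986, 2023)
        out = nbr_trajectory(years, 0.7, 2000, 0.3, duration=3)
        assert out[years == 2000][0] == pytest.approx(0.6)
        assert out[years == 2002][0] == pytest.approx(0.4)
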