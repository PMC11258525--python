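"""Heat-stress index computation and daily exposure summaries."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatwear import weather
from heatwear.weather import (
    ThresholdConfig,
    celsius_to_fahrenheit,
    classify_heat_day,
    compute_heat_index,
    compute_wbgt,
    exceedance_summary,
    fahrenheit_to_celsius,
    summarize_day,
    summarize_days,
    validate_weather_frame,
)
from conftest import constant_weather_day


class TestWBGT:
    @pytest.mark.parametrize(
        "w,y,x,z,mapping,expected",
        [
            (0, 0, 0, 0, "as_printed", -0.45552),
            (20, 500, 60, 25, "as_printed", 33.71068),
            (20, 500, 60, 25, "literature_swap", 22.4684),
        ],
    )
    def test_hand_computed_values(self, w, y, x, z, mapping, expected):
        assert compute_wbgt(w, y, x, z, mapping) == pytest.approx(expected, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_wbgt(np.inf, 0, 50, 20)
        with pytest.raises(ValueError):
            compute_wbgt(20, 500, 105, 25)
        with pytest.raises(ValueError):
            compute_wbgt(20, 500, 60, 25, mapping="nonsense")

    @given(
        w=st.floats(-10, 40),
        y=st.floats(0, 1200),
        x=st.floats(0, 100),
        z=st.floats(-10, 45),
        scale=st.floats(0.1, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_linear_in_each_argument(self, w, y, x, z, scale):
        """The index is an affine function of each input separately."""
        base = compute_wbgt(w, y, x, z)
        bumped = compute_wbgt(w + 1, y, x, z)
        twice = compute_wbgt(w + 2, y, x, z)
        assert (twice - bumped) == pytest.approx(bumped - base, abs=1e-8)
        # same slope irrespective of the operating point -> linearity in w
        other = compute_wbgt(w, y * scale % 1200, x, z)
        assert compute_wbgt(w + 1, y * scale % 1200, x, z) - other == pytest.approx(
            bumped - base, abs=1e-8
        )

    @given(
        w=st.floats(-10, 40), y=st.floats(0, 1200), v=st.floats(0, 45)
    )
    @settings(max_examples=60, deadline=None)
    def test_mappings_agree_when_humidity_equals_temperature(self, w, y, v):
        """Swapping x and z is a no-op when they are numerically equal."""
        assert compute_wbgt(w, y, v, v, "as_printed") == pytest.approx(
            compute_wbgt(w, y, v, v, "literature_swap"), abs=1e-10
        )


class TestHeatIndex:
    def test_steadman_branch_hand_value(self):
        # 70 F at 50 % RH: simple formula gives 69.05 F
        hi_f = celsius_to_fahrenheit(compute_heat_index(fahrenheit_to_celsius(70), 50))
        assert hi_f == pytest.approx(69.05, abs=1e-6)

    def test_rothfusz_matches_nws_chart(self):
        # published NWS heat-index chart: 90 F / 70 % -> 105 F (chart rounds to 1 F)
        hi_f = celsius_to_fahrenheit(compute_heat_index(fahrenheit_to_celsius(90), 70))
        assert hi_f == pytest.approx(105, abs=1.0)

    def test_caution_boundary_temperature(self):
        # 26.67 C is exactly the 80 F caution limit
        assert celsius_to_fahrenheit(26.67) == pytest.approx(80.006, abs=1e-3)

    def test_rh_domain_error(self):
        with pytest.raises(ValueError):
            compute_heat_index(30.0, 101.0)

    @pytest.mark.parametrize("rh", [40, 50, 60])
    def test_branch_discontinuity_bounded_at_moderate_humidity(self, rh):
        """The simple->Rothfusz hand-off jump stays below 1.5 F for RH <= 60 %."""
        ts = np.linspace(fahrenheit_to_celsius(72), fahrenheit_to_celsius(95), 2000)
        hi_f = celsius_to_fahrenheit(compute_heat_index(ts, rh))
        assert np.abs(np.diff(hi_f)).max() < 1.5

    @pytest.mark.parametrize("rh", [40, 60, 80, 100])
    def test_monotone_in_temperature(self, rh):
        ts = np.linspace(20.0, 42.0, 1500)
        hi = compute_heat_index(ts, rh)
        assert np.all(np.diff(hi) > 0)


class TestDailySummary:
    def test_constant_series_max_equals_night_min(self):
        obs = constant_weather_day(value=25.0)
        day = summarize_day(obs, "2021-09-02")
        assert day["temp_max_c"] == pytest.approx(25.0)
        assert day["temp_min_night_c"] == pytest.approx(25.0)
        assert day["wbgt_max_c"] == pytest.approx(day["wbgt_min_night_c"])

    def test_sinusoidal_day_max_is_analytic_peak(self):
        ts = pd.date_range("2021-09-01", periods=2 * 96, freq="15min")
        hours = ts.hour + ts.minute / 60.0
        temp = 24.0 + 5.0 * np.sin(2 * np.pi * (hours - 8.0) / 24.0)
        obs = pd.DataFrame(
            {
                "timestamp": ts,
                "air_temp_c": temp,
                "wet_bulb_temp_c": temp - 4,
                "relative_humidity_pct": 50.0,
                "global_radiation_wm2": 0.0,
                "rainfall_mm": 0.0,
            }
        )
        day = summarize_day(obs, "2021-09-02")
        # the 14:00 slot hits the sinusoid's exact peak, the 02:00 slot its trough
        assert day["temp_max_c"] == pytest.approx(29.0)
        assert day["temp_min_night_c"] == pytest.approx(19.0)

    def test_rain_total_boundary_is_heavy(self):
        obs = constant_weather_day(date="2021-09-02")
        obs.loc[100, "rainfall_mm"] = 2.0
        obs.loc[120, "rainfall_mm"] = 18.0
        day = summarize_day(obs, "2021-09-02")
        assert day["rain_total_mm"] == pytest.approx(20.0)
        assert bool(day["heavy_rain"]) is True  # >= semantics at the cutoff

    def test_empty_day_emitted_all_missing(self, caplog):
        obs = constant_weather_day(date="2021-09-02")
        out = summarize_days(obs, dates=["2021-09-02", "2021-09-10"])
        missing = out[out["date"] == pd.Timestamp("2021-09-10")].iloc[0]
        assert np.isnan(missing["temp_max_c"]) and np.isnan(missing["rain_total_mm"])
        assert missing["hi_category"] == "unknown"

    def test_sparse_day_below_half_slots_is_missing(self):
        obs = constant_weather_day(date="2021-09-02")
        # keep only 40 of 96 slots on the target date
        mask = (obs["timestamp"].dt.normalize() != pd.Timestamp("2021-09-02")) | (
            obs.index % 96 < 40
        )
        day = summarize_day(obs[obs["timestamp"].dt.normalize() == pd.Timestamp("2021-09-02")].head(40), "2021-09-02")
        assert np.isnan(day["temp_max_c"])

    def test_validate_weather_frame_rejects_bad_streams(self):
        obs = constant_weather_day()
        bad = obs.copy()
        bad.loc[0, "relative_humidity_pct"] = 120
        with pytest.raises(ValueError, match="humidity"):
            validate_weather_frame(bad)
        bad = obs.copy()
        bad.loc[0, "wet_bulb_temp_c"] = bad.loc[0, "air_temp_c"] + 1.0
        with pytest.raises(ValueError, match="wet_bulb"):
            validate_weather_frame(bad)
        bad = obs.copy()
        bad.loc[1, "timestamp"] = bad.loc[0, "timestamp"]
        with pytest.raises(ValueError, match="increasing"):
            validate_weather_frame(bad)


class TestClassification:
    def make_day(self, hi_max=np.nan, wbgt_max=np.nan):
        return pd.Series(
            {"date": pd.Timestamp("2021-09-02"), "heat_index_max_c": hi_max,
             "wbgt_max_c": wbgt_max, "temp_max_c": 30.0}
        )

    @pytest.mark.parametrize(
        "hi,expected",
        [(25.0, "none"), (26.67, "caution"), (33.0, "extreme_caution"),
         (39.44, "danger"), (np.nan, "unknown")],
    )
    def test_hi_category(self, hi, expected):
        day = classify_heat_day(self.make_day(hi_max=hi, wbgt_max=20.0))
        assert day["hi_category"] == expected

    def test_wbgt_flags_default_cutoffs(self):
        day = classify_heat_day(self.make_day(hi_max=25.0, wbgt_max=24.0))
        assert bool(day["wbgt_exceeds_very_high_metabolic"]) is True
        assert bool(day["wbgt_exceeds_high_metabolic"]) is False
        assert bool(day["wbgt_exceeds_medium_metabolic"]) is False

    def test_hi_category_monotone_in_heat_index(self):
        order = {"none": 0, "caution": 1, "extreme_caution": 2, "danger": 3}
        cats = [
            classify_heat_day(self.make_day(hi_max=h, wbgt_max=20.0))["hi_category"]
            for h in np.linspace(20, 45, 60)
        ]
        ranks = [order[c] for c in cats]
        assert ranks == sorted(ranks)


class TestExceedanceSummary:
    def synth_days(self, n=40, seed=3):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "date": pd.date_range("2021-09-01", periods=n, freq="D"),
                "temp_max_c": rng.uniform(24, 33, n),
                "wbgt_max_c": rng.uniform(21, 30, n),
                "heat_index_max_c": rng.uniform(24, 41, n),
                "temp_min_night_c": rng.uniform(16, 22, n),
                "wbgt_min_night_c": rng.uniform(14, 20, n),
                "heat_index_min_night_c": rng.uniform(16, 24, n),
                "rain_total_mm": rng.exponential(8, n),
                "heavy_rain": pd.array([None] * n, dtype="boolean"),
            }
        ).assign(heavy_rain=lambda d: (d["rain_total_mm"] >= 20).astype("boolean"))

    def test_counts_match_brute_force_scan(self, small_dataset, thresholds):
        """Flags summarized per day equal a raw scan of the 15-min records."""
        dataset, _ = small_dataset
        days = dataset["exposures"]
        summary = exceedance_summary(days, thresholds).set_index("reference")

        aug = dataset["weather"].copy()
        aug["wbgt"] = weather.compute_wbgt(
            aug["wet_bulb_temp_c"], aug["global_radiation_wm2"],
            aug["relative_humidity_pct"], aug["air_temp_c"],
        )
        aug["hi"] = weather.compute_heat_index(
            aug["air_temp_c"], aug["relative_humidity_pct"]
        )
        by_day = aug.groupby(aug["timestamp"].dt.normalize())
        brute_very_high = int((by_day["wbgt"].max() > 23.0).sum())
        brute_caution = int((by_day["hi"].max() >= 26.67).sum())
        brute_heavy = int((by_day["rainfall_mm"].sum() >= 20.0).sum())
        assert summary.loc["wbgt_very_high_metabolic", "n_days"] == brute_very_high
        assert summary.loc["heat_index_caution", "n_days"] == brute_caution
        assert summary.loc["heavy_rain_days", "n_days"] == brute_heavy

    def test_invariant_under_day_permutation(self):
        days = self.synth_days()
        shuffled = days.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = exceedance_summary(days).drop(columns=[]).reset_index(drop=True)
        b = exceedance_summary(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_hi_categories_partition_days(self):
        days = weather.classify_heat_days(self.synth_days())
        counts = days["hi_category"].value_counts()
        assert counts.sum() == len(days)

    def test_zero_exceedance_row(self):
        days = self.synth_days()
        days["heat_index_max_c"] = 20.0
        summary = exceedance_summary(days).set_index("reference")
        assert summary.loc["heat_index_danger", "n_days"] == 0
        assert summary.loc["heat_index_danger", "pct_days"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            exceedance_summary(self.synth_days(n=40).iloc[:0])


def test_threshold_config_validates_ordering():
    with pytest.raises(ValueError):
        ThresholdConfig(hi_caution_c=33.0)
    with pytest.raises(ValueError):
        ThresholdConfig(wbgt_limits_c={"very_high_metabolic": 28.0,
                                       "high_metabolic": 26.0,
                                       "medium_metabolic": 23.0})
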