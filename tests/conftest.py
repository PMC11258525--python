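import logging

import pandas as pd
import pytest

from heatwear import association, completeness, qc, synthetic, weather

logging.getLogger("heatwear").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def thresholds():
    return weather.ThresholdConfig()


@pytest.fixture(scope="session")
def small_dataset(thresholds):
    """A compact but fully featured synthetic study: 14 participants, 45 days."""
    cfg = synthetic.SynthConfig(seed=7, n_participants=14, study_days=45)
    return synthetic.generate_dataset(cfg, thresholds), cfg


@pytest.fixture(scope="session")
def small_qc(small_dataset, thresholds):
    dataset, _ = small_dataset
    roster = qc.prepare_roster(dataset["roster"])
    res = qc.run_qc(
        roster,
        dataset["sleep_episodes"],
        dataset["steps"],
        dataset["heart_rate"],
        dataset["body_temp"],
        night_window=thresholds.night_window,
    )
    return roster, res


@pytest.fixture(scope="session")
def small_completeness(small_qc):
    roster, res = small_qc
    return completeness.completeness_table(roster, res)


@pytest.fixture(scope="session")
def small_suite(small_dataset, small_qc, small_completeness):
    dataset, _ = small_dataset
    roster, res = small_qc
    return association.run_model_suite(
        res, dataset["exposures"], roster, small_completeness
    )


def constant_weather_day(value=25.0, date="2021-09-02", rh=50.0, rain=0.0):
    """Two days of identical 15-min observations around the given date."""
    start = pd.Timestamp(date) - pd.Timedelta(days=1)
    ts = pd.date_range(start, periods=2 * 96, freq="15min")
    return pd.DataFrame(
        {
            "timestamp": ts,
            "air_temp_c": value,
            "wet_bulb_temp_c": value - 3.0,
            "relative_humidity_pct": rh,
            "global_radiation_wm2": 100.0,
            "rainfall_mm": rain,
        }
    )
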