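"""Synthetic weather-station and wearable streams with known ground truth.

The generator emulates the data structure of a rural equatorial panel study:
a single weather station logging every 15 minutes over a ~200-day period,
and a cohort of ~80 participants each wearing a wrist device (sleep, steps,
pulse rate) — and, in one study arm, a nightly skin-temperature patch — for
a staggered 21-day window.

Ground truth is planted at three levels so every downstream stage is
testable:

- **climate**: a diurnal temperature sinusoid (peak early afternoon) with
  day-to-day offsets and AR(1) noise, anti-phase humidity, a clipped
  daylight radiation curve, humidity-dependent wet-bulb depression, and a
  two-component rainfall process with configurable heavy-rain frequency;
- **exposure–response effects**: nightly sleep responds linearly to the
  night's minimum temperature, log step count to the day's maximum WBGT,
  and body shell temperature carries a gender effect — with effect sizes
  taken as configuration (defaults are the recovery targets used in tests);
- **data pathology**: per-participant coverage rates drawn from Beta
  distributions (matching the large between-participant completeness spread
  seen in field deployments), plus deliberate contaminants: implausible
  heart rates and body temperatures, nap-length and over-long sleep
  episodes, split nights that exercise the episode-merge rule, and zero
  step days.

Everything is deterministic per seed (independent child generators are
spawned per stream from one ``SeedSequence``).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal, stats

from .weather import WEATHER_COLUMNS, ThresholdConfig, summarize_days

START_DATE = pd.Timestamp("2021-09-01")


@dataclass(frozen=True)
class WeatherParams:
    """Climate process parameters (°C, %, W/m², mm)."""

    temp_mean_c: float = 23.8
    temp_amplitude_c: float = 4.5       # diurnal half-range, peak ~14:00
    temp_day_sd_c: float = 0.9          # day-to-day mean offsets
    temp_noise_sd_c: float = 0.4        # AR(1) stationary SD at 15-min lag
    temp_ar1: float = 0.8
    rh_mean_pct: float = 60.0
    rh_day_sd_pct: float = 4.0
    rh_diurnal_amplitude_pct: float = 12.0
    radiation_peak_wm2: float = 750.0
    wet_bulb_offset_scale: float = 1.7  # depression = scale*(100-RH)/10
    rain_day_prob: float = 97 / 204
    heavy_rain_day_prob: float = 16 / 204


@dataclass(frozen=True)
class EffectSizes:
    """Planted exposure–response truths (the parameter-recovery targets)."""

    sleep_slope_min_per_c: float = -5.56     # sleep vs nightly minimum temperature
    log_steps_wbgt_slope: float = 0.06       # log steps vs daily max WBGT
    bodytemp_gender_effect_c: float = -0.72  # men vs women
    bodytemp_bmi_slope: float = -0.03
    age_sleep_slope: float = -0.39
    # secondary coefficients (confounder structure + intercepts)
    sleep_intercept_min: float = 537.5
    sleep_gender_effect_min: float = 0.9
    sleep_noise_sd_min: float = 60.0
    steps_intercept_log: float = 8.25        # calibrated to the as_printed WBGT scale
    log_steps_age_slope: float = -0.02
    log_steps_bmi_slope: float = -0.03
    log_steps_gender_effect: float = 0.05
    log_steps_noise_sd: float = 0.5
    bodytemp_intercept_c: float = 36.31
    bodytemp_temp_slope: float = 0.03        # vs nightly minimum temperature
    bodytemp_night_sd_c: float = 0.95
    bodytemp_reading_sd_c: float = 0.3


@dataclass(frozen=True)
class MissingnessRates:
    """Per-variable (and for HR per-gender) mean coverage with Beta spread.

    Each participant's coverage rate is Beta-distributed with the given mean
    and SD; units are then kept i.i.d. at that rate. SDs reflect that
    adherence varies far more between wearers than binomial noise allows.
    """

    sleep: tuple = (0.826, 0.213)
    steps: tuple = (0.861, 0.189)
    heart_rate_women: tuple = (0.12, 0.14)
    heart_rate_men: tuple = (0.02, 0.04)
    body_temp: tuple = (0.362, 0.245)


@dataclass(frozen=True)
class ContaminantRates:
    """Deliberate invalid-data injection so QC paths are always exercised."""

    hr_out_of_range: float = 0.05
    bodytemp_out_of_range: float = 0.05
    sleep_too_long: float = 0.02     # nights emitted with > 13 h sleep
    nap_per_day: float = 0.15        # stand-alone < 3 h afternoon episodes
    split_night: float = 0.20        # nights emitted as two > 3 h episodes
    zero_step_day: float = 0.02


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_participants: int = 83
    study_days: int = 204
    cycle_days: int = 21
    start_date: pd.Timestamp = START_DATE
    weather: WeatherParams = field(default_factory=WeatherParams)
    effects: EffectSizes = field(default_factory=EffectSizes)
    missingness: MissingnessRates = field(default_factory=MissingnessRates)
    contaminants: ContaminantRates = field(default_factory=ContaminantRates)
    # cohort demographics (target moments)
    age_mean: float = 33.3
    age_sd: float = 19.0
    age_range: tuple = (6, 83)
    prob_woman: float = 0.51
    adult_bmi_mean: float = 23.8
    adult_bmi_sd: float = 4.7
    adult_bmi_range: tuple = (16.0, 37.4)
    prob_patch_arm: float = 0.59

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_date"] = str(pd.Timestamp(self.start_date).date())
        return d


def _beta_params(mean, sd):
    var = min(sd**2, 0.999 * mean * (1 - mean))
    nu = mean * (1 - mean) / var - 1
    return mean * nu, (1 - mean) * nu


def _rngs(cfg: SynthConfig):
    ss = np.random.SeedSequence(cfg.seed)
    kids = ss.spawn(3)
    return [np.random.default_rng(k) for k in kids]


# ---------------------------------------------------------------------------
# weather

def simulate_weather(cfg: SynthConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """15-minute station stream over the study period (weather CSV schema)."""
    rng = rng if rng is not None else _rngs(cfg)[0]
    wp = cfg.weather
    n_days = cfg.study_days
    ts = pd.date_range(cfg.start_date, periods=n_days * 96, freq="15min")
    hours = ts.hour + ts.minute / 60.0
    day_idx = np.repeat(np.arange(n_days), 96)

    diurnal = np.sin(2 * np.pi * (hours - 8.0) / 24.0)  # peak 14:00, trough 02:00
    day_offset = rng.normal(0.0, wp.temp_day_sd_c, size=n_days)
    if wp.temp_noise_sd_c > 0:
        eps = rng.normal(0.0, wp.temp_noise_sd_c * np.sqrt(1 - wp.temp_ar1**2), size=len(ts))
        ar = signal.lfilter([1.0], [1.0, -wp.temp_ar1], eps)
    else:
        ar = np.zeros(len(ts))
    air = wp.temp_mean_c + day_offset[day_idx] + wp.temp_amplitude_c * diurnal + ar

    rh_day = rng.normal(0.0, wp.rh_day_sd_pct, size=n_days)
    rh = np.clip(
        wp.rh_mean_pct + rh_day[day_idx] - wp.rh_diurnal_amplitude_pct * diurnal
        + rng.normal(0.0, 2.0, size=len(ts)),
        5.0,
        100.0,
    )

    daylight = np.clip(np.sin(np.pi * (hours - 6.0) / 12.5), 0.0, None)
    radiation = np.clip(
        wp.radiation_peak_wm2 * daylight * (1.0 + rng.normal(0.0, 0.10, size=len(ts))), 0.0, None
    )

    depression = wp.wet_bulb_offset_scale * (100.0 - rh) / 10.0 + np.abs(
        rng.normal(0.0, 0.2, size=len(ts))
    )
    wet_bulb = air - np.clip(depression, 0.0, None)

    rainfall = _simulate_rainfall(rng, wp, n_days, hours, day_idx)

    return pd.DataFrame(
        {
            "timestamp": ts,
            "air_temp_c": air,
            "wet_bulb_temp_c": wet_bulb,
            "relative_humidity_pct": rh,
            "global_radiation_wm2": radiation,
            "rainfall_mm": rainfall,
        }
    )[WEATHER_COLUMNS]


def _simulate_rainfall(rng, wp: WeatherParams, n_days, hours, day_idx):
    heavy = rng.random(n_days) < wp.heavy_rain_day_prob
    # conditional light-rain probability so the overall rainy-day rate is met
    p_light = max(0.0, (wp.rain_day_prob - wp.heavy_rain_day_prob) / (1 - wp.heavy_rain_day_prob))
    light = (~heavy) & (rng.random(n_days) < p_light)
    totals = np.zeros(n_days)
    totals[heavy] = 20.0 + rng.exponential(15.0, size=int(heavy.sum()))
    totals[light] = np.minimum(rng.exponential(6.0, size=int(light.sum())), 19.9)

    rainfall = np.zeros(len(hours))
    afternoon = hours >= 12.0  # convective rain falls in the afternoon/evening
    for d in np.nonzero(totals > 0)[0]:
        slots = np.nonzero((day_idx == d) & afternoon)[0]
        k = 1 + rng.poisson(5)
        chosen = rng.choice(slots, size=min(k, len(slots)), replace=False)
        weights = rng.dirichlet(np.ones(len(chosen)))
        rainfall[chosen] += totals[d] * weights
    return rainfall


# ---------------------------------------------------------------------------
# cohort

def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(cfg: SynthConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Participant roster (raw CSV schema, before :func:`heatwear.qc.prepare_roster`)."""
    rng = rng if rng is not None else _rngs(cfg)[1]
    if cfg.study_days < cfg.cycle_days:
        raise ValueError(
            f"study_days ({cfg.study_days}) must be at least cycle_days ({cfg.cycle_days})"
        )
    n = cfg.n_participants
    ages = np.round(_truncnorm(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range, size=n)).astype(int)
    ages = np.clip(ages, *cfg.age_range)
    woman = rng.random(n) < cfg.prob_woman

    bmi = np.where(
        ages >= 19,
        _truncnorm(rng, cfg.adult_bmi_mean, cfg.adult_bmi_sd, *cfg.adult_bmi_range, size=n),
        np.clip(rng.normal(17.0, 2.0, size=n), 13.0, 25.0),
    )
    # crude stature model: linear growth to ~1.68 m adult height
    height = np.clip(0.75 + 0.055 * ages, None, 1.68) + rng.normal(0.0, 0.05, size=n)
    weight = bmi * height**2

    starts = rng.integers(0, cfg.study_days - cfg.cycle_days + 1, size=n)
    window_start = cfg.start_date + pd.to_timedelta(starts, unit="D")
    window_end = window_start + pd.Timedelta(days=cfg.cycle_days - 1)

    return pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(1, n + 1)],
            "gender": np.where(woman, "woman", "man"),
            "age_years": ages,
            "height_m": np.round(height, 3),
            "weight_kg": np.round(weight, 2),
            "study_arm": np.where(
                rng.random(n) < cfg.prob_patch_arm, "wphr_plus_patch", "wphr_only"
            ),
            "window_start": window_start,
            "window_end": window_end,
        }
    )


# ---------------------------------------------------------------------------
# wearable streams

def simulate_wearable_streams(
    roster: pd.DataFrame,
    exposures: pd.DataFrame,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> dict:
    """Sleep-episode, step, heart-rate and body-temperature streams.

    ``exposures`` must be the daily summary of the simulated weather (same
    study period); outcomes are generated from its nightly minima / daily
    maxima so that refitting the association models recovers the configured
    effect sizes.
    """
    rng = rng if rng is not None else _rngs(cfg)[2]
    ef, mr, cr = cfg.effects, cfg.missingness, cfg.contaminants

    expo = exposures.set_index("date")
    window_dates = {
        row.participant_id: pd.date_range(row.window_start, row.window_end, freq="D")
        for row in roster.itertuples()
    }
    missing_dates = [
        d for dates in window_dates.values() for d in dates if d not in expo.index
    ]
    if missing_dates:
        raise ValueError(
            f"participant windows extend beyond the exposure series (e.g. {missing_dates[0]})"
        )

    sleep_rows, step_rows, hr_rows, bt_rows = [], [], [], []
    for p in roster.itertuples():
        dates = window_dates[p.participant_id]
        man = p.gender == "man"
        bmi = p.weight_kg / p.height_m**2
        tmin = expo.loc[dates, "temp_min_night_c"].to_numpy()
        wbgt_max = expo.loc[dates, "wbgt_max_c"].to_numpy()

        _sleep_stream(rng, sleep_rows, p, dates, tmin, man, ef, mr, cr)
        _step_stream(rng, step_rows, p, dates, wbgt_max, man, bmi, ef, mr, cr)
        _hr_stream(rng, hr_rows, p, dates, man, mr, cr)
        if p.study_arm == "wphr_plus_patch":
            _bodytemp_stream(rng, bt_rows, p, dates, tmin, man, bmi, ef, mr, cr)

    return {
        "sleep_episodes": pd.DataFrame(
            sleep_rows, columns=["participant_id", "start", "end", "wake_minutes"]
        ),
        "steps": pd.DataFrame(step_rows, columns=["participant_id", "date", "steps"]),
        "heart_rate": pd.DataFrame(hr_rows, columns=["participant_id", "timestamp", "bpm"]),
        "body_temp": pd.DataFrame(bt_rows, columns=["participant_id", "timestamp", "temp_c"]),
    }


def _sleep_stream(rng, rows, p, dates, tmin, man, ef, mr, cr):
    cover = rng.random(len(dates)) < rng.beta(*_beta_params(*mr.sleep))
    for d, t, covered in zip(dates, tmin, cover):
        if not covered or not np.isfinite(t):
            continue
        sleep = (
            ef.sleep_intercept_min
            + ef.sleep_slope_min_per_c * t
            + ef.age_sleep_slope * p.age_years
            + ef.sleep_gender_effect_min * man
            + rng.normal(0.0, ef.sleep_noise_sd_min)
        )
        sleep = float(np.clip(sleep, 200.0, 770.0))
        if rng.random() < cr.sleep_too_long:
            sleep = float(rng.uniform(790.0, 840.0))
        wake = float(np.clip(rng.normal(25.0, 10.0), 0.0, 60.0))
        # wake-up time jitter is bounded so even the longest emitted night
        # starts after any same-day nap has ended (no overlapping episodes)
        end = d + pd.Timedelta(hours=6, minutes=30) + pd.Timedelta(
            minutes=float(np.clip(rng.normal(0, 40), -60.0, 90.0))
        )
        span = sleep + wake
        start = end - pd.Timedelta(minutes=span)
        if start >= d:
            # keep every night's onset before midnight: under the merge
            # rule's noon deadline an after-midnight onset would chain the
            # *next* evening's episode into the same night block
            start = d - pd.Timedelta(minutes=15)
            end = start + pd.Timedelta(minutes=span)
        if rng.random() < cr.split_night and sleep > 400.0:
            frac = rng.uniform(0.45, 0.55)
            gap = float(rng.uniform(10.0, 50.0))
            mid = start + pd.Timedelta(minutes=frac * span)
            w1, w2 = wake * frac, wake * (1 - frac)
            rows.append((p.participant_id, start, mid, round(w1, 1)))
            rows.append((p.participant_id, mid + pd.Timedelta(minutes=gap),
                         end + pd.Timedelta(minutes=gap), round(w2, 1)))
        else:
            rows.append((p.participant_id, start, end, round(wake, 1)))
        if rng.random() < cr.nap_per_day:
            # late-morning naps ending by 13:00: even the longest emitted
            # night (<= 840 + 60 min starting no earlier than ~14:20 the
            # previous afternoon) cannot overlap them
            nap_len = float(rng.uniform(20.0, 90.0))
            nap_start = d + pd.Timedelta(hours=9, minutes=float(rng.uniform(0, 150)))
            rows.append((p.participant_id, nap_start,
                         nap_start + pd.Timedelta(minutes=nap_len), 0.0))


def _step_stream(rng, rows, p, dates, wbgt_max, man, bmi, ef, mr, cr):
    cover = rng.random(len(dates)) < rng.beta(*_beta_params(*mr.steps))
    log_mu = (
        ef.steps_intercept_log
        + ef.log_steps_wbgt_slope * wbgt_max
        + ef.log_steps_age_slope * p.age_years
        + ef.log_steps_bmi_slope * bmi
        + ef.log_steps_gender_effect * man
    )
    noise = rng.normal(0.0, ef.log_steps_noise_sd, size=len(dates))
    zero = rng.random(len(dates)) < cr.zero_step_day
    for d, mu, eps, covered, z in zip(dates, log_mu, noise, cover, zero):
        if not covered or not np.isfinite(mu):
            continue
        steps = 0 if z else int(round(np.exp(mu + eps)))
        rows.append((p.participant_id, d, steps))


def _hr_stream(rng, rows, p, dates, man, mr, cr):
    rate = rng.beta(*_beta_params(*(mr.heart_rate_men if man else mr.heart_rate_women)))
    slots = pd.date_range(dates[0], dates[-1] + pd.Timedelta(days=1), freq="30min", inclusive="left")
    covered = np.nonzero(rng.random(len(slots)) < rate)[0]
    if len(covered) == 0:
        return
    hours = slots[covered].hour + slots[covered].minute / 60.0
    bpm = 75.0 + 6.0 * np.sin(2 * np.pi * (hours - 16.0) / 24.0) + rng.normal(0, 8, len(covered))
    bpm = np.clip(bpm, 40.0, 140.0)
    bad = rng.random(len(covered)) < cr.hr_out_of_range
    low_side = rng.random(len(covered)) < 0.5
    max_hr = 208.0 - 0.7 * p.age_years
    bpm = np.where(bad & low_side, rng.uniform(15.0, 29.5, len(covered)), bpm)
    bpm = np.where(bad & ~low_side, max_hr + rng.uniform(1.0, 40.0, len(covered)), bpm)
    jitter = rng.uniform(0, 29, size=len(covered))
    for s, b, j in zip(slots[covered], bpm, jitter):
        rows.append((p.participant_id, s + pd.Timedelta(minutes=float(j)), round(float(b), 1)))


def _bodytemp_stream(rng, rows, p, dates, tmin, man, bmi, ef, mr, cr):
    cover = rng.random(len(dates)) < rng.beta(*_beta_params(*mr.body_temp))
    for d, t, covered in zip(dates, tmin, cover):
        if not covered or not np.isfinite(t):
            continue
        night_mu = (
            ef.bodytemp_intercept_c
            + ef.bodytemp_gender_effect_c * man
            + ef.bodytemp_bmi_slope * bmi
            + ef.bodytemp_temp_slope * t
            + rng.normal(0.0, ef.bodytemp_night_sd_c)
        )
        for hrs in (22.0, 0.0, 2.0, 4.0):
            offset = -2.0 if hrs >= 18 else hrs  # hours relative to midnight of d
            temp = night_mu + rng.normal(0.0, ef.bodytemp_reading_sd_c)
            if rng.random() < cr.bodytemp_out_of_range:
                temp = rng.uniform(24.0, 27.5) if rng.random() < 0.5 else rng.uniform(42.5, 44.0)
            ts = d + pd.Timedelta(hours=offset + float(rng.uniform(0, 0.5)))
            rows.append((p.participant_id, ts, round(float(temp), 2)))


# ---------------------------------------------------------------------------
# one-call dataset

def generate_dataset(cfg: SynthConfig, threshold_cfg: ThresholdConfig | None = None) -> dict:
    """Simulate weather, cohort and wearable streams in one deterministic call.

    Returns a dict with keys ``weather``, ``roster``, ``exposures`` (the
    daily summary used to plant the effects), ``sleep_episodes``, ``steps``,
    ``heart_rate``, ``body_temp``.
    """
    threshold_cfg = threshold_cfg or ThresholdConfig()
    rng_w, rng_c, rng_s = _rngs(cfg)
    weather = simulate_weather(cfg, rng_w)
    roster = simulate_cohort(cfg, rng_c)
    exposures = summarize_days(weather, threshold_cfg)
    streams = simulate_wearable_streams(roster, exposures, cfg, rng_s)
    return {"weather": weather, "roster": roster, "exposures": exposures, **streams}


def write_dataset(dataset: dict, outdir) -> dict:
    """Materialize a generated dataset as the CSV files the pipeline consumes."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = {
        "weather": "weather.csv",
        "roster": "participants.csv",
        "sleep_episodes": "sleep_episodes.csv",
        "steps": "steps.csv",
        "heart_rate": "heart_rate.csv",
        "body_temp": "body_temp.csv",
    }
    paths = {}
    for key, fname in names.items():
        path = outdir / fname
        dataset[key].to_csv(path, index=False)
        paths[key] = path
    return paths
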