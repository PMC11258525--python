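"""Daily heat-stress exposure from 15-minute weather-station records.

A station stream (air temperature, natural wet-bulb temperature, relative
humidity, global radiation, rainfall at 15-minute cadence) is reduced to one
row per calendar day carrying the daily maxima and the nighttime minima of
three heat indicators — air temperature, wet bulb globe temperature (WBGT)
and the NWS heat index — plus the daily rainfall total. Days are then flagged
against occupational WBGT limits (per metabolic-rate class) and the NWS heat
index risk categories, and tallied into a threshold-exceedance table.

Column schema for a weather frame::

    timestamp, air_temp_c, wet_bulb_temp_c, relative_humidity_pct,
    global_radiation_wm2, rainfall_mm

Timestamps are naive local time (the study region does not observe DST).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rounding import round_half_up

logger = logging.getLogger(__name__)

WEATHER_COLUMNS = [
    "timestamp",
    "air_temp_c",
    "wet_bulb_temp_c",
    "relative_humidity_pct",
    "global_radiation_wm2",
    "rainfall_mm",
]

#: WBGT metabolic-rate classes, from the most demanding work (lowest limit) up.
WBGT_CLASSES = ["very_high_metabolic", "high_metabolic", "medium_metabolic"]

#: Heat-index risk categories in increasing order of severity.
HI_CATEGORIES = ["none", "caution", "extreme_caution", "danger"]

# Nominal 15-minute cadence.
SLOTS_PER_DAY = 96


def fahrenheit_to_celsius(t_f):
    return (np.asarray(t_f, dtype=float) - 32.0) * 5.0 / 9.0


def celsius_to_fahrenheit(t_c):
    return np.asarray(t_c, dtype=float) * 9.0 / 5.0 + 32.0


@dataclass(frozen=True)
class ThresholdConfig:
    """Risk thresholds and windowing conventions for daily summaries.

    Heat-index limits are the NWS category boundaries (80/90/103 °F expressed
    in °C). WBGT limits default to ISO-7243-style acclimatized reference
    values per metabolic-rate class; the source tables name the classes
    without printing °C values, so these are configurable. ``night_window``
    is the (start_hour, end_hour) clock interval, spanning midnight, whose
    minima are attributed to the morning's date.
    """

    hi_caution_c: float = 26.67
    hi_extreme_c: float = 32.22
    hi_danger_c: float = 39.44
    wbgt_limits_c: dict = field(
        default_factory=lambda: {
            "very_high_metabolic": 23.0,
            "high_metabolic": 26.0,
            "medium_metabolic": 28.0,
        }
    )
    heavy_rain_mm: float = 20.0
    night_window: tuple = (18, 8)
    wbgt_mapping: str = "as_printed"
    #: WBGT flags use strict '>' ("exceeded"); heat index uses '>=' ("reached").
    wbgt_exceed_strict: bool = True
    hi_reached_inclusive: bool = True
    #: minimum fraction of expected 15-min slots for a max/min to be non-missing
    min_slot_fraction: float = 0.5

    def __post_init__(self):
        if not (self.hi_caution_c < self.hi_extreme_c < self.hi_danger_c):
            raise ValueError("heat-index thresholds must be strictly increasing")
        lims = [self.wbgt_limits_c[c] for c in WBGT_CLASSES]
        if not (lims[0] < lims[1] < lims[2]):
            raise ValueError(
                "WBGT limits must increase strictly from very_high to medium metabolic rate"
            )

    @property
    def hi_thresholds(self):
        return {
            "caution": self.hi_caution_c,
            "extreme_caution": self.hi_extreme_c,
            "danger": self.hi_danger_c,
        }


def compute_wbgt(w, y, x, z, mapping: str = "as_printed"):
    """Wet bulb globe temperature (°C) for outdoor (sun-exposed) conditions.

    Parameters
    ----------
    w : natural wet-bulb temperature, °C
    y : global radiation, W/m²
    x : relative humidity, %
    z : air (dry-bulb) temperature, °C
    mapping : ``"as_printed"`` or ``"literature_swap"``

    The index is the weighted sum 0.7·Tw + 0.2·Tg + 0.1·Td where the globe
    temperature Tg is estimated from radiation, humidity and air temperature.
    Two variable mappings are provided because the formula circulates in two
    forms that differ in which of humidity and air temperature enters the
    globe estimate's linear term and the final 0.1 weight:

    - ``as_printed``: 0.7·w + 0.2·(0.009624·y − 0.00404·z + 1.102·x − 2.2776) + 0.1·x
    - ``literature_swap``: 0.7·w + 0.2·(0.009624·y − 0.00404·x + 1.102·z − 2.2776) + 0.1·z

    The swapped form (humidity in the small negative term, air temperature
    carrying the 1.102 coefficient and the 0.1 weight) matches the original
    outdoor-WBGT estimation literature and yields values on the usual WBGT
    scale at tropical humidity; ``as_printed`` is the default for fidelity to
    the formula as published in the field protocol this package follows.
    """
    w = np.asarray(w, dtype=float)
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    for name, arr in (("w", w), ("y", y), ("x", x), ("z", z)):
        if not np.all(np.isfinite(arr) | np.isnan(arr)):
            raise ValueError(f"non-finite value in WBGT input {name!r}")
    if np.any((x < 0) | (x > 100)):
        raise ValueError("relative humidity must lie in [0, 100]")
    if mapping == "as_printed":
        globe = 0.009624 * y - 0.00404 * z + 1.102 * x - 2.2776
        out = 0.7 * w + 0.2 * globe + 0.1 * x
    elif mapping == "literature_swap":
        globe = 0.009624 * y - 0.00404 * x + 1.102 * z - 2.2776
        out = 0.7 * w + 0.2 * globe + 0.1 * z
    else:
        raise ValueError(f"unknown WBGT mapping {mapping!r}")
    return out.item() if out.ndim == 0 else out


def compute_heat_index(air_temp_c, rh):
    """NWS heat index (apparent temperature), °C.

    Computed in °F internally. The simple Steadman formula
    ``0.5*(T + 61 + (T-68)*1.2 + RH*0.094)`` is used whenever its average
    with the air temperature is below 80 °F; otherwise the Rothfusz
    regression applies, with the standard low-humidity (RH < 13 %,
    80–112 °F) and high-humidity (RH > 85 %, 80–87 °F) adjustments.
    """
    t = celsius_to_fahrenheit(air_temp_c)
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100]")
    t, rh = np.broadcast_arrays(t, rh)
    simple = 0.5 * (t + 61.0 + (t - 68.0) * 1.2 + rh * 0.094)

    hi = (
        -42.379
        + 2.04901523 * t
        + 10.14333127 * rh
        - 0.22475541 * t * rh
        - 0.00683783 * t * t
        - 0.05481717 * rh * rh
        + 0.00122874 * t * t * rh
        + 0.00085282 * t * rh * rh
        - 0.00000199 * t * t * rh * rh
    )
    low = (rh < 13) & (t >= 80) & (t <= 112)
    with np.errstate(invalid="ignore"):
        adj_low = ((13.0 - rh) / 4.0) * np.sqrt(np.clip(17.0 - np.abs(t - 95.0), 0.0, None) / 17.0)
    hi = np.where(low, hi - adj_low, hi)
    high = (rh > 85) & (t >= 80) & (t <= 87)
    adj_high = ((rh - 85.0) / 10.0) * ((87.0 - t) / 5.0)
    hi = np.where(high, hi + adj_high, hi)

    out_f = np.where(0.5 * (simple + t) < 80.0, simple, hi)
    out = fahrenheit_to_celsius(out_f)
    return out.item() if out.ndim == 0 else out


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    validate_weather_frame(df)
    return df


def validate_weather_frame(df: pd.DataFrame) -> None:
    """Range and ordering checks for a station stream; raises ValueError."""
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather frame missing columns: {missing}")
    rh = df["relative_humidity_pct"]
    if ((rh < 0) | (rh > 100)).any():
        raise ValueError("relative_humidity_pct outside [0, 100]")
    if (df["rainfall_mm"] < 0).any():
        raise ValueError("negative rainfall_mm")
    # +0.5 °C tolerance for sensor noise on the wet-bulb depression
    if (df["wet_bulb_temp_c"] > df["air_temp_c"] + 0.5).any():
        raise ValueError("wet_bulb_temp_c exceeds air_temp_c beyond 0.5 °C tolerance")
    ts = pd.to_datetime(df["timestamp"])
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("timestamps must be strictly increasing")


def _night_date(ts: pd.Series, night_window) -> pd.Series:
    """Map each timestamp inside the night window to the morning's date.

    Timestamps outside the window map to NaT. The window spans midnight
    (start_hour in the evening, end_hour the next morning).
    """
    start_h, end_h = night_window
    hours = ts.dt.hour + ts.dt.minute / 60.0
    date = ts.dt.normalize()
    out = pd.Series(pd.NaT, index=ts.index)
    evening = hours >= start_h
    morning = hours < end_h
    out[evening] = date[evening] + pd.Timedelta(days=1)
    out[morning] = date[morning]
    return out


def _expected_night_slots(night_window) -> int:
    start_h, end_h = night_window
    return int(round(((24 - start_h) + end_h) * 4))


def _augment(df: pd.DataFrame, cfg: ThresholdConfig) -> pd.DataFrame:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    out["wbgt_c"] = compute_wbgt(
        out["wet_bulb_temp_c"].to_numpy(),
        out["global_radiation_wm2"].to_numpy(),
        out["relative_humidity_pct"].to_numpy(),
        out["air_temp_c"].to_numpy(),
        mapping=cfg.wbgt_mapping,
    )
    out["heat_index_c"] = compute_heat_index(
        out["air_temp_c"].to_numpy(), out["relative_humidity_pct"].to_numpy()
    )
    out["date"] = out["timestamp"].dt.normalize()
    out["night_date"] = _night_date(out["timestamp"], cfg.night_window)
    return out


_METRICS = {"temp": "air_temp_c", "wbgt": "wbgt_c", "heat_index": "heat_index_c"}


def summarize_day(obs: pd.DataFrame, date, cfg: ThresholdConfig | None = None) -> pd.Series:
    """One day's exposure summary (see :func:`summarize_days` for columns)."""
    cfg = cfg or ThresholdConfig()
    date = pd.Timestamp(date).normalize()
    return summarize_days(obs, cfg, dates=[date]).iloc[0]


def summarize_days(
    obs: pd.DataFrame, cfg: ThresholdConfig | None = None, dates=None
) -> pd.DataFrame:
    """Reduce a station stream to per-day exposure summaries.

    Daily maxima are taken over 00:00–24:00 of each date; nighttime minima
    over the configured night window ending on the date's morning; rainfall
    is summed per date. A max/min is emitted only when at least
    ``cfg.min_slot_fraction`` of the expected 15-minute slots are present,
    otherwise the field is NaN. Dates with no observations at all are still
    emitted (all-missing) with a logged warning.
    """
    cfg = cfg or ThresholdConfig()
    aug = _augment(obs, cfg)
    if dates is None:
        dates = pd.date_range(aug["date"].min(), aug["date"].max(), freq="D")
    else:
        dates = pd.DatetimeIndex([pd.Timestamp(d).normalize() for d in dates])

    day_g = aug.groupby("date")
    day_max = day_g[list(_METRICS.values())].max()
    day_n = day_g.size()
    rain = day_g["rainfall_mm"].sum()

    night = aug.dropna(subset=["night_date"])
    night_g = night.groupby("night_date")
    night_min = night_g[list(_METRICS.values())].min()
    night_n = night_g.size()

    min_day = cfg.min_slot_fraction * SLOTS_PER_DAY
    min_night = cfg.min_slot_fraction * _expected_night_slots(cfg.night_window)

    rows = []
    for d in dates:
        row = {"date": d}
        nd = int(day_n.get(d, 0))
        nn = int(night_n.get(d, 0))
        if nd == 0 and nn == 0:
            logger.warning("no weather observations for %s; emitting all-missing day", d.date())
        for key, col in _METRICS.items():
            row[f"{key}_max_c"] = day_max.at[d, col] if (nd >= min_day and d in day_max.index) else np.nan
            row[f"{key}_min_night_c"] = (
                night_min.at[d, col] if (nn >= min_night and d in night_min.index) else np.nan
            )
        row["rain_total_mm"] = float(rain.get(d, np.nan)) if nd > 0 else np.nan
        row["n_day_obs"] = nd
        row["n_night_obs"] = nn
        rows.append(row)
    out = pd.DataFrame(rows)
    out["heavy_rain"] = (out["rain_total_mm"] >= cfg.heavy_rain_mm).astype("boolean")
    out.loc[out["rain_total_mm"].isna(), "heavy_rain"] = pd.NA
    return classify_heat_days(out, cfg)


def classify_heat_day(summary: pd.Series, cfg: ThresholdConfig | None = None) -> pd.Series:
    """Fill exceedance flags and the heat-index risk category for one day."""
    return classify_heat_days(summary.to_frame().T, cfg or ThresholdConfig()).iloc[0]


def classify_heat_days(days: pd.DataFrame, cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    cfg = cfg or ThresholdConfig()
    out = days.copy()
    wbgt = pd.to_numeric(out["wbgt_max_c"], errors="coerce")
    for cls in WBGT_CLASSES:
        lim = cfg.wbgt_limits_c[cls]
        flag = wbgt > lim if cfg.wbgt_exceed_strict else wbgt >= lim
        flag = flag.astype("boolean")
        flag[wbgt.isna()] = pd.NA  # unknown, counted separately downstream
        out[f"wbgt_exceeds_{cls}"] = flag

    hi = pd.to_numeric(out["heat_index_max_c"], errors="coerce")
    cat = pd.Series("none", index=out.index, dtype=object)
    for name, thr in cfg.hi_thresholds.items():
        reached = hi >= thr if cfg.hi_reached_inclusive else hi > thr
        cat[reached.fillna(False)] = name
    cat[hi.isna()] = "unknown"
    out["hi_category"] = cat
    return out


def exceedance_summary(days: pd.DataFrame, cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Threshold-exceedance tallies over the study period.

    One row per WBGT metabolic-rate class, per heat-index limit (cumulative
    "reached at least this limit" counts, so a danger day also counts toward
    caution), plus rainfall rows. Percentages are taken over days with the
    relevant field non-missing and rounded half-up to one decimal.
    """
    cfg = cfg or ThresholdConfig()
    if len(days) == 0:
        raise ValueError("exceedance_summary requires at least one day")
    days = classify_heat_days(days, cfg)
    rows = []

    def add(reference, flags: pd.Series):
        known = flags.notna()
        n = int((flags[known].astype(bool)).sum())
        denom = int(known.sum())
        pct = round_half_up(100.0 * n / denom, 1) if denom else np.nan
        rows.append(
            {
                "reference": reference,
                "n_days": n,
                "n_known": denom,
                "n_unknown": int((~known).sum()),
                "pct_days": pct,
            }
        )

    for cls in WBGT_CLASSES:
        add(f"wbgt_{cls}", days[f"wbgt_exceeds_{cls}"])
    hi = pd.to_numeric(days["heat_index_max_c"], errors="coerce")
    for name, thr in cfg.hi_thresholds.items():
        reached = (hi >= thr) if cfg.hi_reached_inclusive else (hi > thr)
        flags = reached.astype("boolean")
        flags[hi.isna()] = pd.NA
        add(f"heat_index_{name}", flags)
    rain = pd.to_numeric(days["rain_total_mm"], errors="coerce")
    rainy = (rain > 0).astype("boolean")
    rainy[rain.isna()] = pd.NA
    add("rain_days", rainy)
    add("heavy_rain_days", days["heavy_rain"].astype("boolean"))
    return pd.DataFrame(rows)


def with_mapping(cfg: ThresholdConfig, mapping: str) -> ThresholdConfig:
    return replace(cfg, wbgt_mapping=mapping)
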