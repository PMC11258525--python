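"""Validity filtering and assembly of raw wearable streams.

Four streams are quality-controlled per participant:

- **sleep**: wearable-detected sleep episodes are merged into nights (an
  episode longer than 3 h joins the current night block while it starts
  before noon of the day after the block's first episode), wake minutes are
  subtracted, and nights shorter than 3 h or longer than 13 h are rejected.
- **heart rate**: readings below 30 bpm or above the age-predicted maximum
  (208 − 0.7·age) are rejected.
- **body shell temperature**: readings outside a physiological plausibility
  band (default 28–42 °C: hypothermic loss of consciousness below, protein
  denaturation above) are rejected; kept readings are averaged per night.
- **steps**: daily totals; zero counts are treated as non-wear (missing) by
  default because an unworn device and a genuinely stationary day are
  indistinguishable and a zero breaks the log-scale association models.

Participant demographics (BMI class, age group) drive both the filters and
the downstream confounder adjustment.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SLEEP_MIN_MINUTES = 180.0   # "< 3 h (including naps)" rejected
SLEEP_MAX_MINUTES = 780.0   # "> 13 h" rejected
HR_MIN_BPM = 30.0
BODY_TEMP_BOUNDS_C = (28.0, 42.0)

AGE_GROUPS = ["school_child", "adolescent", "young_adult", "older_adult"]
BMI_CLASSES = ["underweight", "normal", "overweight"]


# ---------------------------------------------------------------------------
# demographics

def classify_bmi(bmi):
    """WHO adult BMI class: <18.5 underweight, [18.5, 25) normal, >=25 overweight.

    The printed class bounds (18.5–24.9 / >25) leave (24.9, 25) open; the
    half-open convention closes the gap at 25.0.
    """
    arr = np.asarray(bmi, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("bmi must be positive")
    out = np.where(arr < 18.5, "underweight", np.where(arr < 25.0, "normal", "overweight"))
    return out.item() if out.ndim == 0 else out


def assign_age_group(age_years):
    """Integer-year study age groups: 6–11, 12–18, 19–45, >45."""
    arr = np.asarray(age_years, dtype=float)
    if np.any(arr < 6):
        raise ValueError("study eligibility requires age >= 6 years")
    out = np.select(
        [arr <= 11, arr <= 18, arr <= 45],
        ["school_child", "adolescent", "young_adult"],
        default="older_adult",
    )
    return out.item() if out.ndim == 0 else out


def prepare_roster(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and annotate a participant roster.

    Requires columns ``participant_id, gender, age_years, height_m,
    weight_kg, study_arm, window_start, window_end``. Recomputes BMI from
    height/weight (cross-checked against a ``bmi`` column when present,
    tolerance 0.05), assigns ``bmi_class`` (adults only) and ``age_group``.
    """
    out = df.copy()
    for col in ("window_start", "window_end"):
        out[col] = pd.to_datetime(out[col]).dt.normalize()
    if (out["window_end"] <= out["window_start"]).any():
        raise ValueError("window_end must fall after window_start")
    if out["participant_id"].duplicated().any():
        raise ValueError("duplicate participant_id in roster")
    bmi = out["weight_kg"] / out["height_m"] ** 2
    if "bmi" in out.columns and (np.abs(out["bmi"] - bmi) > 0.05).any():
        raise ValueError("stored bmi disagrees with weight/height^2 beyond 0.05")
    out["bmi"] = bmi
    out["age_group"] = assign_age_group(out["age_years"].to_numpy())
    adult = out["age_years"] >= 19
    out["bmi_class"] = pd.NA
    out.loc[adult, "bmi_class"] = classify_bmi(out.loc[adult, "bmi"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# heart rate

def expected_max_hr(age_years):
    """Age-predicted maximum heart rate, 208 − 0.7·age (bpm)."""
    arr = np.asarray(age_years, dtype=float)
    if np.any(arr < 0):
        raise ValueError("age must be nonnegative")
    out = 208.0 - 0.7 * arr
    return out.item() if out.ndim == 0 else out


def filter_heart_rate(readings: pd.DataFrame, roster: pd.DataFrame):
    """Split HR readings into (kept, rejected-with-reason).

    Keeps 30 <= bpm <= expected_max_hr(age); both boundaries are kept since
    the exclusion rule is strict ("<30" / ">max"). Readings for participants
    absent from the roster raise.
    """
    ages = roster.set_index("participant_id")["age_years"]
    unknown = set(readings["participant_id"]) - set(ages.index)
    if unknown:
        raise ValueError(f"heart-rate readings for unknown participants: {sorted(unknown)}")
    out = readings.copy()
    max_hr = out["participant_id"].map(ages).astype(float).pipe(expected_max_hr)
    low = out["bpm"] < HR_MIN_BPM
    high = out["bpm"] > max_hr
    out["reject_reason"] = np.select([low, high], ["low", "high"], default="none")
    kept = out[out["reject_reason"] == "none"].drop(columns="reject_reason")
    rejected = out[out["reject_reason"] != "none"]
    return kept, rejected


# ---------------------------------------------------------------------------
# sleep

def _check_overlaps(eps: pd.DataFrame) -> None:
    for pid, grp in eps.groupby("participant_id"):
        grp = grp.sort_values("start")
        collide = grp["start"].iloc[1:].to_numpy() < grp["end"].iloc[:-1].to_numpy()
        if collide.any():
            i = int(np.argmax(collide))
            a, b = grp.iloc[i], grp.iloc[i + 1]
            raise ValueError(
                f"overlapping sleep episodes for {pid}: "
                f"[{a['start']}, {a['end']}] overlaps [{b['start']}, {b['end']}]"
            )


def assemble_nights(episodes: pd.DataFrame, participant_id=None) -> pd.DataFrame:
    """Group sleep episodes into candidate nights (pre-validation).

    Episodes longer than 180 min open or extend a night block: each
    subsequent long episode joins the block while it starts before 12:00 of
    the calendar day following the block's *first* episode's start date.
    Episodes of 180 min or less (naps) stay stand-alone candidates and never
    merge. Per night, sleep_minutes = Σ(duration − wake_minutes); the night
    is keyed by the date of the block's end (the morning the night ends).

    Columns in: participant_id, start, end, wake_minutes.
    Columns out: participant_id, night_date, sleep_minutes, n_episodes,
    block_start, block_end.
    """
    eps = episodes.copy()
    if participant_id is not None and "participant_id" not in eps.columns:
        eps["participant_id"] = participant_id
    eps["start"] = pd.to_datetime(eps["start"])
    eps["end"] = pd.to_datetime(eps["end"])
    if (eps["end"] <= eps["start"]).any():
        raise ValueError("sleep episode with end <= start")
    dur = (eps["end"] - eps["start"]).dt.total_seconds() / 60.0
    if (eps["wake_minutes"] < 0).any() or (eps["wake_minutes"] > dur + 1e-9).any():
        raise ValueError("wake_minutes must lie in [0, episode duration]")
    eps["duration_min"] = dur
    _check_overlaps(eps)

    records = []
    for pid, grp in eps.groupby("participant_id"):
        grp = grp.sort_values("start")
        block = []  # current night block of long episodes
        deadline = None

        def close():
            if not block:
                return
            sleep = sum(e["duration_min"] - e["wake_minutes"] for e in block)
            records.append(
                {
                    "participant_id": pid,
                    "night_date": block[-1]["end"].normalize(),
                    "sleep_minutes": float(sleep),
                    "n_episodes": len(block),
                    "block_start": block[0]["start"],
                    "block_end": block[-1]["end"],
                }
            )
            block.clear()

        for _, ep in grp.iterrows():
            if ep["duration_min"] <= SLEEP_MIN_MINUTES:
                # nap-length episode: stand-alone candidate, fails validation later
                records.append(
                    {
                        "participant_id": pid,
                        "night_date": ep["end"].normalize(),
                        "sleep_minutes": float(ep["duration_min"] - ep["wake_minutes"]),
                        "n_episodes": 1,
                        "block_start": ep["start"],
                        "block_end": ep["end"],
                    }
                )
                continue
            if block and ep["start"] < deadline:
                block.append(ep)
            else:
                close()
                block.append(ep)
                deadline = ep["start"].normalize() + pd.Timedelta(days=1, hours=12)
        close()
    return pd.DataFrame(
        records,
        columns=[
            "participant_id",
            "night_date",
            "sleep_minutes",
            "n_episodes",
            "block_start",
            "block_end",
        ],
    )


def validate_sleep(nights: pd.DataFrame) -> pd.DataFrame:
    """Flag nights outside [180, 780] min as invalid (too_short / too_long)."""
    out = nights.copy()
    if (out["sleep_minutes"] < 0).any():
        raise ValueError("negative sleep_minutes")
    short = out["sleep_minutes"] < SLEEP_MIN_MINUTES
    long = out["sleep_minutes"] > SLEEP_MAX_MINUTES
    out["reject_reason"] = np.select([short, long], ["too_short", "too_long"], default="none")
    out["valid"] = out["reject_reason"] == "none"
    return out


# ---------------------------------------------------------------------------
# body shell temperature

def filter_body_temp(readings: pd.DataFrame, bounds=BODY_TEMP_BOUNDS_C):
    """Split body-temperature readings into (kept, rejected) by plausibility band."""
    low, high = bounds
    if not low < high:
        raise ValueError("body-temp bounds must satisfy low < high")
    t = readings["temp_c"]
    keep = (t >= low) & (t <= high)
    rejected = readings[~keep].copy()
    rejected["reject_reason"] = np.where(t[~keep] < low, "hypothermia_range", "denaturation_range")
    return readings[keep].copy(), rejected


def nightly_mean_body_temp(kept: pd.DataFrame, night_window=(18, 8)) -> pd.DataFrame:
    """Per participant-night arithmetic mean of kept readings.

    Readings are attributed to the morning date of the night window they fall
    in; daytime readings are ignored. Nights with no kept readings are simply
    absent (missing).
    """
    from .weather import _night_date

    df = kept.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["night_date"] = _night_date(df["timestamp"], night_window)
    df = df.dropna(subset=["night_date"])
    out = (
        df.groupby(["participant_id", "night_date"], as_index=False)
        .agg(temp_c_mean=("temp_c", "mean"), n_readings=("temp_c", "size"))
    )
    return out


# ---------------------------------------------------------------------------
# steps

def filter_steps(steps: pd.DataFrame, zero_is_nonwear: bool = True):
    """Split daily step counts into (kept, rejected).

    Zero counts default to non-wear days and are rejected with reason
    ``nonwear_zero``; negative counts always reject.
    """
    s = steps.copy()
    neg = s["steps"] < 0
    zero = (s["steps"] == 0) & zero_is_nonwear
    s["reject_reason"] = np.select([neg, zero], ["negative", "nonwear_zero"], default="none")
    kept = s[s["reject_reason"] == "none"].drop(columns="reject_reason")
    return kept, s[s["reject_reason"] != "none"]


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class QCResult:
    """QC'd streams plus the consolidated rejection log."""

    nights: pd.DataFrame          # validated nights incl. invalid ones (flagged)
    valid_nights: pd.DataFrame
    steps: pd.DataFrame
    heart_rate: pd.DataFrame
    body_temp_readings: pd.DataFrame
    body_temp_nights: pd.DataFrame
    rejections: pd.DataFrame      # participant_id, stream, timestamp, reason


def run_qc(
    roster: pd.DataFrame,
    sleep_episodes: pd.DataFrame,
    steps: pd.DataFrame,
    heart_rate: pd.DataFrame,
    body_temp: pd.DataFrame,
    body_temp_bounds=BODY_TEMP_BOUNDS_C,
    night_window=(18, 8),
    zero_steps_nonwear: bool = True,
) -> QCResult:
    """Apply every stream filter and assemble the rejection log."""
    rej = []

    nights = validate_sleep(assemble_nights(sleep_episodes))
    for _, r in nights[~nights["valid"]].iterrows():
        rej.append((r["participant_id"], "sleep", r["block_end"], r["reject_reason"]))
    valid_nights = nights[nights["valid"]].drop(columns=["reject_reason", "valid"])

    steps_kept, steps_rej = filter_steps(steps, zero_is_nonwear=zero_steps_nonwear)
    for _, r in steps_rej.iterrows():
        rej.append((r["participant_id"], "steps", r["date"], r["reject_reason"]))

    hr_kept, hr_rej = filter_heart_rate(heart_rate, roster)
    for _, r in hr_rej.iterrows():
        rej.append((r["participant_id"], "heart_rate", r["timestamp"], r["reject_reason"]))

    bt_kept, bt_rej = filter_body_temp(body_temp, bounds=body_temp_bounds)
    for _, r in bt_rej.iterrows():
        rej.append((r["participant_id"], "body_temp", r["timestamp"], r["reject_reason"]))
    bt_nights = nightly_mean_body_temp(bt_kept, night_window=night_window)

    rejections = pd.DataFrame(rej, columns=["participant_id", "stream", "timestamp", "reason"])
    logger.info(
        "QC: %d nights (%d valid), %d step-days kept, %d HR kept, %d body-temp kept; %d rejections",
        len(nights), len(valid_nights), len(steps_kept), len(hr_kept), len(bt_kept), len(rejections),
    )
    return QCResult(
        nights=nights,
        valid_nights=valid_nights,
        steps=steps_kept,
        heart_rate=hr_kept,
        body_temp_readings=bt_kept,
        body_temp_nights=bt_nights,
        rejections=rejections,
    )
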