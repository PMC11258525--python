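"""Data-completeness quantification and group comparisons.

Completeness of a wearable variable for one participant is the fraction of
the study window covered by at least one valid measurement, counted in the
variable's natural interval unit: nights for sleep and body temperature,
days for step counts, and 30-minute slots for heart rate (the PPG sensor
samples opportunistically, so a coarse slot grid is the honest unit).

Completeness is then compared across demographic strata (gender, study arm,
age groups, BMI class) with a Welch two-sided t test and a Mann-Whitney U
test, both with 95% confidence intervals, and the resulting p-value family
is corrected with the Holm step-down procedure.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VARIABLES = ["sleep", "steps", "heart_rate", "body_temp"]

#: interval unit per variable: "night", "day", or a slot width in minutes
DEFAULT_CADENCE = {"sleep": "night", "steps": "day", "heart_rate": 30, "body_temp": "night"}


@dataclass(frozen=True)
class CompletenessRecord:
    participant_id: str
    variable: str
    covered_units: int
    expected_units: int

    @property
    def fraction(self) -> float:
        return self.covered_units / self.expected_units

    def __post_init__(self):
        if not 0 <= self.covered_units <= self.expected_units:
            raise ValueError("covered_units must lie in [0, expected_units]")


def _units_in_window(window_start, window_end, unit):
    """Number of interval units in the inclusive date window."""
    n_days = (window_end - window_start).days + 1
    if unit in ("night", "day"):
        return n_days
    return n_days * (24 * 60 // int(unit))


def coverage_fraction(
    record_times,
    window_start,
    window_end,
    variable: str,
    participant_id: str = "",
    cadence: dict | None = None,
) -> CompletenessRecord:
    """Completeness of one participant's stream over their study window.

    ``record_times`` are the timestamps (heart rate) or unit dates
    (sleep/steps/body-temp nights and days) of *valid* records; duplicates
    within a unit count once. Records outside the window are ignored.
    """
    cadence = cadence or DEFAULT_CADENCE
    unit = cadence[variable]
    window_start = pd.Timestamp(window_start).normalize()
    window_end = pd.Timestamp(window_end).normalize()
    if window_end < window_start:
        raise ValueError("empty study window")
    expected = _units_in_window(window_start, window_end, unit)

    times = pd.to_datetime(pd.Series(list(record_times)))
    if len(times) == 0:
        return CompletenessRecord(participant_id, variable, 0, expected)
    if unit in ("night", "day"):
        units = times.dt.normalize()
        inside = (units >= window_start) & (units <= window_end)
        covered = units[inside].nunique()
    else:
        slots = times.dt.floor(f"{int(unit)}min")
        inside = (slots >= window_start) & (slots < window_end + pd.Timedelta(days=1))
        covered = slots[inside].nunique()
    return CompletenessRecord(participant_id, variable, int(covered), int(expected))


def completeness_table(
    roster: pd.DataFrame,
    qc,
    cadence: dict | None = None,
) -> pd.DataFrame:
    """Per-participant, per-variable completeness for a whole cohort.

    ``qc`` is a :class:`heatwear.qc.QCResult`; every participant appears for
    every variable (zero coverage when the stream is empty for them).
    """
    cadence = cadence or DEFAULT_CADENCE
    streams = {
        "sleep": (qc.valid_nights, "night_date"),
        "steps": (qc.steps, "date"),
        "heart_rate": (qc.heart_rate, "timestamp"),
        "body_temp": (qc.body_temp_nights, "night_date"),
    }
    rows = []
    for _, p in roster.iterrows():
        for var, (df, col) in streams.items():
            times = df.loc[df["participant_id"] == p["participant_id"], col]
            rec = coverage_fraction(
                times, p["window_start"], p["window_end"], var,
                participant_id=p["participant_id"], cadence=cadence,
            )
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "variable": var,
                    "covered_units": rec.covered_units,
                    "expected_units": rec.expected_units,
                    "fraction": rec.fraction,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-sample comparisons

@dataclass
class GroupComparison:
    grouping: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    welch_t: float
    welch_df: float
    welch_p: float
    welch_ci95: tuple
    mwu_u: float
    mwu_p: float
    mwu_ci95: tuple
    hodges_lehmann: float
    holm_welch_p: float = field(default=np.nan)
    holm_mwu_p: float = field(default=np.nan)


def _hodges_lehmann_ci(a, b, alpha=0.05):
    """Hodges-Lehmann shift estimate with a distribution-based 95% CI.

    The point estimate is the median of all pairwise differences a_i − b_j;
    the CI takes the k-th smallest/largest pairwise differences with k from
    the normal approximation to the Mann-Whitney null distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    m = diffs.size
    est = float(np.median(diffs))
    n1, n2 = len(a), len(b)
    z = stats.norm.ppf(1 - alpha / 2)
    c = n1 * n2 / 2 - z * np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    k = int(np.floor(c))
    k = max(k, 0)
    if k >= m // 2:  # too few pairs for a proper interval
        return est, (diffs[0], diffs[-1])
    return est, (float(diffs[k]), float(diffs[m - 1 - k]))


def compare_groups(values_a, values_b, grouping: str = "") -> GroupComparison:
    """Welch t and Mann-Whitney U comparison of two samples with 95% CIs.

    Welch uses the unequal-variance t statistic with Welch–Satterthwaite
    degrees of freedom and a t-based CI on the mean difference. The MWU test
    uses the normal approximation with tie and continuity corrections; its
    CI is the Hodges–Lehmann interval on the location shift. Two identical
    zero-variance samples return t=0, p=1 rather than erroring.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("compare_groups needs n >= 2 per group for the Welch test")

    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            t_stat, df, p_t, ci_t = 0.0, float(len(a) + len(b) - 2), 1.0, (0.0, 0.0)
        else:
            t_stat = np.inf if a.mean() > b.mean() else -np.inf
            df, p_t = float(len(a) + len(b) - 2), 0.0
            d = a.mean() - b.mean()
            ci_t = (d, d)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p_t = float(res.statistic), float(res.pvalue)
        df = float(res.df)
        ci = res.confidence_interval(0.95)
        ci_t = (float(ci.low), float(ci.high))

    mwu = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    hl, ci_m = _hodges_lehmann_ci(a, b)

    return GroupComparison(
        grouping=grouping,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        welch_t=t_stat,
        welch_df=df,
        welch_p=p_t,
        welch_ci95=ci_t,
        mwu_u=float(mwu.statistic),
        mwu_p=float(mwu.pvalue),
        mwu_ci95=ci_m,
        hodges_lehmann=hl,
    )


def holm_adjust(p_values):
    """Holm step-down adjusted p-values, returned in the input order.

    adjusted_(i) = max_{j<=i} min(1, (m−j+1)·p_(j)) over the ascending order
    statistics; monotone and never smaller than the raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adjusted_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


# ---------------------------------------------------------------------------
# the study's comparison battery

def _strata(roster: pd.DataFrame):
    """(label, mask_a, mask_b) pairs for the demographic contrasts."""
    adult = roster["age_years"] >= 19
    yield "gender_women_vs_men_adults", adult & (roster["gender"] == "woman"), adult & (
        roster["gender"] == "man"
    )
    yield "arm_wphr_only_vs_plus_patch", roster["study_arm"] == "wphr_only", roster[
        "study_arm"
    ] == "wphr_plus_patch"
    groups = ["school_child", "adolescent", "young_adult", "older_adult"]
    for g1, g2 in itertools.combinations(groups, 2):
        yield f"age_{g1}_vs_{g2}", roster["age_group"] == g1, roster["age_group"] == g2
    yield "bmi_normal_vs_overweight_adults", adult & (roster["bmi_class"] == "normal"), adult & (
        roster["bmi_class"] == "overweight"
    )


def comparison_battery(
    completeness: pd.DataFrame, roster: pd.DataFrame, variables=VARIABLES
) -> pd.DataFrame:
    """Run every demographic contrast per variable and Holm-correct the family.

    Contrasts with fewer than two participants on either side are skipped
    with a log note. Holm correction is applied across the whole family,
    separately for the Welch and MWU p-values.
    """
    wide = completeness.pivot(index="participant_id", columns="variable", values="fraction")
    roster = roster.set_index("participant_id")
    results = []
    for var in variables:
        frac = wide[var].reindex(roster.index)
        for label, mask_a, mask_b in _strata(roster.reset_index()):
            a = frac[mask_a.to_numpy()].dropna()
            b = frac[mask_b.to_numpy()].dropna()
            if len(a) < 2 or len(b) < 2:
                logger.info("skipping %s/%s: group too small (%d vs %d)", var, label, len(a), len(b))
                continue
            results.append((var, compare_groups(a, b, grouping=label)))
    if not results:
        return pd.DataFrame()
    welch_adj = holm_adjust([c.welch_p for _, c in results])
    mwu_adj = holm_adjust([c.mwu_p for _, c in results])
    rows = []
    for (var, c), wp, mp in zip(results, welch_adj, mwu_adj):
        c.holm_welch_p = float(wp)
        c.holm_mwu_p = float(mp)
        rows.append(
            {
                "variable": var,
                "grouping": c.grouping,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "mean_a": c.mean_a,
                "mean_b": c.mean_b,
                "welch_t": c.welch_t,
                "welch_df": c.welch_df,
                "welch_p": c.welch_p,
                "welch_ci_low": c.welch_ci95[0],
                "welch_ci_high": c.welch_ci95[1],
                "mwu_u": c.mwu_u,
                "mwu_p": c.mwu_p,
                "hodges_lehmann": c.hodges_lehmann,
                "mwu_ci_low": c.mwu_ci95[0],
                "mwu_ci_high": c.mwu_ci95[1],
                "holm_welch_p": c.holm_welch_p,
                "holm_mwu_p": c.holm_mwu_p,
            }
        )
    return pd.DataFrame(rows)
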