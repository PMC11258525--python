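"""Exposure–response regression on the participant-day panel.

Each health outcome (daily step count, nightly sleep duration, nightly mean
body shell temperature) is paired with a same-day or same-night heat
exposure and fitted by pooled ordinary least squares, once unadjusted and
once adjusted for gender, age and BMI. Step counts enter the adjusted
models on the natural-log scale; sleep and body temperature stay on their
native scales. Observations are pooled across participants and days with no
random effects or autocorrelation correction — a deliberate simplification
whose consequences are documented in the methods note.

Eligibility follows the study protocol: adults only (age >= 19) with at
least 50% completeness for the outcome variable in question.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rounding import round_half_up  # re-exported; shared with weather tables

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisTableError",
    "SingularDesignError",
    "RegressionFit",
    "build_daily_table",
    "fit_ols",
    "run_model_suite",
    "models_frame",
    "round_half_up",
]

OUTCOMES = ["steps", "log_steps", "sleep_minutes", "body_temp"]
EXPOSURES = ["temp", "wbgt", "heat_index", "no_heavy_rain"]

#: which completeness variable gates each outcome
_COMPLETENESS_KEY = {
    "steps": "steps",
    "log_steps": "steps",
    "sleep_minutes": "sleep",
    "body_temp": "body_temp",
}

CONFOUNDERS = ["gender_man", "age_years", "bmi"]


class AnalysisTableError(ValueError):
    """No eligible participants / rows for the requested model."""


class SingularDesignError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


@dataclass
class RegressionFit:
    """Per-term estimates of one OLS fit (the results-table cell contract)."""

    outcome: str
    exposure: str
    adjusted: bool
    terms: list  # of (name, estimate, std_error, t_stat, p_value)
    n_obs: int
    r2: float
    adj_r2: float

    def term(self, name: str):
        for t in self.terms:
            if t[0] == name:
                return t
        raise KeyError(name)

    @property
    def exposure_term(self):
        return self.term("exposure")


def build_daily_table(
    qc,
    exposures: pd.DataFrame,
    roster: pd.DataFrame,
    completeness: pd.DataFrame,
    outcome: str,
    exposure: str,
    min_completeness: float = 0.5,
    min_age: float = 19.0,
) -> pd.DataFrame:
    """Join one outcome stream with its matching daily exposure.

    Step outcomes pair with the date's daily maxima (or the no-heavy-rain
    indicator); sleep and body-temperature outcomes pair with the nighttime
    minima of the night ending that morning. Rows with any missing field are
    dropped (count logged). Raises :class:`AnalysisTableError` when nothing
    survives.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    if exposure not in EXPOSURES:
        raise ValueError(f"unknown exposure {exposure!r}")
    if exposure == "no_heavy_rain" and outcome not in ("steps", "log_steps"):
        raise ValueError("the no-heavy-rain indicator exposure applies to step models only")

    comp = completeness[completeness["variable"] == _COMPLETENESS_KEY[outcome]]
    eligible_comp = set(comp.loc[comp["fraction"] >= min_completeness, "participant_id"])
    adults = roster[roster["age_years"] >= min_age]
    eligible = adults[adults["participant_id"].isin(eligible_comp)]
    if eligible.empty:
        raise AnalysisTableError(
            f"no adult participants with >= {min_completeness:.0%} completeness for "
            f"{_COMPLETENESS_KEY[outcome]}"
        )

    if outcome in ("steps", "log_steps"):
        stream = qc.steps.rename(columns={"date": "date"})
        date_col = "date"
        if exposure == "no_heavy_rain":
            expo = exposures[["date", "heavy_rain"]].copy()
            expo["x"] = 1.0 - expo["heavy_rain"].astype("float")
        else:
            expo = exposures[["date", f"{exposure}_max_c"]].rename(
                columns={f"{exposure}_max_c": "x"}
            )
        y = stream["steps"].astype(float)
        stream = stream.assign(y=np.log(y) if outcome == "log_steps" else y)
    else:
        if outcome == "sleep_minutes":
            stream = qc.valid_nights.assign(y=lambda d: d["sleep_minutes"].astype(float))
        else:
            stream = qc.body_temp_nights.assign(y=lambda d: d["temp_c_mean"].astype(float))
        date_col = "night_date"
        expo = exposures[["date", f"{exposure}_min_night_c"]].rename(
            columns={f"{exposure}_min_night_c": "x"}
        )

    stream = stream[stream["participant_id"].isin(set(eligible["participant_id"]))]
    merged = stream.merge(expo, left_on=date_col, right_on="date", how="inner")
    merged = merged.merge(
        eligible[["participant_id", "gender", "age_years", "bmi"]], on="participant_id"
    )
    merged["gender_man"] = (merged["gender"] == "man").astype(float)
    cols = ["participant_id", date_col, "y", "x", "gender_man", "age_years", "bmi"]
    out = merged[cols].rename(columns={date_col: "date"})
    n0 = len(out)
    out = out.dropna()
    if n0 - len(out):
        logger.info("build_daily_table(%s, %s): dropped %d incomplete rows", outcome, exposure, n0 - len(out))
    if out.empty:
        raise AnalysisTableError(f"analysis table empty for {outcome} ~ {exposure}")
    return out.reset_index(drop=True)


def fit_ols(table: pd.DataFrame, adjusted: bool, outcome: str = "", exposure: str = "") -> RegressionFit:
    """Pooled OLS of y on the exposure (plus confounders when adjusted).

    Estimates are ordinary least squares with SE_j = sqrt(σ̂²·[(XᵀX)⁻¹]_jj),
    σ̂² = RSS/(n−k−1), two-sided p-values from t(n−k−1), and the usual R²
    and adjusted R². Gender enters as an indicator with men = 1 (women the
    reference level).
    """
    predictors = ["x"] + (CONFOUNDERS if adjusted else [])
    X = table[predictors].to_numpy(dtype=float)
    y = table["y"].to_numpy(dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise AnalysisTableError(f"need n > {k + 1} observations, got {n}")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design, ["intercept"] + predictors)
        raise SingularDesignError(f"rank-deficient design; collinear columns: {bad}")

    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    names = ["intercept"] + ["exposure" if p == "x" else p for p in predictors]
    terms = [
        (name, float(est), float(se), float(t), float(p))
        for name, est, se, t, p in zip(names, res.params, res.bse, res.tvalues, res.pvalues)
    ]
    return RegressionFit(
        outcome=outcome,
        exposure=exposure,
        adjusted=adjusted,
        terms=terms,
        n_obs=int(res.nobs),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
    )


def _collinear_columns(design: np.ndarray, names) -> list:
    """Greedy identification of columns that do not extend the column space."""
    bad = []
    kept = design[:, :1]
    for j in range(1, design.shape[1]):
        trial = np.column_stack([kept, design[:, j]])
        if np.linalg.matrix_rank(trial) == kept.shape[1]:
            bad.append(names[j])
        else:
            kept = trial
    return bad


#: (outcome for the unadjusted model, outcome for the adjusted model, exposures)
_SUITE_PLAN = [
    ("steps", "log_steps", ["temp", "wbgt", "heat_index", "no_heavy_rain"]),
    ("sleep_minutes", "sleep_minutes", ["temp", "wbgt", "heat_index"]),
    ("body_temp", "body_temp", ["temp", "wbgt", "heat_index"]),
]


def run_model_suite(
    qc,
    exposures: pd.DataFrame,
    roster: pd.DataFrame,
    completeness: pd.DataFrame,
    min_completeness: float = 0.5,
) -> dict:
    """Fit the full unadjusted + adjusted model grid.

    Step-count models: unadjusted on raw counts per exposure (incl. the
    no-heavy-rain indicator), adjusted on natural-log counts with gender,
    age and BMI. Sleep and body temperature: unadjusted and adjusted on the
    native scale per heat exposure. Per-model failures are recorded as
    strings and the suite continues.

    Returns {(outcome, exposure, 'unadjusted'|'adjusted'): RegressionFit | str}.
    """
    results = {}
    for raw_outcome, adj_outcome, expos in _SUITE_PLAN:
        for expo in expos:
            for adjusted, outc in ((False, raw_outcome), (True, adj_outcome)):
                key = (outc, expo, "adjusted" if adjusted else "unadjusted")
                try:
                    table = build_daily_table(
                        qc, exposures, roster, completeness, outc, expo,
                        min_completeness=min_completeness,
                    )
                    results[key] = fit_ols(table, adjusted, outcome=outc, exposure=expo)
                except (AnalysisTableError, SingularDesignError) as err:
                    logger.warning("model %s failed: %s", key, err)
                    results[key] = str(err)
    return results


def models_frame(results: dict, digits: int = 2) -> pd.DataFrame:
    """Flatten a model suite into the models.csv layout.

    Estimates/SE are additionally reported rounded half-up to ``digits``
    decimals (the raw values stay in the unrounded columns).
    """
    rows = []
    for (outcome, exposure, kind), fit in results.items():
        if isinstance(fit, str):
            rows.append(
                {
                    "health_parameter": outcome, "exposure": exposure, "model": kind,
                    "term": "<error>", "estimate": np.nan, "se": np.nan, "t": np.nan,
                    "p": np.nan, "n": 0, "r2": np.nan, "adj_r2": np.nan, "note": fit,
                }
            )
            continue
        for name, est, se, t, p in fit.terms:
            rows.append(
                {
                    "health_parameter": outcome,
                    "exposure": exposure,
                    "model": kind,
                    "term": name,
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p": p,
                    "estimate_rounded": round_half_up(est, digits),
                    "se_rounded": round_half_up(se, digits),
                    "n": fit.n_obs,
                    "r2": fit.r2,
                    "adj_r2": fit.adj_r2,
                    "note": "",
                }
            )
    return pd.DataFrame(rows)
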