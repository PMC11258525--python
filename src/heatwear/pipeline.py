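"""Pipeline orchestration: configuration, stage running, reports.

``run_pipeline`` chains the stages — optional simulation, daily exposure
summarization, wearable QC, completeness + group comparisons, and the
regression suite — writing one CSV artifact per stage plus a JSON run
manifest (config hash, seed, package versions, per-stage record counts).
Reruns with the same config and inputs are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, completeness, qc, synthetic, weather
from .rounding import round_half_up

logger = logging.getLogger(__name__)

INPUT_KEYS = ["weather", "participants", "sleep_episodes", "steps", "heart_rate", "body_temp"]


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    outdir: str = "heatwear_run"
    seed: int = 0
    simulate: bool = True
    #: input CSV paths; ignored (and written) when simulate is true
    inputs: dict = field(default_factory=dict)
    thresholds: weather.ThresholdConfig = field(default_factory=weather.ThresholdConfig)
    cadence: dict = field(default_factory=lambda: dict(completeness.DEFAULT_CADENCE))
    body_temp_bounds: tuple = qc.BODY_TEMP_BOUNDS_C
    zero_steps_nonwear: bool = True
    min_completeness: float = 0.5
    synth: synthetic.SynthConfig = field(default_factory=synthetic.SynthConfig)

    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir,
            "seed": self.seed,
            "simulate": self.simulate,
            "inputs": {k: str(v) for k, v in self.inputs.items()},
            "thresholds": {
                **dataclasses.asdict(self.thresholds),
                "night_window": list(self.thresholds.night_window),
            },
            "cadence": dict(self.cadence),
            "body_temp_bounds": list(self.body_temp_bounds),
            "zero_steps_nonwear": self.zero_steps_nonwear,
            "min_completeness": self.min_completeness,
            "synth": self.synth.to_dict(),
        }
        for key in ("weather", "effects", "missingness", "contaminants"):
            sub = d["synth"][key]
            d["synth"][key] = {
                k: list(v) if isinstance(v, tuple) else v for k, v in sub.items()
            }
        d["synth"]["age_range"] = list(d["synth"]["age_range"])
        d["synth"]["adult_bmi_range"] = list(d["synth"]["adult_bmi_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        thr = dict(d.pop("thresholds", {}))
        if "night_window" in thr:
            thr["night_window"] = tuple(thr["night_window"])
        synth_d = dict(d.pop("synth", {}))
        for key, sub_cls in (
            ("weather", synthetic.WeatherParams),
            ("effects", synthetic.EffectSizes),
            ("missingness", synthetic.MissingnessRates),
            ("contaminants", synthetic.ContaminantRates),
        ):
            if key in synth_d:
                sub = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in synth_d[key].items()
                }
                synth_d[key] = sub_cls(**sub)
        for key in ("age_range", "adult_bmi_range"):
            if key in synth_d:
                synth_d[key] = tuple(synth_d[key])
        if "start_date" in synth_d:
            synth_d["start_date"] = pd.Timestamp(synth_d["start_date"])
        bounds = d.pop("body_temp_bounds", qc.BODY_TEMP_BOUNDS_C)
        return cls(
            thresholds=weather.ThresholdConfig(**thr),
            synth=synthetic.SynthConfig(**synth_d),
            body_temp_bounds=tuple(bounds),
            **d,
        )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def dump_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg: PipelineConfig) -> str:
    blob = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _load_inputs(cfg: PipelineConfig) -> dict:
    missing = [k for k in INPUT_KEYS if k not in cfg.inputs or not Path(cfg.inputs[k]).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing input files for {missing}; set simulate: true or point "
            f"'inputs' at existing CSVs"
        )
    data = {"weather": weather.read_weather_csv(cfg.inputs["weather"])}
    data["roster"] = pd.read_csv(cfg.inputs["participants"])
    data["sleep_episodes"] = pd.read_csv(
        cfg.inputs["sleep_episodes"], parse_dates=["start", "end"]
    )
    data["steps"] = pd.read_csv(cfg.inputs["steps"], parse_dates=["date"])
    data["heart_rate"] = pd.read_csv(cfg.inputs["heart_rate"], parse_dates=["timestamp"])
    data["body_temp"] = pd.read_csv(cfg.inputs["body_temp"], parse_dates=["timestamp"])
    return data


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    On a stage failure the partial outputs remain in place and the manifest
    records the failing stage before the exception propagates.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "versions": _versions(),
        "stages": {},
        "failed_stage": None,
    }
    dump_config(cfg, outdir / "config.yaml")

    stage = "simulate"
    try:
        if cfg.simulate:
            synth_cfg = dataclasses.replace(cfg.synth, seed=cfg.seed)
            dataset = synthetic.generate_dataset(synth_cfg, cfg.thresholds)
            synthetic.write_dataset(dataset, outdir / "inputs")
            roster_raw = dataset["roster"]
            streams = {k: dataset[k] for k in ("sleep_episodes", "steps", "heart_rate", "body_temp")}
            weather_df = dataset["weather"]
            manifest["stages"]["simulate"] = {
                "weather_rows": len(weather_df),
                "participants": len(roster_raw),
                **{k: len(v) for k, v in streams.items()},
            }
        else:
            data = _load_inputs(cfg)
            weather_df = data["weather"]
            roster_raw = data["roster"]
            streams = {k: data[k] for k in ("sleep_episodes", "steps", "heart_rate", "body_temp")}

        stage = "weather"
        exposures = weather.summarize_days(weather_df, cfg.thresholds)
        exceed = weather.exceedance_summary(exposures, cfg.thresholds)
        exposures.to_csv(outdir / "daily_exposure.csv", index=False)
        exceed.to_csv(outdir / "exceedance.csv", index=False)
        manifest["stages"]["weather"] = {"days": len(exposures)}

        stage = "qc"
        roster = qc.prepare_roster(roster_raw)
        qcres = qc.run_qc(
            roster,
            streams["sleep_episodes"],
            streams["steps"],
            streams["heart_rate"],
            streams["body_temp"],
            body_temp_bounds=cfg.body_temp_bounds,
            night_window=cfg.thresholds.night_window,
            zero_steps_nonwear=cfg.zero_steps_nonwear,
        )
        qcres.nights.to_csv(outdir / "qc_sleep_nights.csv", index=False)
        qcres.steps.to_csv(outdir / "qc_steps.csv", index=False)
        qcres.heart_rate.to_csv(outdir / "qc_heart_rate.csv", index=False)
        qcres.body_temp_nights.to_csv(outdir / "qc_body_temp_nights.csv", index=False)
        qcres.rejections.to_csv(outdir / "rejection_log.csv", index=False)
        manifest["stages"]["qc"] = {
            "nights": len(qcres.nights),
            "valid_nights": len(qcres.valid_nights),
            "step_days": len(qcres.steps),
            "hr_readings": len(qcres.heart_rate),
            "body_temp_nights": len(qcres.body_temp_nights),
            "rejections_by_reason": qcres.rejections.groupby(["stream", "reason"])
            .size()
            .to_dict()
            if len(qcres.rejections)
            else {},
        }
        manifest["stages"]["qc"]["rejections_by_reason"] = {
            f"{s}:{r}": int(n)
            for (s, r), n in manifest["stages"]["qc"]["rejections_by_reason"].items()
        }

        stage = "completeness"
        comp = completeness.completeness_table(roster, qcres, cfg.cadence)
        comparisons = completeness.comparison_battery(comp, roster)
        comp.to_csv(outdir / "completeness.csv", index=False)
        comparisons.to_csv(outdir / "comparisons.csv", index=False)
        manifest["stages"]["completeness"] = {
            "records": len(comp),
            "comparisons": len(comparisons),
        }

        stage = "models"
        suite = association.run_model_suite(
            qcres, exposures, roster, comp, min_completeness=cfg.min_completeness
        )
        models = association.models_frame(suite)
        models.to_csv(outdir / "models.csv", index=False)
        manifest["stages"]["models"] = {
            "fitted": sum(not isinstance(v, str) for v in suite.values()),
            "failed": sum(isinstance(v, str) for v in suite.values()),
        }
    except Exception:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def recovery_fits(
    seed: int,
    n_participants: int = 83,
    study_days: int = 204,
    effects: synthetic.EffectSizes | None = None,
    thresholds: weather.ThresholdConfig | None = None,
    which: tuple = ("sleep_temp", "log_steps_wbgt", "bodytemp_gender"),
) -> dict:
    """Generate one synthetic cohort and refit the three adjusted headline models.

    Returns {"sleep_temp": fit, "log_steps_wbgt": fit, "bodytemp_gender": fit}
    — the adjusted sleep-vs-nightly-minimum-temperature model, the adjusted
    log-step-count-vs-daily-max-WBGT model, and the adjusted body-shell-
    temperature model (whose gender term is the quantity of interest).
    Used for parameter-recovery checks: each planted effect should be
    recovered within its fitted standard error band.
    """
    thresholds = thresholds or weather.ThresholdConfig()
    synth_cfg = synthetic.SynthConfig(
        seed=seed, n_participants=n_participants, study_days=study_days,
        **({"effects": effects} if effects is not None else {}),
    )
    dataset = synthetic.generate_dataset(synth_cfg, thresholds)
    roster = qc.prepare_roster(dataset["roster"])
    qcres = qc.run_qc(
        roster, dataset["sleep_episodes"], dataset["steps"],
        dataset["heart_rate"], dataset["body_temp"],
        night_window=thresholds.night_window,
    )
    comp = completeness.completeness_table(roster, qcres)
    expo = dataset["exposures"]

    def fit(outcome, exposure):
        table = association.build_daily_table(qcres, expo, roster, comp, outcome, exposure)
        return association.fit_ols(table, adjusted=True, outcome=outcome, exposure=exposure)

    specs = {
        "sleep_temp": ("sleep_minutes", "temp"),
        "log_steps_wbgt": ("log_steps", "wbgt"),
        "bodytemp_gender": ("body_temp", "temp"),
    }
    return {name: fit(*specs[name]) for name in which}


# ---------------------------------------------------------------------------
# report rendering

def render_reports(artifact_dir, outdir=None) -> dict:
    """Render exposure and model tables (markdown) and overview plots.

    Requires a completed ``run_pipeline`` artifact directory; outputs an
    exceedance table in "n (pct)" cell style, a model-suite table, a daily
    heat-indicator plot and a step-count seasonality plot.
    """
    artifact_dir = Path(artifact_dir)
    outdir = Path(outdir) if outdir else artifact_dir
    outdir.mkdir(parents=True, exist_ok=True)
    needed = ["exceedance.csv", "models.csv", "daily_exposure.csv"]
    for name in needed:
        if not (artifact_dir / name).exists():
            raise FileNotFoundError(f"missing pipeline artifact {artifact_dir / name}")

    exceed = pd.read_csv(artifact_dir / "exceedance.csv")
    lines = ["| Reference | Days with exceedance, n (%) |", "| --- | --- |"]
    for _, r in exceed.iterrows():
        pct = r["pct_days"]
        pct_s = "0" if r["n_days"] == 0 else f"{pct:g}"
        lines.append(f"| {r['reference']} | {int(r['n_days'])} ({pct_s}) |")
    (outdir / "exceedance_table.md").write_text("\n".join(lines) + "\n")

    models = pd.read_csv(artifact_dir / "models.csv")
    lines = [
        "| Health parameter | Exposure | Model | Term | Estimate (SE) | P value | n | adj. R2 |",
        "| --- | --- | --- | --- | --- | --- | --- | --- |",
    ]
    if models.empty or (models["term"] == "<error>").all():
        lines.append("| (no models fitted) | | | | | | | |")
    else:
        for _, r in models[models["term"] != "<error>"].iterrows():
            est = round_half_up(r["estimate"], 2)
            se = round_half_up(r["se"], 2)
            p = r["p"]
            p_s = "<.001" if p < 0.001 else f"{round_half_up(p, 3):g}"
            lines.append(
                f"| {r['health_parameter']} | {r['exposure']} | {r['model']} | {r['term']} "
                f"| {est:g} ({se:g}) | {p_s} | {int(r['n'])} | {round_half_up(r['adj_r2'], 3):g} |"
            )
    (outdir / "models_table.md").write_text("\n".join(lines) + "\n")

    _plot_daily_heat(pd.read_csv(artifact_dir / "daily_exposure.csv", parse_dates=["date"]), outdir)
    steps_path = artifact_dir / "qc_steps.csv"
    if steps_path.exists():
        _plot_daily_steps(pd.read_csv(steps_path, parse_dates=["date"]), outdir)
    return {"outdir": str(outdir)}


def _plot_daily_heat(expo: pd.DataFrame, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    ax.plot(expo["date"], expo["wbgt_max_c"], label="daily max WBGT", lw=0.8)
    ax.plot(expo["date"], expo["heat_index_max_c"], label="daily max heat index", lw=0.8)
    ax.fill_between(
        expo["date"], expo["temp_min_night_c"], expo["temp_max_c"], alpha=0.2,
        label="air temp night-min to day-max",
    )
    ax.set_ylabel("°C")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "fig_daily_heat.png", dpi=120)
    plt.close(fig)


def _plot_daily_steps(steps: pd.DataFrame, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    daily = steps.groupby("date")["steps"].mean()
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(daily.index, daily.to_numpy(), ".", ms=3)
    if len(daily) > 10:
        smooth = daily.rolling(7, center=True, min_periods=3).mean()
        ax.plot(smooth.index, smooth.to_numpy(), lw=1.5)
    ax.set_ylabel("mean daily steps")
    fig.tight_layout()
    fig.savefig(outdir / "fig_daily_steps.png", dpi=120)
    plt.close(fig)


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "heatwear": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
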