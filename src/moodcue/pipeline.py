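"""End-to-end study analysis and the reproducible pipeline runner.

:func:`analyze_study` mirrors the study's inferential sequence on a cleaned
cohort: weekly compliance ANOVA, affect-instability and affect-mean t-tests,
accuracy ANOVA, novel-RT practice ANOVA, normalized across-day slope ANOVA,
within-day slope t-test, novel-RT instability t-test, and the
mood-cognition correlations.  :func:`run_pipeline` wires simulation,
cleaning, metrics and statistics into a fully seeded run that writes tidy
CSV tables, a markdown report and a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import GroupParams, SimulatedDataset, simulate_cohort
from .curves import (across_day_slopes, novel_rt_instability,
                     weekly_epoch_means, within_day_slopes)
from .design import StudyDesign, week_of_day
from .errors import ConfigurationError
from .mood import compliance_per_week, group_instability_summary, pair_with_task_days
from .preprocess import CleanResult, clean_pipeline
from .stats import gated_correlation, mixed_anova, two_sample_t

RESULT_COLUMNS = ["analysis", "effect", "method", "statistic", "df1", "df2",
                  "p", "effect_size_name", "effect_size", "n"]


def _anova_rows(analysis: str, res) -> list[dict]:
    rows = []
    for eff in res.effects():
        rows.append({"analysis": analysis, "effect": eff.name,
                     "method": "mixed_anova", "statistic": eff.F,
                     "df1": eff.df1_gg if eff.gg_applied else eff.df1,
                     "df2": eff.df2_gg if eff.gg_applied else eff.df2,
                     "p": eff.p, "effect_size_name": "partial_eta_sq",
                     "effect_size": eff.partial_eta_sq, "n": res.n_subjects})
    return rows


def _ttest_row(analysis: str, res) -> dict:
    return {"analysis": analysis, "effect": "group", "method": "t_test",
            "statistic": res.t, "df1": res.df, "df2": np.nan, "p": res.p,
            "effect_size_name": "cohens_d", "effect_size": res.cohens_d,
            "n": res.n1 + res.n2}


def _corr_row(analysis: str, res) -> dict:
    return {"analysis": analysis, "effect": "association", "method": res.method,
            "statistic": res.coefficient, "df1": np.nan, "df2": np.nan,
            "p": res.p, "effect_size_name": res.method, "effect_size":
            res.coefficient, "n": res.n}


@dataclass
class AnalysisResults:
    """Assembled study analysis: tidy results plus intermediate tables."""

    results: pd.DataFrame
    clean: CleanResult
    instability: pd.DataFrame
    slopes_across: pd.DataFrame
    slopes_within: pd.DataFrame
    rt_instability: pd.DataFrame
    compliance: pd.DataFrame


def _group_map(trials: pd.DataFrame) -> pd.Series:
    return trials.drop_duplicates("participant_id").set_index("participant_id")["group"]


def analyze_study(dataset: SimulatedDataset | tuple, *, min_weeks: int = 3,
                  two_sided_trim: bool = False, correction: str = "auto",
                  welch: bool = False) -> AnalysisResults:
    """Run the full inferential sequence on a (simulated or imported) cohort."""
    if isinstance(dataset, SimulatedDataset):
        trials, mood = dataset.trials, dataset.mood
    else:
        trials, mood = dataset
    clean = clean_pipeline(trials, mood, min_weeks=min_weeks,
                           two_sided_trim=two_sided_trim)
    groups = _group_map(clean.accuracy_trials)
    rows: list[dict] = []

    # 1. weekly compliance (paired mood+task days), group x week
    paired = pair_with_task_days(clean.mood, clean.accuracy_trials)
    compliance = compliance_per_week(paired)
    compliance["group"] = compliance["participant_id"].map(groups)
    rows += _anova_rows("compliance", mixed_anova(
        compliance, "n_days", "week", "group", "participant_id",
        correction=correction))

    # 2. affect instability and means
    instability = group_instability_summary(paired)
    instability["group"] = instability["participant_id"].map(groups)
    for col in ("trmssd_neg", "trmssd_pos", "mean_neg", "mean_pos"):
        sub = instability.dropna(subset=[col])
        rows.append(_ttest_row(f"mood_{col}", two_sample_t(
            sub[col], sub["group"], welch=welch)))

    # 3. accuracy, group x condition
    acc = (clean.accuracy_trials.groupby(["participant_id", "condition"],
                                         observed=True)["correct"]
           .mean().mul(100).rename("accuracy_pct").reset_index())
    acc["group"] = acc["participant_id"].map(groups)
    rows += _anova_rows("accuracy", mixed_anova(
        acc, "accuracy_pct", "condition", "group", "participant_id",
        correction=correction))

    # 4. novel-trial RT practice effect, group x week (complete cases only)
    weekly = weekly_epoch_means(clean.rt_trials)
    novel_weekly = weekly[weekly["condition"] == "novel"].copy()
    wide = novel_weekly.pivot_table(index="participant_id", columns="week",
                                    values="mean_rt").dropna()
    long = wide.reset_index().melt(id_vars="participant_id",
                                   var_name="week", value_name="mean_rt")
    long["group"] = long["participant_id"].map(groups)
    rows += _anova_rows("novel_rt", mixed_anova(
        long, "mean_rt", "week", "group", "participant_id",
        correction=correction))

    # 5. normalized across-day learning slopes, group x condition
    slopes_across = across_day_slopes(weekly)
    slopes_across["group"] = slopes_across["participant_id"].map(groups)
    slope_long = slopes_across.melt(
        id_vars=["participant_id", "group"],
        value_vars=["normalized_daily", "normalized_alternate"],
        var_name="condition", value_name="slope").dropna(subset=["slope"])
    complete = (slope_long.groupby("participant_id").size() == 2)
    slope_long = slope_long[slope_long["participant_id"]
                            .map(complete).fillna(False)]
    rows += _anova_rows("across_day_slopes", mixed_anova(
        slope_long, "slope", "condition", "group", "participant_id",
        correction=correction))

    # 6. within-day normalized slope, group t-test
    slopes_within = within_day_slopes(clean.rt_trials)
    slopes_within["group"] = slopes_within["participant_id"].map(groups)
    sub = slopes_within.dropna(subset=["normalized_within"])
    rows.append(_ttest_row("within_day_slope", two_sample_t(
        sub["normalized_within"], sub["group"], welch=welch)))

    # 7. instability of daily novel-RT means, group t-test (outliers excluded)
    rt_inst = novel_rt_instability(clean.rt_trials)
    rt_inst["group"] = rt_inst["participant_id"].map(groups)
    keep = rt_inst.dropna(subset=["rt_trmssd"]).query("~is_extreme_outlier")
    rows.append(_ttest_row("novel_rt_instability", two_sample_t(
        keep["rt_trmssd"], keep["group"], welch=welch)))

    # 8. mood-cognition correlations
    merged = keep.merge(instability, on="participant_id", how="inner")
    for col in ("trmssd_neg", "trmssd_pos"):
        pairs = merged.dropna(subset=["rt_trmssd", col])
        rows.append(_corr_row(f"rt_instability_vs_{col}", gated_correlation(
            pairs["rt_trmssd"], pairs[col])))

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return AnalysisResults(results, clean, instability, slopes_across,
                           slopes_within, rt_inst, compliance)


# ---------------------------------------------------------------------------
# Configuration and the pipeline runner
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Default run configuration (the study's protocol and calibration)."""
    return {
        "design": {},                # StudyDesign field overrides
        "n_per_group": 37,
        "calibrate_mood": True,
        "groups": {"high": {}, "low": {}},   # GroupParams field overrides
        "analysis": {"min_weeks": 3, "two_sided_trim": False,
                     "correction": "auto", "welch": False},
    }


def load_config(path) -> dict:
    """Load and validate a YAML run configuration (merged over defaults)."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for key, value in user.items():
        if key not in cfg:
            raise ConfigurationError(
                f"unknown config key {key!r}; known: {sorted(cfg)}")
        if isinstance(cfg[key], dict):
            if not isinstance(value, dict):
                raise ConfigurationError(f"config key {key!r} must be a mapping")
            cfg[key] = {**cfg[key], **value}
        else:
            cfg[key] = value
    return cfg


def _build_params(cfg: dict) -> tuple[StudyDesign, GroupParams, GroupParams]:
    try:
        design = StudyDesign(**cfg.get("design", {}))
    except TypeError as exc:
        raise ConfigurationError(f"invalid design options: {exc}") from exc
    groups = cfg.get("groups", {})
    high = GroupParams.high_mdq()
    low = GroupParams.low_mdq()
    for params, overrides in ((high, groups.get("high", {})),
                              (low, groups.get("low", {}))):
        for key, value in overrides.items():
            if not hasattr(params, key):
                raise ConfigurationError(f"unknown group parameter {key!r}")
            setattr(params, key, value)
    return design, high, low


def _report_markdown(analysis: AnalysisResults, manifest: dict) -> str:
    lines = ["# Simulated-cohort analysis report", "",
             f"Seed: {manifest['seed']}; participants: "
             f"2 x {manifest['n_per_group']}", "",
             "## Cleaning", "```",
             analysis.clean.report.summary(), "```", "",
             "## Results", "", "```",
             analysis.results.to_string(index=False), "```"]
    return "\n".join(lines) + "\n"


def run_pipeline(config: dict | str | Path | None = None, *, seed: int = 1,
                 outdir: str | Path = "moodcue-run") -> dict:
    """Simulate, clean, analyse and report, fully seeded.

    Returns a dict with the output paths and the in-memory
    :class:`AnalysisResults`.
    """
    if config is None:
        cfg = default_config()
    elif isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = {**default_config(), **config}
    design, high, low = _build_params(cfg)
    if cfg.get("calibrate_mood", True):
        high.calibrate_mood(seed=0)
        low.calibrate_mood(seed=0)
    dataset = simulate_cohort(design, high, low,
                              n_per_group=int(cfg["n_per_group"]), seed=seed)
    analysis = analyze_study(dataset, **cfg["analysis"])

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = dataset.write(outdir)
    analysis.results.to_csv(outdir / "results.csv", index=False)
    analysis.instability.to_csv(outdir / "instability.csv", index=False)
    slopes = analysis.slopes_across.merge(
        analysis.slopes_within, on="participant_id", how="outer")
    slopes.to_csv(outdir / "slopes.csv", index=False)
    analysis.clean.report.to_json(outdir / "cleaning_report.json")
    manifest = {"seed": seed, "n_per_group": int(cfg["n_per_group"]),
                "config": cfg,
                "design": dataclasses.asdict(design),
                "params": {"high": dataclasses.asdict(high),
                           "low": dataclasses.asdict(low)}}
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    (outdir / "report.md").write_text(_report_markdown(analysis, manifest))
    paths.update({"results": str(outdir / "results.csv"),
                  "slopes": str(outdir / "slopes.csv"),
                  "instability": str(outdir / "instability.csv"),
                  "cleaning_report": str(outdir / "cleaning_report.json"),
                  "run_manifest": str(outdir / "run_manifest.json"),
                  "report": str(outdir / "report.md")})
    return {"paths": paths, "analysis": analysis, "manifest": manifest}
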