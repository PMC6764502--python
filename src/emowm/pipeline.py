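"""End-to-end orchestration: simulate → score → valence → analyze.

Every stage is a pure function of its inputs plus the seed, so rerunning a
configuration reproduces every numeric output bit for bit.  A manifest
(JSON) records the seed, a hash of the configuration, the package version
and any warnings (dropped trials, empty bins) for reproducibility audits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .scoring import score_participants
from .stats import mixed_ancova, one_sample_t, welch_t
from .synthetic_responses import GenerativeParams, params_from_dict, simulate_cohort
from .trial_data import EXCLUSION_VARIANTS, read_trials, write_trials
from .valence import valence_summary

logger = logging.getLogger(__name__)

DEFAULT_VARIANTS = ("all_trials", "drop_wrong_emotion", "drop_wrong_emotion_and_neutral")


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    seed: int | None = None
    n_young: int = 20
    n_old: int = 20
    params_young: GenerativeParams = field(default_factory=GenerativeParams)
    params_old: GenerativeParams = field(default_factory=GenerativeParams)
    variants: tuple[str, ...] = DEFAULT_VARIANTS
    out_dir: str | Path = "emowm_out"
    ci_level: float = 90.0
    weighting: str = "condition"
    normalizer: str = "paper"
    trials_path: str | None = None  # analyze an existing table instead of simulating

    def __post_init__(self) -> None:
        unknown = set(self.variants) - set(EXCLUSION_VARIANTS)
        if unknown:
            raise ValueError(f"unknown exclusion variant(s): {sorted(unknown)}")
        if self.trials_path is None and self.seed is None:
            raise ValueError("a seed is mandatory for simulation runs")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("params_young", "params_old"):
            if key in raw:
                raw[key] = params_from_dict(raw[key])
        if "variants" in raw:
            raw["variants"] = tuple(raw["variants"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _ancova_or_none(*args, **kwargs):
    try:
        return mixed_ancova(*args, **kwargs)
    except ValueError as err:
        logger.warning("ANCOVA skipped: %s", err)
        return None


def analyze_scores(scores: pd.DataFrame, vsummary: pd.DataFrame, *,
                   ci_level: float = 90.0) -> dict[str, pd.DataFrame]:
    """Group-level models for one task × exclusion variant.

    Runs the ANCOVAs (error and per-emotion bias with within-subject factor
    Emotion Type; overall bias between-subjects only; valence proportion
    correct with Emotion Type × Intensity) with Age group as the
    between-subjects factor, trait anxiety as continuous covariate and
    Gender as a covariate of no interest, plus the Welch and one-sample
    t-test contrasts.
    """
    between = ["group"]
    if scores["gender"].nunique() >= 2:
        between.append("gender")
    covariates = ["trait_anxiety"]

    out: dict[str, pd.DataFrame] = {}
    long_err = scores.melt(
        id_vars=["participant_id", "group", "gender", "trait_anxiety"],
        value_vars=["error_fear", "error_happy"], var_name="emotion", value_name="error")
    long_err["emotion"] = long_err["emotion"].str.removeprefix("error_")
    tab = _ancova_or_none(long_err, "error", "participant_id", within=["emotion"],
                          between=between, covariates=covariates, ci_level=ci_level)
    if tab is not None:
        out["ancova_error"] = tab

    tab = _ancova_or_none(scores, "bias_overall", "participant_id",
                          between=between, covariates=covariates, ci_level=ci_level)
    if tab is not None:
        out["ancova_bias_overall"] = tab

    long_bias = scores.melt(
        id_vars=["participant_id", "group", "gender", "trait_anxiety"],
        value_vars=["bias_fear", "bias_happy"], var_name="emotion", value_name="bias")
    long_bias["emotion"] = long_bias["emotion"].str.removeprefix("bias_")
    tab = _ancova_or_none(long_bias, "bias", "participant_id", within=["emotion"],
                          between=between, covariates=covariates, ci_level=ci_level)
    if tab is not None:
        out["ancova_bias_by_emotion"] = tab

    if vsummary is not None and len(vsummary):
        tab = _ancova_or_none(vsummary, "prop_correct", "participant_id",
                              within=["emotion", "bin"], between=between,
                              covariates=covariates, ci_level=ci_level)
        if tab is not None:
            out["ancova_valence"] = tab

    # group contrasts and slope tests
    rows = []
    young = scores[scores["group"] == "young"]
    old = scores[scores["group"] == "old"]
    if len(young) >= 2 and len(old) >= 2:
        for dv in ("mean_error", "error_fear", "error_happy",
                   "bias_overall", "bias_fear", "bias_happy"):
            r = welch_t(young[dv], old[dv])
            rows.append({"test": f"welch_young_vs_old_{dv}", "statistic": r.statistic,
                         "df": r.df, "p": r.p, "effect_size": r.effect_size,
                         "effect_name": r.effect_name, "ci_low": r.effect_ci[0],
                         "ci_high": r.effect_ci[1], "ci_level": r.ci_level})
    out["ttests"] = pd.DataFrame(rows)
    return out


def analyze_slopes(slopes: pd.DataFrame) -> pd.DataFrame:
    """One-sample t tests of valence slopes (and slope differences) vs 0."""
    rows = []
    per_part = slopes.pivot(index="participant_id", columns="emotion", values="slope")
    diffs = slopes.drop_duplicates("participant_id").set_index("participant_id")["slope_diff"]
    candidates = {"slope_all": per_part.mean(axis=1), "slope_fear": per_part["fear"],
                  "slope_happy": per_part["happy"], "slope_diff": diffs}
    for name, vals in candidates.items():
        vals = vals.dropna()
        if len(vals) >= 2 and vals.std() > 0:
            r = one_sample_t(vals)
            rows.append({"test": f"one_sample_{name}_vs_0", "mean": float(vals.mean()),
                         "statistic": r.statistic, "df": r.df, "p": r.p,
                         "effect_size": r.effect_size, "effect_name": r.effect_name,
                         "ci_low": r.effect_ci[0], "ci_high": r.effect_ci[1],
                         "ci_level": r.ci_level})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact set under ``config.out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    stage = "simulate"
    try:
        if config.trials_path is not None:
            trials = read_trials(config.trials_path)
        else:
            trials = simulate_cohort(config.n_young, config.n_old, config.params_young,
                                     config.params_old, config.seed)
        trials_csv = out_dir / "trials.csv"
        write_trials(trials, trials_csv)

        stage = "valence"
        files = {"trials": str(trials_csv)}
        bins, vsum = valence_summary(trials[trials["task"] == "wm"])
        bins.to_csv(out_dir / "valence_bins.csv", index=False)
        vsum.to_csv(out_dir / "valence_summary.csv", index=False)
        files["valence_bins"] = str(out_dir / "valence_bins.csv")
        files["valence_summary"] = str(out_dir / "valence_summary.csv")
        slope_tests = analyze_slopes(vsum[vsum["task"] == "wm"])
        slope_tests.to_csv(out_dir / "slope_tests.csv", index=False)
        files["slope_tests"] = str(out_dir / "slope_tests.csv")

        for variant in config.variants:
            for task in sorted(trials["task"].unique()):
                stage = f"score[{task},{variant}]"
                sub = trials[trials["task"] == task]
                scores = score_participants(sub, variant, weighting=config.weighting,
                                            normalizer=config.normalizer)
                name = f"scores_{task}_{variant}.csv"
                scores.to_csv(out_dir / name, index=False)
                files[name] = str(out_dir / name)

                stage = f"analyze[{task},{variant}]"
                vsum_task = vsum[vsum["task"] == task].merge(
                    bins[bins["task"] == task][
                        ["participant_id", "emotion", "bin", "prop_correct"]],
                    on=["participant_id", "emotion"]) if task == "wm" else None
                results = analyze_scores(scores, vsum_task, ci_level=config.ci_level)
                for key, tab in results.items():
                    fname = f"{key}_{task}_{variant}.csv"
                    tab.to_csv(out_dir / fname, index=False)
                    files[fname] = str(out_dir / fname)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "version": __version__,
        "n_trials": int(len(trials)),
        "n_participants": int(trials["participant_id"].nunique()),
        "warnings": warnings,
        "files": sorted(files),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
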