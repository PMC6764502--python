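"""Derived per-participant measures: error, bias, feedback, binned curve.

All measures operate on the signed intensity scale (fear negative, happy
positive).  The trial-level primitives are:

* error  = |signed_target - signed_response|   (absolute deviation)
* bias   =  signed_response - signed_target    (positive = toward happy)

so a 20%-fearful target reported as 15% happy has error |−20 − 15| = 35 and
bias +35.  The largest possible error over the full scale is 200 (a 100%
target reported as 100% of the opposite emotion); for a target of magnitude
m it is m + 100.

The overall bias statistic is the mean of the psychometric curve: the mean
signed response, averaged by default over the distinct target intensity
conditions (−100..+100) rather than over raw trials — on the balanced
design the two coincide, but after trial exclusions they diverge and the
condition-mean average keeps conditions equally weighted.  Per-emotion bias
flips fearful-trial responses to positive, excludes neutral targets,
averages over the 19 nonzero intensity conditions and subtracts a
normalizer of 50; since the design grid's mean intensity is 1000/19 ≈ 52.63
an unbiased responder scores ≈ +2.63 under this convention (the
``exact`` normalizer option subtracts 1000/19 instead, making the unbiased
score exactly 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trial_data import EMOTIONAL_INTENSITY_LEVELS, apply_exclusions, validate_trials

#: Mean of the 19 nonzero ladder intensities {5,...,45,55,...,100}.
DESIGN_GRID_MEAN: float = sum(EMOTIONAL_INTENSITY_LEVELS) / len(EMOTIONAL_INTENSITY_LEVELS)

#: The per-emotion bias normalizer used in the original analysis.
PAPER_NORMALIZER: float = 50.0

#: Eleven psychometric-curve bins: five 20-unit fear bins (the −20 bin
#: covering −20..−1), a 0 bin, and five mirrored happy bins.
CURVE_BINS: list[tuple[str, int, int]] = [
    ("fear_100_81", -100, -81),
    ("fear_80_61", -80, -61),
    ("fear_60_41", -60, -41),
    ("fear_40_21", -40, -21),
    ("fear_20_1", -20, -1),
    ("neutral_0", 0, 0),
    ("happy_1_20", 1, 20),
    ("happy_21_40", 21, 40),
    ("happy_41_60", 41, 60),
    ("happy_61_80", 61, 80),
    ("happy_81_100", 81, 100),
]


def _check_range(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(np.abs(arr) > 100):
        raise ValueError(f"{name} must be in -100..100")
    return arr


def trial_error(signed_target, signed_response):
    """Absolute report error |target − response| on the signed scale."""
    t = _check_range("signed_target", signed_target)
    r = _check_range("signed_response", signed_response)
    out = np.abs(t - r)
    return float(out) if out.ndim == 0 else out


def trial_bias(signed_target, signed_response):
    """Signed bias response − target; positive = reported happier."""
    t = _check_range("signed_target", signed_target)
    r = _check_range("signed_response", signed_response)
    out = r - t
    return float(out) if out.ndim == 0 else out


def _one_participant_task(trials: pd.DataFrame) -> None:
    if trials["participant_id"].nunique() > 1 or trials["task"].nunique() > 1:
        raise ValueError("expected trials from a single participant and task")


def participant_error(trials: pd.DataFrame, variant: str = "all_trials") -> float:
    """Mean absolute error over retained trials."""
    _one_participant_task(trials)
    kept = apply_exclusions(trials, variant)
    if kept.empty:
        raise ValueError("no retained trials; error undefined")
    return float(trial_error(kept["signed_target"], kept["signed_response"]).mean())


def participant_bias_overall(trials: pd.DataFrame, variant: str = "all_trials",
                             *, weighting: str = "condition") -> float:
    """Mean of the psychometric curve (mean signed response).

    ``weighting="condition"`` (default) averages the per-intensity-condition
    mean responses; ``"trial"`` averages raw trials.
    """
    _one_participant_task(trials)
    kept = apply_exclusions(trials, variant)
    if kept.empty:
        raise ValueError("no retained trials; bias undefined")
    if weighting == "trial":
        return float(kept["signed_response"].mean())
    if weighting != "condition":
        raise ValueError("weighting must be 'condition' or 'trial'")
    cond_means = kept.groupby("signed_target")["signed_response"].mean()
    return float(cond_means.mean())


def participant_bias_by_emotion(trials: pd.DataFrame, variant: str = "all_trials",
                                *, weighting: str = "condition",
                                normalizer: str = "paper") -> tuple[float, float]:
    """Per-emotion bias (bias_fear, bias_happy).

    Fearful-trial responses are flipped to positive so both emotions are
    comparable; neutral targets are always excluded; the mean over the 19
    nonzero intensity conditions is normalized by subtracting 50
    (``normalizer="paper"``) or the exact grid mean 1000/19
    (``normalizer="exact"``).
    """
    _one_participant_task(trials)
    if normalizer == "paper":
        norm = PAPER_NORMALIZER
    elif normalizer == "exact":
        norm = DESIGN_GRID_MEAN
    else:
        raise ValueError("normalizer must be 'paper' or 'exact'")
    kept = apply_exclusions(trials, variant)
    kept = kept[kept["signed_target"] != 0]

    out = {}
    for emotion, sign in (("fear", -1), ("happy", 1)):
        sub = kept[np.sign(kept["signed_target"]) == sign]
        if sub.empty:
            raise ValueError(f"no retained {emotion} trials; bias undefined")
        flipped = sub["signed_response"] * sign  # fear responses flipped to positive
        if weighting == "trial":
            mean_resp = float(flipped.mean())
        else:
            mean_resp = float(flipped.groupby(sub["target_intensity"]).mean().mean())
        out[emotion] = mean_resp - norm
    return out["fear"], out["happy"]


def block_feedback(block_trials: pd.DataFrame) -> float:
    """End-of-block feedback: 100 − mean error (may go negative)."""
    if block_trials.empty:
        raise ValueError("empty block")
    return 100.0 - float(
        trial_error(block_trials["signed_target"], block_trials["signed_response"]).mean()
    )


def feedback_by_block(trials: pd.DataFrame) -> pd.Series:
    """Feedback value per block, indexed by block number."""
    _one_participant_task(trials)
    return trials.groupby("block").apply(block_feedback, include_groups=False)


def bin_psychometric_curve(trials: pd.DataFrame) -> pd.DataFrame:
    """Eleven-bin psychometric curve: mean signed response per target bin.

    Returns one row per bin (``bin, lo, hi, n, mean_response``); empty bins
    have n = 0 and a missing mean.
    """
    _one_participant_task(trials)
    rows = []
    t = trials["signed_target"]
    for label, lo, hi in CURVE_BINS:
        sel = trials[(t >= lo) & (t <= hi)]
        rows.append((label, lo, hi, len(sel),
                     float(sel["signed_response"].mean()) if len(sel) else np.nan))
    return pd.DataFrame(rows, columns=["bin", "lo", "hi", "n", "mean_response"])


def score_participants(table: pd.DataFrame, variant: str = "all_trials",
                       *, weighting: str = "condition",
                       normalizer: str = "paper") -> pd.DataFrame:
    """Tidy score table: one row per participant × task.

    Columns include mean error (overall and per emotion ladder), overall
    bias, per-emotion bias, and participant covariates carried through for
    the group-level models.
    """
    if "signed_target" not in table.columns:
        table = validate_trials(table)
    rows = []
    for (pid, task), trials in table.groupby(["participant_id", "task"], sort=False):
        kept = apply_exclusions(trials, variant)
        errs = trial_error(kept["signed_target"], kept["signed_response"])
        sign = np.sign(kept["signed_target"])
        bias_f, bias_h = participant_bias_by_emotion(
            trials, variant, weighting=weighting, normalizer=normalizer)
        first = trials.iloc[0]
        rows.append({
            "participant_id": pid,
            "task": task,
            "variant": variant,
            "group": first["group"],
            "gender": first["gender"],
            "trait_anxiety": first["trait_anxiety"],
            "n_trials": len(kept),
            "mean_error": float(errs.mean()),
            "error_fear": float(errs[sign == -1].mean()),
            "error_happy": float(errs[sign == 1].mean()),
            "bias_overall": participant_bias_overall(trials, variant, weighting=weighting),
            "bias_fear": bias_f,
            "bias_happy": bias_h,
        })
    return pd.DataFrame(rows)
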