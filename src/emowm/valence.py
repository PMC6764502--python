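"""Categorical valence judgments: correct/incorrect emotion type and slopes.

A trial's valence judgment is *correct* when the reported emotion type
matches the target's (signs of signed response and signed target agree),
*incorrect* when it opposes, and a *neutral report* when the response is
exactly 0 (no emotion type reported).  Neutral-target trials are out of
scope, and neutral reports are excluded from both numerator and denominator
of the proportion-correct analysis.

Proportion correct is computed within five equal target-intensity bins
(1-20, 21-40, 41-60, 61-80, 81-100), separately per emotion type.  The
per-participant slope of proportion correct against bin index (1..5) —
units: proportion per bin step — summarizes how strongly miscategorization
concentrates at low, ambiguous intensities; the happy-minus-fear slope
difference contrasts the two emotion types.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trial_data import validate_trials

#: Intensity bins on |signed_target|, indexed 1..5.
INTENSITY_BINS: list[tuple[int, int, int]] = [
    (1, 1, 20), (2, 21, 40), (3, 41, 60), (4, 61, 80), (5, 81, 100)]


def categorize_trial(signed_target: int, signed_response: int) -> str:
    """Classify one emotional-target trial: correct / incorrect / neutral_report."""
    if signed_target == 0:
        raise ValueError("neutral targets have no emotion type to categorize")
    if signed_response == 0:
        return "neutral_report"
    return "correct" if np.sign(signed_target) == np.sign(signed_response) else "incorrect"


def intensity_bin(intensity) -> np.ndarray:
    """Map |signed target| in 1..100 to bin index 1..5."""
    intensity = np.abs(np.asarray(intensity))
    if np.any((intensity < 1) | (intensity > 100)):
        raise ValueError("intensity must be in 1..100")
    return np.minimum((intensity - 1) // 20 + 1, 5).astype(int)


def bin_proportion_correct(trials: pd.DataFrame) -> pd.DataFrame:
    """Per emotion × intensity bin: proportion of correct-emotion reports.

    Expects trials of a single participant × task.  Neutral targets and
    neutral reports are dropped before counting; proportion = correct /
    (correct + incorrect).  Empty bins appear with n = 0 and a missing
    proportion.
    """
    if trials["participant_id"].nunique() > 1 or trials["task"].nunique() > 1:
        raise ValueError("expected trials from a single participant and task")
    emotional = trials[trials["signed_target"] != 0]
    judged = emotional[emotional["signed_response"] != 0].copy()
    judged["bin"] = intensity_bin(judged["signed_target"])
    judged["correct"] = np.sign(judged["signed_target"]) == np.sign(judged["signed_response"])

    rows = []
    for emotion, sign in (("fear", -1), ("happy", 1)):
        sub = judged[np.sign(judged["signed_target"]) == sign]
        for b, lo, hi in INTENSITY_BINS:
            cell = sub[sub["bin"] == b]
            rows.append((emotion, b, lo, hi, len(cell),
                         float(cell["correct"].mean()) if len(cell) else np.nan))
    return pd.DataFrame(rows, columns=["emotion", "bin", "lo", "hi", "n", "prop_correct"])


def proportion_slope(proportions, bins=None) -> float:
    """OLS slope of proportion correct against bin index (1..5).

    Missing (NaN) bins are omitted; at least two populated bins required.
    """
    p = np.asarray(proportions, dtype=float)
    x = np.arange(1, len(p) + 1, dtype=float) if bins is None else np.asarray(bins, float)
    ok = np.isfinite(p)
    if ok.sum() < 2:
        raise ValueError("need at least two populated bins to fit a slope")
    x, p = x[ok], p[ok]
    xc = x - x.mean()
    return float((xc * (p - p.mean())).sum() / (xc ** 2).sum())


def valence_summary(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort-level valence tables.

    Returns ``(bins, summary)``: ``bins`` holds per participant × task ×
    emotion × bin proportions; ``summary`` one row per participant × task ×
    emotion with the overall wrong-emotion proportion and the slope, plus a
    ``slope_diff`` column (happy − fear) repeated on both rows.
    """
    if "signed_target" not in table.columns:
        table = validate_trials(table)
    bin_frames, summary_rows = [], []
    for (pid, task), trials in table.groupby(["participant_id", "task"], sort=False):
        bins = bin_proportion_correct(trials)
        bins.insert(0, "participant_id", pid)
        bins.insert(1, "task", task)
        bin_frames.append(bins)

        slopes = {}
        for emotion in ("fear", "happy"):
            sub = bins[bins["emotion"] == emotion]
            slopes[emotion] = proportion_slope(sub["prop_correct"], sub["bin"])
        diff = slopes["happy"] - slopes["fear"]
        first = trials.iloc[0]
        for emotion in ("fear", "happy"):
            sub = bins[bins["emotion"] == emotion]
            n = sub["n"].sum()
            n_wrong = ((1 - sub["prop_correct"].fillna(0)) * sub["n"]).sum()
            summary_rows.append({
                "participant_id": pid,
                "task": task,
                "group": first["group"],
                "gender": first["gender"],
                "trait_anxiety": first["trait_anxiety"],
                "emotion": emotion,
                "prop_wrong": float(n_wrong / n) if n else np.nan,
                "slope": slopes[emotion],
                "slope_diff": diff,
            })
    return pd.concat(bin_frames, ignore_index=True), pd.DataFrame(summary_rows)
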