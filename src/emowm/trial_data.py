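"""Trial-level data model for the emotional working-memory task.

Responses and targets live on a single signed intensity scale: fearful
expressions are encoded as negative percentages (-1 to -100), happy
expressions as positive percentages (+1 to +100), and a neutral expression
as 0.  A trial table is an ordinary :class:`pandas.DataFrame` with one row
per trial, carrying both the trial fields and the participant-level fields
(group, gender, trait anxiety) so that downstream scoring and statistics
can operate on a single tidy table.

This module owns validation of that table, delimited-text I/O, and the
trial-exclusion filters used throughout the analysis (wrong-emotion
reports, neutral targets, response timeouts).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Admissible target intensities in both tasks: 0-45% and 55-100% in 5%
#: steps; 50% is left out of the morph ladder.
INTENSITY_LEVELS: tuple[int, ...] = tuple(range(0, 50, 5)) + tuple(range(55, 105, 5))

#: Nonzero intensities per emotion ladder (19 levels).
EMOTIONAL_INTENSITY_LEVELS: tuple[int, ...] = tuple(i for i in INTENSITY_LEVELS if i > 0)

#: Maximum allowed response time in seconds; at this point the intensity
#: currently on screen is recorded as the response.
MAX_RESPONSE_TIME: float = 11.0

N_IDENTITIES: int = 10

EMOTIONS = ("fear", "happy", "neutral")
TASKS = ("wm", "matching")
GROUPS = ("young", "old")

EXCLUSION_VARIANTS = (
    "all_trials",
    "drop_wrong_emotion",
    "drop_wrong_emotion_and_neutral",
    "drop_timeouts",
)

REQUIRED_COLUMNS = [
    "participant_id",
    "group",
    "gender",
    "trait_anxiety",
    "task",
    "block",
    "trial_index",
    "target_emotion",
    "target_intensity",
    "identity_id",
    "signed_response",
    "response_time",
    "timed_out",
]

OPTIONAL_COLUMNS = [
    "state_anxiety",
    "bdi",
    "panas_pos",
    "panas_neg",
    "scroll_mapping",
]


class ValidationError(ValueError):
    """A trial table violates the task's structural invariants."""


def signed_target_from(emotion: Iterable[str], intensity: Iterable[int]) -> np.ndarray:
    """Map (target_emotion, target_intensity) to the signed scale.

    fear -> -intensity, happy -> +intensity, neutral -> 0.
    """
    emotion = np.asarray(emotion, dtype=object)
    intensity = np.asarray(intensity, dtype=float)
    sign = np.where(emotion == "fear", -1.0, np.where(emotion == "happy", 1.0, 0.0))
    return (sign * intensity).astype(int)


def _fail(errors: list[str]) -> None:
    raise ValidationError("; ".join(errors))


def validate_trials(df: pd.DataFrame, *, strict: bool = True) -> pd.DataFrame:
    """Validate a trial table and return a canonical copy.

    The returned frame has numeric dtypes coerced, a boolean ``timed_out``
    column, and a ``signed_target`` column recomputed from
    (target_emotion, target_intensity).  If the input already carries a
    ``signed_target`` column it is cross-checked against the recomputed
    values.

    Parameters
    ----------
    strict
        If True (default) any invalid row raises :class:`ValidationError`
        naming the offending rows.  If False, invalid rows are dropped with
        a logged warning and the count is recorded in
        ``df.attrs["n_dropped_invalid"]``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")

    out = df.copy()
    for col in ("block", "trial_index", "target_intensity", "identity_id", "signed_response"):
        out[col] = pd.to_numeric(out[col], errors="raise")
    out["trait_anxiety"] = pd.to_numeric(out["trait_anxiety"], errors="raise")
    out["response_time"] = pd.to_numeric(out["response_time"], errors="raise")
    if out["timed_out"].dtype != bool:
        out["timed_out"] = (
            out["timed_out"].astype(str).str.strip().str.lower().isin(("true", "1", "yes"))
        )

    errors: list[str] = []
    bad = pd.Series(False, index=out.index)

    def check(mask: pd.Series, message: str) -> None:
        nonlocal bad
        if mask.any():
            rows = list(out.index[mask][:5])
            errors.append(f"{message} (rows {rows}{'...' if mask.sum() > 5 else ''})")
            bad |= mask

    check(~out["task"].isin(TASKS), f"task must be one of {TASKS}")
    check(~out["target_emotion"].isin(EMOTIONS), f"target_emotion must be one of {EMOTIONS}")
    check(out["block"] < 1, "block must be >= 1")
    check(out["trial_index"] < 1, "trial_index must be >= 1")
    check(~out["target_intensity"].isin(INTENSITY_LEVELS),
          "target_intensity must be on the 5%-step ladder (50% excluded)")
    check((out["target_emotion"] == "neutral") != (out["target_intensity"] == 0),
          "target_emotion is 'neutral' exactly when target_intensity is 0")
    check(~out["identity_id"].between(1, N_IDENTITIES),
          f"identity_id must be in 1..{N_IDENTITIES}")
    check(~out["signed_response"].between(-100, 100),
          "signed_response must be in -100..100")
    check(out["response_time"] < 0, "response_time must be >= 0")
    check(out["timed_out"] & (out["response_time"] != MAX_RESPONSE_TIME),
          f"timed_out implies response_time == {MAX_RESPONSE_TIME}")

    if "signed_target" in out.columns:
        recomputed = signed_target_from(out["target_emotion"], out["target_intensity"])
        check(pd.Series(out["signed_target"].to_numpy() != recomputed, index=out.index),
              "stored signed_target disagrees with emotion/intensity")

    if errors:
        if strict:
            _fail(errors)
        n_bad = int(bad.sum())
        logger.warning("dropping %d invalid trial row(s): %s", n_bad, "; ".join(errors))
        out = out.loc[~bad].copy()
        out.attrs["n_dropped_invalid"] = n_bad

    out["signed_target"] = signed_target_from(out["target_emotion"], out["target_intensity"])

    dup = out.duplicated(subset=["participant_id", "task", "block", "trial_index"])
    if dup.any():
        raise ValidationError(
            f"duplicate (participant, task, block, trial) rows: {list(out.index[dup][:5])}"
        )
    return out


def read_trials(path, *, delimiter: str = ",", strict: bool = True) -> pd.DataFrame:
    """Read a delimited trial table (header row required) and validate it.

    Column order is free; ``signed_target`` is recomputed from emotion and
    intensity and cross-checked against any stored column.  Row order is
    preserved.
    """
    df = pd.read_csv(path, sep=delimiter)
    return validate_trials(df, strict=strict)


def write_trials(table: pd.DataFrame, path, *, delimiter: str = ",") -> None:
    """Write a trial table as delimited text.

    Only canonical columns (plus any optional covariates present) are
    written; the derived ``signed_target`` column is omitted so the file
    carries a single source of truth.  ``read_trials(write_trials(t))``
    reproduces ``t`` field for field.
    """
    cols = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in table.columns]
    table.loc[:, cols].to_csv(path, sep=delimiter, index=False)


def is_wrong_emotion(table: pd.DataFrame) -> pd.Series:
    """True where the reported emotion type opposes the target's.

    A wrong-emotion trial is one where the signs of the signed target and
    signed response oppose, both nonzero.  A neutral (0) report on an
    emotional target carries no emotion type and is not flagged.
    """
    t = table["signed_target"]
    r = table["signed_response"]
    return (np.sign(t) * np.sign(r) == -1)


def apply_exclusions(table: pd.DataFrame, variant: str = "all_trials") -> pd.DataFrame:
    """Filter a trial table under one of the analysis exclusion variants.

    Variants
    --------
    all_trials
        No filtering (identity).
    drop_wrong_emotion
        Remove trials where the reported emotion type opposes the target.
    drop_wrong_emotion_and_neutral
        Additionally remove neutral-target (0% intensity) trials.
    drop_timeouts
        Remove trials that consumed the full response window.

    The returned copy records per-participant removed-trial counts in
    ``attrs["n_excluded"]``.
    """
    if variant not in EXCLUSION_VARIANTS:
        raise ValueError(f"unknown exclusion variant {variant!r}; choose from {EXCLUSION_VARIANTS}")
    if "signed_target" not in table.columns:
        table = validate_trials(table)

    keep = pd.Series(True, index=table.index)
    if variant in ("drop_wrong_emotion", "drop_wrong_emotion_and_neutral"):
        keep &= ~is_wrong_emotion(table)
    if variant == "drop_wrong_emotion_and_neutral":
        keep &= table["signed_target"] != 0
    if variant == "drop_timeouts":
        keep &= ~table["timed_out"].astype(bool)

    out = table.loc[keep].copy()
    removed = table.loc[~keep]
    counts = removed.groupby("participant_id").size().to_dict() if len(removed) else {}
    out.attrs["exclusion_variant"] = variant
    out.attrs["n_excluded"] = counts
    return out
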