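"""Trial-schedule generation for the WM and perceptual-matching tasks.

The WM task runs 8 blocks of 20 trials (160 total).  Each emotion ladder
(fearful, happy) contributes 20 intensity conditions (0-45% and 55-100% in
5% steps), each presented exactly 4 times, for 80 trials per ladder.  Ten
facial identities are pseudorandomly allocated to trials such that every
identity appears exactly 16 times and in both emotion ladders.  Emotion
types are intermixed within every block.

The matching task runs 2 blocks of 20 trials with each of the 20 per-ladder
conditions presented once, and with identity-to-condition pairings that
differ from the WM schedule for the same participant.

A schedule is a DataFrame with columns ``task, block, trial_index,
condition_emotion, target_emotion, target_intensity, signed_target,
identity_id``.  ``condition_emotion`` records the morph ladder a trial was
drawn from (used for balancing); ``target_emotion`` is what the participant
sees, i.e. ``neutral`` for 0%-intensity trials on either ladder.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trial_data import INTENSITY_LEVELS, N_IDENTITIES, signed_target_from

WM_N_BLOCKS = 8
WM_BLOCK_LEN = 20
WM_REPEATS_PER_CONDITION = 4
MATCHING_N_BLOCKS = 2
MATCHING_BLOCK_LEN = 20

SCHEDULE_COLUMNS = [
    "task",
    "block",
    "trial_index",
    "condition_emotion",
    "target_emotion",
    "target_intensity",
    "signed_target",
    "identity_id",
]

_MAX_REJECTIONS = 1000


def _conditions() -> list[tuple[str, int]]:
    return [(emo, i) for emo in ("fear", "happy") for i in INTENSITY_LEVELS]


def _assemble(task: str, rows: list[tuple[str, int, int]], n_blocks: int,
              block_len: int, rng: np.random.Generator, seed: int) -> pd.DataFrame:
    """Shuffle trial rows, chunk into blocks, and require emotion mixing."""
    for _ in range(_MAX_REJECTIONS):
        order = rng.permutation(len(rows))
        shuffled = [rows[i] for i in order]
        blocks = [shuffled[b * block_len:(b + 1) * block_len] for b in range(n_blocks)]
        if all(len({emo for emo, _, _ in blk if emo != "neutral"}) == 2 for blk in blocks):
            break
    else:  # pragma: no cover - probability ~0
        raise RuntimeError("could not build a schedule with emotion-mixed blocks")

    records = []
    for b, blk in enumerate(blocks, start=1):
        for t, (cond_emo, intensity, identity) in enumerate(blk, start=1):
            records.append((task, b, t, cond_emo,
                            cond_emo if intensity > 0 else "neutral",
                            intensity, identity))
    df = pd.DataFrame(records, columns=[c for c in SCHEDULE_COLUMNS if c != "signed_target"])
    df["signed_target"] = signed_target_from(df["target_emotion"], df["target_intensity"])
    df = df[SCHEDULE_COLUMNS]
    df.attrs["rng_seed"] = seed
    return df


def build_wm_schedule(seed: int) -> pd.DataFrame:
    """Build one participant's WM schedule (deterministic in ``seed``)."""
    rng = np.random.default_rng(seed)
    slots = [cond for cond in _conditions() for _ in range(WM_REPEATS_PER_CONDITION)]
    pool = np.repeat(np.arange(1, N_IDENTITIES + 1),
                     len(slots) // N_IDENTITIES)  # 16 appearances per identity
    for _ in range(_MAX_REJECTIONS):
        identities = rng.permutation(pool)
        by_identity: dict[int, set[str]] = {}
        for (emo, _), ident in zip(slots, identities):
            by_identity.setdefault(int(ident), set()).add(emo)
        if all(covered == {"fear", "happy"} for covered in by_identity.values()):
            break
    else:  # pragma: no cover - probability ~0
        raise RuntimeError("could not allocate identities to both emotion ladders")

    rows = [(emo, intensity, int(ident))
            for (emo, intensity), ident in zip(slots, identities)]
    return _assemble("wm", rows, WM_N_BLOCKS, WM_BLOCK_LEN, rng, seed)


def build_matching_schedule(seed: int, wm_schedule: pd.DataFrame) -> pd.DataFrame:
    """Build the perceptual-matching schedule paired with a WM schedule.

    Each of the 40 (ladder, intensity) conditions appears once.  For every
    condition the assigned identity is drawn from those NOT used for that
    condition in the WM schedule, so the identity-to-condition pairing
    differs between tasks.
    """
    rng = np.random.default_rng(seed)
    used = (wm_schedule.groupby(["condition_emotion", "target_intensity"])["identity_id"]
            .agg(lambda s: set(int(v) for v in s)).to_dict())
    rows = []
    for emo, intensity in _conditions():
        taken = used.get((emo, intensity), set())
        allowed = [i for i in range(1, N_IDENTITIES + 1) if i not in taken]
        if not allowed:
            raise ValueError(
                f"no identity available for condition ({emo}, {intensity}); "
                "degenerate WM schedule")
        rows.append((emo, intensity, int(rng.choice(allowed))))
    return _assemble("matching", rows, MATCHING_N_BLOCKS, MATCHING_BLOCK_LEN, rng, seed)
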