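"""Generative response model for exercising the analysis pipeline.

The study's data are not bundled with the package, so a simple simulator
stands in: it produces the qualitative structure the analyses are built to
detect — noisy continuous intensity reports, a signed bias shift per
emotion type (e.g. a positivity shift for fearful targets in the old
group), and valence flips (reporting the opposite emotion type) whose
probability decays with target intensity, concentrating miscategorization
at ambiguous low-intensity expressions.

Response rule for an emotional target t (signed):

* with probability ``flip_base_rate * exp(-|t| / flip_decay)`` the report
  flips to the opposite emotion type, with magnitude ``|N(15, 10)|``
  clipped to 1..100;
* otherwise the report is ``round(t + bias_shift + N(0, noise_sd))``
  clipped to -100..100 (``bias_shift`` is signed toward happy).

Neutral targets are reported as ``round(N(0, noise_sd))`` clipped.  These
distributional choices are simulator conventions, not estimates from data;
the model exists for pipeline tests and parameter recovery, not for
fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .task_design import build_matching_schedule, build_wm_schedule
from .trial_data import MAX_RESPONSE_TIME, validate_trials

__all__ = ["GenerativeParams", "simulate_response", "simulate_participant", "simulate_cohort"]


def _per_emotion(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {"fear": float(value["fear"]), "happy": float(value["happy"])}
    return {"fear": float(value), "happy": float(value)}


@dataclass
class GenerativeParams:
    """Per-group response-model parameters.

    Scalar values apply to both emotion types; a ``{"fear": x, "happy": y}``
    mapping sets them separately.  Units are intensity percent throughout.
    """

    report_noise_sd: float | Mapping[str, float] = 12.0
    bias_shift: float | Mapping[str, float] = 0.0
    flip_base_rate: float | Mapping[str, float] = 0.3
    flip_decay: float = 30.0
    timeout_rate: float = 0.01
    flip_magnitude_mean: float = 15.0
    flip_magnitude_sd: float = 10.0
    anxiety_mean: float = 38.0
    anxiety_sd: float = 9.0
    prop_female: float = 0.65

    def __post_init__(self) -> None:
        noise = _per_emotion(self.report_noise_sd)
        if any(v < 0 for v in noise.values()):
            raise ValueError("report_noise_sd must be >= 0")
        flips = _per_emotion(self.flip_base_rate)
        if any(not 0 <= v <= 1 for v in flips.values()):
            raise ValueError("flip_base_rate must be in [0, 1]")
        if self.flip_decay <= 0:
            raise ValueError("flip_decay must be > 0 (math.inf gives a flat flip curve)")
        if not 0 <= self.timeout_rate <= 1:
            raise ValueError("timeout_rate must be in [0, 1]")
        if self.anxiety_sd < 0:
            raise ValueError("anxiety_sd must be >= 0")

    def noise_sd(self, emotion: str) -> float:
        return _per_emotion(self.report_noise_sd)[emotion]

    def shift(self, emotion: str) -> float:
        return _per_emotion(self.bias_shift)[emotion]

    def flip_rate_at(self, emotion: str, intensity: float) -> float:
        """Valence-flip probability at a given target intensity."""
        base = _per_emotion(self.flip_base_rate)[emotion]
        if math.isinf(self.flip_decay):
            return base
        return base * math.exp(-abs(intensity) / self.flip_decay)


def simulate_response(signed_target: int, params: GenerativeParams,
                      rng: np.random.Generator) -> int:
    """Draw one signed intensity report (-100..100) for a signed target."""
    if not -100 <= signed_target <= 100:
        raise ValueError("signed_target must be in -100..100")
    if signed_target == 0:
        sd = 0.5 * (params.noise_sd("fear") + params.noise_sd("happy"))
        value = rng.normal(0.0, sd) if sd > 0 else 0.0
        return int(np.clip(round(value), -100, 100))

    emotion = "fear" if signed_target < 0 else "happy"
    if rng.random() < params.flip_rate_at(emotion, signed_target):
        magnitude = abs(rng.normal(params.flip_magnitude_mean, params.flip_magnitude_sd))
        magnitude = int(np.clip(round(magnitude), 1, 100))
        return -int(np.sign(signed_target)) * magnitude

    sd = params.noise_sd(emotion)
    noise = rng.normal(0.0, sd) if sd > 0 else 0.0
    value = signed_target + params.shift(emotion) + noise
    return int(np.clip(round(value), -100, 100))


def _simulate_rt(rng: np.random.Generator) -> float:
    # right-skewed around ~3 s, capped below the 11 s response window
    return float(min(rng.gamma(shape=4.0, scale=0.75), MAX_RESPONSE_TIME - 0.01))


def simulate_participant(participant_id: str, group: str, params: GenerativeParams,
                         seed_seq: np.random.SeedSequence) -> pd.DataFrame:
    """Simulate one participant's WM + matching sessions as a trial table."""
    rng = np.random.default_rng(seed_seq)
    wm_seed, match_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    wm = build_wm_schedule(wm_seed)
    matching = build_matching_schedule(match_seed, wm)
    schedule = pd.concat([wm, matching], ignore_index=True)

    gender = "female" if rng.random() < params.prop_female else "male"
    anxiety = float(rng.normal(params.anxiety_mean, params.anxiety_sd))
    scroll = "happy-right" if rng.random() < 0.5 else "happy-left"

    responses, rts, timeouts = [], [], []
    for target in schedule["signed_target"]:
        responses.append(simulate_response(int(target), params, rng))
        timed_out = rng.random() < params.timeout_rate
        timeouts.append(timed_out)
        rts.append(MAX_RESPONSE_TIME if timed_out else _simulate_rt(rng))

    out = schedule.drop(columns=["condition_emotion"]).copy()
    out.insert(0, "participant_id", participant_id)
    out.insert(1, "group", group)
    out.insert(2, "gender", gender)
    out.insert(3, "trait_anxiety", round(anxiety, 2))
    out["signed_response"] = responses
    out["response_time"] = np.round(rts, 3)
    out["timed_out"] = timeouts
    out["scroll_mapping"] = scroll
    return out


def simulate_cohort(n_young: int, n_old: int, params_young: GenerativeParams,
                    params_old: GenerativeParams, seed: int) -> pd.DataFrame:
    """Simulate a full two-group cohort; fully reproducible from ``seed``.

    Each participant draws from an independent RNG substream keyed by
    position, so enlarging one group does not perturb other participants'
    data.
    """
    if n_young < 1 or n_old < 1:
        raise ValueError("group sizes must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_young + n_old)
    frames = []
    for i in range(n_young):
        frames.append(simulate_participant(f"Y{i + 1:03d}", "young", params_young, children[i]))
    for i in range(n_old):
        frames.append(simulate_participant(f"O{i + 1:03d}", "old", params_old,
                                           children[n_young + i]))
    table = pd.concat(frames, ignore_index=True)
    return validate_trials(table)


def params_from_dict(d: Mapping) -> GenerativeParams:
    """Build :class:`GenerativeParams` from a plain mapping (YAML-friendly)."""
    return replace(GenerativeParams(), **dict(d))
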