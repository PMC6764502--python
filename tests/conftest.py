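import numpy as np
import pandas as pd
import pytest

from emowm.synthetic_responses import GenerativeParams, simulate_cohort
from emowm.trial_data import validate_trials


def make_trials(pairs, participant="P1", task="wm", group="young", **meta):
    """Build a validated one-participant trial table from (target, response) pairs.

    Targets must be admissible signed ladder values (multiples of 5 with
    |t| != 50, or 0).
    """
    rows = []
    for i, (t, r) in enumerate(pairs):
        emotion = "neutral" if t == 0 else ("fear" if t < 0 else "happy")
        rows.append({
            "participant_id": participant, "group": group,
            "gender": meta.get("gender", "female"),
            "trait_anxiety": meta.get("trait_anxiety", 40.0),
            "task": task, "block": i // 20 + 1, "trial_index": i % 20 + 1,
            "target_emotion": emotion, "target_intensity": abs(t),
            "identity_id": i % 10 + 1, "signed_response": r,
            "response_time": meta.get("response_time", 3.0),
            "timed_out": meta.get("timed_out", False),
        })
    return validate_trials(pd.DataFrame(rows))


def noiseless_params(**overrides):
    base = dict(report_noise_sd=0.0, bias_shift=0.0, flip_base_rate=0.0,
                timeout_rate=0.0)
    base.update(overrides)
    return GenerativeParams(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """3 + 3 participants with default generative parameters."""
    return simulate_cohort(3, 3, GenerativeParams(), GenerativeParams(), seed=42)


@pytest.fixture(scope="session")
def perfect_participant():
    """One participant whose responses equal the targets exactly."""
    table = simulate_cohort(1, 1, noiseless_params(), noiseless_params(), seed=5)
    return table[(table["task"] == "wm") & (table["participant_id"] == "Y001")]


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
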