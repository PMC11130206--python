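import numpy as np
import pandas as pd
import pytest

from pongocog import (
    ChoiceGenParams,
    DotProbeGenParams,
    SamplerSettings,
    schedule_dotprobe,
    schedule_preference,
    simulate_choices,
    simulate_dotprobe,
)
from pongocog.synthetic import default_flange_pairs

SUBJECTS = ["Baju", "Indah", "Kawan", "Samboja", "Sandy", "Wattana"]


@pytest.fixture(scope="session")
def flange_pairs():
    return default_flange_pairs(72, seed=11)


@pytest.fixture(scope="session")
def fast_settings():
    """Reduced sampler settings for unit tests (models are cheap but many)."""
    return SamplerSettings(n_chains=2, n_iterations=700, n_warmup=300, seed=99)


@pytest.fixture(scope="session")
def dotprobe_trials(flange_pairs):
    """One clean simulated subject at the study's flange-task size."""
    plan = schedule_dotprobe(flange_pairs, 6, 24, seed=21, subject_id="Kawan")
    params = DotProbeGenParams(
        b_congruent_ms=-25.0, p_anticipatory=0.0, p_slow=0.0
    )
    return simulate_dotprobe(plan, params, seed=22)


@pytest.fixture(scope="session")
def preference_trials():
    """Six simulated subjects at the study's preference-task size."""
    plan = schedule_preference(SUBJECTS, seed=31)
    return simulate_choices(plan, ChoiceGenParams(), seed=32)


@pytest.fixture()
def tiny_dotprobe():
    """Hand-built table exercising both exclusion rules for one subject."""
    rts = [300.0, 320.0, 340.0, 360.0, 2000.0, 150.0]
    return pd.DataFrame(
        {
            "subject_id": "A",
            "session_id": ["s1", "s1", "s1", "s2", "s2", "s2"],
            "trial_index": range(1, 7),
            "task": "flange",
            "congruence": ["congruent", "incongruent"] * 3,
            "probe_side": ["left", "right"] * 3,
            "rt_ms": rts,
            "pair_id": [f"F{i}" for i in range(6)],
            "width_diff": np.linspace(20, 70, 6),
            "is_repetition": False,
        }
    )
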