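import numpy as np
import pandas as pd
import pytest

from feedbacklearn import task

TRIAL_DEFAULTS = {
    "participant_id": "P001",
    "group": "HC",
    "session": 1,
    "agency": "active",
    "phase": "learning",
    "block": 1,
    "pair": "A/B",
    "stim_left": "A",
    "stim_right": "B",
    "side_of_choice": "left",
    "chosen_stimulus": "A",
    "feedback": "none",
    "rt": 500.0,
    "points_delta": 0,
    "catch": False,
}


def make_trials(rows: list[dict]) -> pd.DataFrame:
    """Build a trial table from sparse row dicts, filling task defaults."""
    out = []
    for i, row in enumerate(rows):
        rec = dict(TRIAL_DEFAULTS, trial=i + 1)
        rec.update(row)
        if "stim_left" not in row and "pair" in row:
            a, b = row["pair"].split("/")
            rec["stim_left"], rec["stim_right"] = a, b
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def default_schedule() -> pd.DataFrame:
    return task.build_design(seed=0)


@pytest.fixture(scope="session")
def active_session(default_schedule) -> pd.DataFrame:
    return task.simulate_active_session(default_schedule, task.AgentParams(), seed=42)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    spec = task.CohortSpec(group_sizes={"OCD": 3, "HC": 3, "SAD": 3}, seed=7)
    return task.simulate_cohort(spec)
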