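from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mimicry_risk import Attitude, GeneratorConfig, SurveyDataset


def make_respondents(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "respondent_id",
            "municipality",
            "saw_snake_last_year",
            "seen_where",
            "attitude",
        ],
    )


def make_trials(rows):
    return pd.DataFrame(
        rows, columns=["respondent_id", "picture_id", "true_species", "response"]
    )


def full_trials_for(rid: str, responses: dict | None = None) -> list[tuple]:
    """Nine trials (3 pictures per species) for one respondent."""
    responses = responses or {}
    rows = []
    for sp in ("adder", "smooth", "grass"):
        for j in (1, 2, 3):
            pid = f"{sp}_{j}"
            rows.append((rid, pid, sp, responses.get(pid, sp)))
    return rows


@pytest.fixture
def two_respondent_dataset() -> SurveyDataset:
    resp = make_respondents(
        [
            ("R1", "M1", True, "yard", "kill_selective"),
            ("R2", "M2", False, "none", "no_kill"),
        ]
    )
    trials = make_trials(
        full_trials_for("R1", {"smooth_1": "adder", "grass_2": "unknown"})
        + full_trials_for("R2", {"smooth_2": "adder"})
    )
    return SurveyDataset(respondents=resp, trials=trials)


@pytest.fixture
def zero_delta() -> dict:
    return {a: 0.0 for a in Attitude}


@pytest.fixture
def calibrated_config(zero_delta) -> GeneratorConfig:
    """Study-scale ground truth with no attitude-skill effect."""
    return GeneratorConfig(n_respondents=102, delta_attitude=zero_delta, seed=0)
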