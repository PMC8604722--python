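import warnings

import numpy as np
import pandas as pd
import pytest

from csu_trial.config import TrialConfig, ArmSpec
from csu_trial.synthetic_cohort import generate_cohort


@pytest.fixture(scope="session")
def default_config() -> TrialConfig:
    return TrialConfig()


@pytest.fixture(scope="session")
def small_config() -> TrialConfig:
    """A small but structurally complete trial for fast end-to-end tests."""
    return TrialConfig(
        arms=(
            ArmSpec("placebo", 8, -11.2, 0.0, 0.20),
            ArmSpec("active", 8, -20.7, 0.0, -0.44),
        ),
        dropout_rate=0.10,
        session_missing_rate=0.02,
        assay_noise_sd=0.0,
        countries=(("US", 0.5), ("Germany", 0.5)),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(small_config, seed=11)


def make_diary(records) -> pd.DataFrame:
    """Long diary table from (patient, day, session, itch, hive) tuples."""
    rows = [
        {"patient_id": p, "study_day": d, "session": s, "itch": i, "hive": h,
         "rescue": False, "missing": False}
        for p, d, s, i, h in records
    ]
    return pd.DataFrame(rows)


def full_week(patient="P1", days=range(-6, 1), itch=3, hive=3) -> list[tuple]:
    return [
        (patient, d, s, itch, hive) for d in days for s in ("AM", "PM")
    ]
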