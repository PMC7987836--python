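import numpy as np
import pandas as pd
import pytest

from phonoflux import (AnalysisConfig, KalmanSettings, TrialTable,
                       static_network)


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def kalman():
    return KalmanSettings()


@pytest.fixture(scope="session")
def coupled_2ch():
    """2-channel net with a single planted edge ch0 -> ch1 (coeff 0.5)."""
    return static_network({(0, 1): 0.5}, n_channels=2, order=5,
                          self_coeff=0.3)


def full_design_table(subject="s01", group="sr-familiarization",
                      trials_per_cell=27) -> TrialTable:
    """Deterministic full crossed design for one subject: 270 rows."""
    rows = []
    for context in ("_l", "_r"):
        for step in (1, 2, 3, 4, 5):
            for i in range(trials_per_cell):
                response = "S" if i % 2 == 0 else "SH"
                rows.append((subject, group, context, step, response))
    return TrialTable(pd.DataFrame(
        rows, columns=["subject_id", "group", "context", "step", "response"]))


@pytest.fixture()
def design_table():
    return full_design_table()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
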