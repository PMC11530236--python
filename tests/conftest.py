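import numpy as np
import pandas as pd
import pytest

from ratpheno import GeneratorConfig, simulate_cohort
from ratpheno.data_model import validate_study_tables


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def sim_cohort(default_config):
    """One default simulated cohort (567 cocaine + 49 naive), shared read-only."""
    return simulate_cohort(default_config, seed=20240)


@pytest.fixture()
def three_rat_tables():
    """Minimal hand-written valid study tables (3 cocaine rats, 1 cohort)."""
    rats = pd.DataFrame({
        "rat_id": ["r1", "r2", "r3"],
        "sex": ["F", "M", "F"],
        "cohort": [1, 1, 1],
        "group": ["cocaine", "cocaine", "cocaine"],
        "excluded": [0, 0, 0],
    })
    rows = []
    for rid, base in (("r1", 40), ("r2", 60), ("r3", 80)):
        for day in range(1, 15):
            inf = base + day
            rows.append((rid, "LgA", day, 6.0, inf, inf // 3, inf + 2, 3, 0))
        rows.append((rid, "PR", 2, 6.0, base // 10, base // 20, base // 10 + 1, 2, 0))
        rows.append((rid, "PreShock", 1, 1.0, 12, 12, 13, 1, 0))
        rows.append((rid, "Shock", 1, 1.0, 6, 6, 7, 1, 0))
    sessions = pd.DataFrame(rows, columns=[
        "rat_id", "phase", "day_index", "duration_h", "infusions",
        "hour1_infusions", "active_presses", "inactive_presses", "missing"])
    irritability = pd.DataFrame({
        "rat_id": ["r1", "r1", "r2", "r2", "r3", "r3"],
        "timepoint": ["baseline", "withdrawal"] * 3,
        "aggressive": [3.0, 6.0, 2.0, 4.0, 5.0, 5.0],
        "defensive": [2.0, 3.0, 1.0, 2.0, 2.0, 4.0],
        "total": [5.0, 9.0, 3.0, 6.0, 7.0, 9.0],
    })
    return validate_study_tables(rats, sessions, irritability)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
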