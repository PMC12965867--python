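import numpy as np
import pandas as pd
import pytest

from proteintrial.cohort import apply_eligibility
from proteintrial.fitting import fit_all
from proteintrial.synthetic import compact_config, default_config, generate_cohort


@pytest.fixture(scope="session")
def default_config_small():
    return default_config(n=900)


@pytest.fixture(scope="session")
def default_cohort_small(default_config_small):
    cohort = generate_cohort(default_config_small, seed=7)
    eligible, _ = apply_eligibility(cohort)
    return eligible


@pytest.fixture(scope="session")
def compact_cfg():
    return compact_config(n=2500)


@pytest.fixture(scope="session")
def compact_cohort(compact_cfg):
    cohort = generate_cohort(compact_cfg, seed=42)
    eligible, _ = apply_eligibility(cohort)
    return eligible


@pytest.fixture(scope="session")
def compact_models(compact_cohort):
    return fit_all(compact_cohort)


def make_manual_cohort(rows: dict) -> pd.DataFrame:
    """Tiny hand-built frame following the toy (l, y) column layout."""
    n = len(next(iter(rows.values())))
    base = {
        "id": np.arange(1, n + 1),
        "energy_1": np.full(n, 2000.0),
        "y_0": np.zeros(n),
        "y_1": np.zeros(n),
        "censor": np.array(["none"] * n, dtype=object),
    }
    base.update(rows)
    if "protein_0" not in base:
        base["protein_0"] = base["protein_1"]
    if "l_1" not in base and "l_0" in base:
        base["l_1"] = base["l_0"]
    return pd.DataFrame(base)
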