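import numpy as np
import pandas as pd
import pytest

from panelqc.codebook import default_codebook, packaged_path
from panelqc.synthetic_cohort import PersonaConfig, generate_cohort


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def convenience_config():
    """Mid-size convenience-panel configuration used across detector tests."""
    return PersonaConfig.from_yaml(
        packaged_path("personas_convenience.yaml"), n_respondents=1500, seed=71
    )


@pytest.fixture(scope="session")
def convenience_cohort(convenience_config, codebook):
    return generate_cohort(convenience_config, codebook)


@pytest.fixture(scope="session")
def large_convenience_cohort(codebook):
    """Full-size convenience cohort (n = 6750) for rate-recovery checks."""
    cfg = PersonaConfig.from_yaml(
        packaged_path("personas_convenience.yaml"), n_respondents=6750, seed=202
    )
    return cfg, generate_cohort(cfg, codebook)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_responses(rows, items=None):
    """Small response frame from a list of per-respondent dicts/lists."""
    df = pd.DataFrame(rows, dtype=float)
    if items is not None:
        df.columns = items
    df.index = pd.Index([f"R{i:03d}" for i in range(len(df))], name="respondent_id")
    return df
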