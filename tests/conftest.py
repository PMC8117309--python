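import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mrprev as m

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_classification():
    return m.default_classification()


@pytest.fixture(scope="session")
def default_spec(default_classification):
    return m.build_design_matrix(default_classification, m.ModelConfig())


@pytest.fixture(scope="session")
def small_classification():
    """24-cell toy classification reusing the real factor names."""
    return m.build_classification(
        [
            ("age_group", ["20-29", "30-39", "40-49", "50-59"]),
            ("sex", ["female", "male"]),
            ("education", ["primary or lower", "secondary or higher"]),
        ]
    )


@pytest.fixture(scope="session")
def small_spec(small_classification):
    return m.build_design_matrix(
        small_classification,
        m.ModelConfig(interactions=(("age_group", "sex"),)),
    )


@pytest.fixture()
def survey_records():
    """Deterministic 20-row respondent table covering several cells."""
    rng = np.random.default_rng(42)
    c = m.default_classification()
    rows = []
    for _ in range(20):
        levels = [
            c.levels(f)[rng.integers(len(c.levels(f)))] for f in c.factor_names
        ]
        rows.append(dict(zip(c.factor_names, levels)))
    df = pd.DataFrame(rows)
    df["waist_cm"] = np.round(rng.uniform(60, 120, size=20), 1)
    return df
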