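import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pigmentscore.scores import DosageMatrix, load_score_definitions

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def definitions():
    return load_score_definitions()


@pytest.fixture(scope="session")
def by_name(definitions):
    return {d.name: d for d in definitions}


def make_dosages(values, rsids, counted, individuals=None):
    """Small DosageMatrix from a nested list."""
    values = np.asarray(values, dtype=float)
    if individuals is None:
        individuals = [f"i{k}" for k in range(values.shape[0])]
    frame = pd.DataFrame(values, index=individuals, columns=rsids)
    return DosageMatrix(frame, dict(zip(rsids, counted)))


@pytest.fixture
def make_dosage_matrix():
    return make_dosages
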