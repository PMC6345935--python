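import numpy as np
import pandas as pd
import pytest

from alstrat.cohort import ClinicalTable


def make_table(rows):
    """rows: iterable of (subject_id, feature_name, value, delta_days)."""
    return ClinicalTable(
        pd.DataFrame(rows, columns=["subject_id", "feature_name", "value", "delta_days"])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def frs_table():
    """Two subjects with ALSFRS trajectories spanning both windows."""
    return make_table(
        [
            ("s1", "ALSFRS", "40", 92),
            ("s1", "ALSFRS", "31", 365),
            ("s1", "ALSFRS", "44", 0),  # outside the outcome window
            ("s1", "weight", "70", 100),  # other feature must not matter
            ("s2", "ALSFRS", "38", 100),
            ("s2", "ALSFRS", "38", 300),
        ]
    )
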