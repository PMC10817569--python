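import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ruleboost import CohortTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_cohort(feature_dict, outcome):
    """Build a CohortTable from plain lists; None marks a missing cell."""
    frame = pd.DataFrame(
        {k: [np.nan if v is None else float(v) for v in vals] for k, vals in feature_dict.items()}
    )
    return CohortTable(frame, pd.Series(list(outcome), index=frame.index, name="events"))


@pytest.fixture
def toy_cohort():
    """Ten patients, two events both carrying f1; five f1 carriers overall."""
    return make_cohort(
        {
            "f1": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
            "f2": [0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
        },
        [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
    )


@pytest.fixture
def separable_cohort():
    """Forty rows where one feature predicts the outcome perfectly."""
    rng = np.random.default_rng(42)
    n = 40
    carrier = np.repeat([1, 0], n // 2)
    noise = rng.integers(0, 2, n)
    return make_cohort({"signal": carrier.tolist(), "noise": noise.tolist()}, carrier.tolist())
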