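import numpy as np
import pandas as pd
import pytest

from pbam.correction import ObservedCounts


def records_from_counts(a_case: int, b_case: int, a_control: int, b_control: int) -> pd.DataFrame:
    """Expand 2x2 margins into a subject-level table."""
    outcome = np.concatenate([
        np.ones(a_case + b_case, dtype=np.int8),
        np.zeros(a_control + b_control, dtype=np.int8),
    ])
    exposure = np.concatenate([
        np.ones(a_case, dtype=np.int8), np.zeros(b_case, dtype=np.int8),
        np.ones(a_control, dtype=np.int8), np.zeros(b_control, dtype=np.int8),
    ])
    return pd.DataFrame({"outcome": outcome, "exposure_observed": exposure})


@pytest.fixture(scope="session")
def study_case_counts() -> ObservedCounts:
    """Observed case-group margins of the motivating study (40 exposed / 892 not)."""
    return ObservedCounts(40, 892, "case")


@pytest.fixture(scope="session")
def study_control_counts() -> ObservedCounts:
    """Observed control-group margins (29 exposed / 971 not)."""
    return ObservedCounts(29, 971, "control")


@pytest.fixture(scope="session")
def study_records(study_case_counts, study_control_counts) -> pd.DataFrame:
    return records_from_counts(
        study_case_counts.a_star, study_case_counts.b_star,
        study_control_counts.a_star, study_control_counts.b_star,
    )
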