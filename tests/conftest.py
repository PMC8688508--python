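import numpy as np
import pandas as pd
import pytest

from aitia import CohortSpec, generate_raw_cohort, preprocess_cohort
from aitia.preprocessing import PROCESSED_FEATURES


@pytest.fixture(scope="session")
def study_cohort() -> pd.DataFrame:
    """Raw synthetic cohort at the study conditions (126 records, 29 good)."""
    return generate_raw_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def processed(study_cohort) -> pd.DataFrame:
    matrix, _ = preprocess_cohort(study_cohort)
    return matrix.reset_index(drop=True)


@pytest.fixture(scope="session")
def labels(processed) -> np.ndarray:
    return processed["outcome"].to_numpy()


def make_matrix(values: dict, n: int) -> pd.DataFrame:
    """Processed-schema matrix with given columns, everything else 0."""
    frame = pd.DataFrame(0.0, index=range(n),
                         columns=PROCESSED_FEATURES + ["outcome"])
    for col, vals in values.items():
        frame[col] = vals
    return frame
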