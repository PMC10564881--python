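import numpy as np
import pandas as pd
import pytest

from evoselect import CohortSpec, FeatureTable, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_table(values: np.ndarray, mask: np.ndarray | None = None) -> FeatureTable:
    """Small helper: FeatureTable from a plain array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(values, columns=[f"f{j}" for j in range(values.shape[1])])
    if mask is None:
        mask = df.notna()
    else:
        mask = pd.DataFrame(mask, columns=df.columns)
    return FeatureTable(df, mask)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with four planted linear effects at the Bayes AUC ~0.9 condition."""
    beta = 1.3
    spec = CohortSpec(
        n_subjects=1400,
        n_features=40,
        latent_rank=3,
        informative_map={
            "condition": [
                (0, "linear", beta),
                (5, "linear", beta),
                (11, "linear", beta),
                (20, "linear", beta),
            ]
        },
        case_rate={"condition": 0.3},
        seed=11,
    )
    return generate_cohort(spec)
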