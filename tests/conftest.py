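import numpy as np
import pandas as pd
import pytest

from nodewalk import CohortConfig, generate_cohort


def random_survival_data(seed: int, n: int = 40, p: int = 2, with_ties: bool = True):
    """Small random right-censored dataset with binary + continuous covariates.

    Integer (month-like) times when ``with_ties`` so tied event times occur.
    """
    rng = np.random.default_rng(seed)
    X = np.column_stack(
        [rng.integers(0, 2, n).astype(float)]
        + [rng.normal(0.0, 1.0, n) for _ in range(p - 1)]
    )
    beta = rng.normal(0.0, 0.5, p)
    t = rng.exponential(np.exp(-X @ beta) * 10.0)
    c = rng.exponential(15.0, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    if with_ties:
        time = np.ceil(time)
    if event.sum() < 3:  # keep every dataset informative
        event[:3] = 1
    return time, event, X


@pytest.fixture(scope="session")
def effect_cohort() -> pd.DataFrame:
    """Default-configuration cohort (positive percentage effect), n=4387."""
    return generate_cohort(CohortConfig(seed=20))


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """Cohort with no percentage effect but covariate effects retained."""
    return generate_cohort(CohortConfig(n_patients=4000, beta_pct=0.0, seed=21))
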