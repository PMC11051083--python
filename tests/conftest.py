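import numpy as np
import pandas as pd
import pytest

from tricoat import CohortSpec, fit_scaler, simulate_cohort, tensorize


@pytest.fixture(scope="session")
def small_cohort():
    """Modest cohort with strong planted signal for training smoke tests."""
    spec = CohortSpec(n_per_class=(40, 50, 12), effect_size=2.0, seed=11)
    cohort, labels = simulate_cohort(spec)
    return cohort, labels


@pytest.fixture(scope="session")
def small_arrays(small_cohort):
    cohort, labels = small_cohort
    scaler = fit_scaler(cohort, cohort.subjects)
    return tensorize(scaler.transform(cohort)), labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def split_ids(labels: pd.Series, test_frac: float, seed: int):
    from sklearn.model_selection import train_test_split
    ids = labels.index.to_numpy()
    tr, te = train_test_split(ids, test_size=test_frac, stratify=labels,
                              random_state=seed)
    return tr, te
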