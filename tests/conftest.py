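import numpy as np
import pytest

from toxalert.synthetic import DEFAULT_ALERTS, SyntheticSpec, generate


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-noise balanced dataset: labels are exactly the planted alerts."""
    return generate(SyntheticSpec(n_active=50, n_inactive=50, label_noise=0.0, seed=11))


@pytest.fixture(scope="session")
def thiophosphate_dataset():
    """Zero-noise imbalanced dataset with a single planted pattern."""
    spec = SyntheticSpec(n_active=80, n_inactive=320, label_noise=0.0, seed=5,
                         alert_patterns=[DEFAULT_ALERTS[0]])
    return generate(spec)


@pytest.fixture(scope="session")
def features_and_labels(thiophosphate_dataset):
    from toxalert.featurize import feature_matrix

    ds = thiophosphate_dataset
    fm = feature_matrix(ds.records)
    return fm, np.array(ds.labels(), dtype=int)
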