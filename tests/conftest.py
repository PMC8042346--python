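import numpy as np
import pytest

from neglectmap import metrics, pca, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient six-subtype cohort (no lesions) shared across tests."""
    cfg = synthetic.default_cohort_config(n_patients=60, seed=11)
    cfg.generate_lesions = False
    return synthetic.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return metrics.build_feature_table(small_cohort)


@pytest.fixture(scope="session")
def small_pca(small_features):
    return pca.fit_pca(small_features)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
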