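import numpy as np
import pytest

from gbmrec.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-size cohort under the default DGP, shared across read-only tests."""
    cohort, truth = generate_cohort(CohortConfig(n=2000, seed=7))
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def null_config(n, seed):
    """DGP with no covariate or treatment effects (pure noise survival)."""
    return CohortConfig(n=n, seed=seed, gamma={}, gamma0=0.4, beta={},
                        delta={}, delta0=0.0)
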