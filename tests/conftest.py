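import numpy as np
import pandas as pd
import pytest

from mindpls import ffmq
from mindpls.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def key():
    return ffmq.default_key()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted-effect cohort reused across read-only tests."""
    return generate_cohort(CohortConfig(n_subjects=120, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_standardized_blocks(rng, n=60, p=3, q=4):
    """Independent standardized blocks for contract-level tests."""
    from mindpls.pls import standardize_columns

    x = standardize_columns(rng.standard_normal((n, p)))
    y = standardize_columns(rng.standard_normal((n, q)))
    return x, y


@pytest.fixture()
def complete_sheet(key):
    """A deterministic complete response sheet for 8 subjects."""
    rng = np.random.default_rng(7)
    data = rng.integers(1, 6, size=(8, ffmq.N_ITEMS)).astype(float)
    idx = pd.Index([f"s{i}" for i in range(8)], name="subject")
    return pd.DataFrame(data, index=idx, columns=list(key.items))
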