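import numpy as np
import pytest

from hcca.io import OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, name="m", sample_prefix="s", feature_prefix="f") -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(
        sample_ids=[f"{sample_prefix}{i}" for i in range(values.shape[0])],
        feature_ids=[f"{feature_prefix}{j}" for j in range(values.shape[1])],
        values=values,
        name=name,
    )


@pytest.fixture
def make_m():
    return make_matrix
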