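import numpy as np
import pytest

from netpredict.core_matrix import FilteredMatrix


def make_filtered(vals) -> FilteredMatrix:
    """Wrap a raw matrix as a FilteredMatrix for estimator-level tests."""
    vals = np.asarray(vals)
    return FilteredMatrix(
        values=vals,
        row_links=np.zeros((vals.shape[0], 2), dtype=np.int64),
        n_nodes=0,
        activation_rates=(vals != 0).mean(axis=1),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
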