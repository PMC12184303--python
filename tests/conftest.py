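import numpy as np
import pytest

from luvburst import PhotonTrace


def make_trace(counts, bin_width_s=1e-4):
    counts = np.asarray(counts, dtype=np.int64)
    return PhotonTrace(
        counts=counts,
        bin_width_s=bin_width_s,
        duration_s=counts.size * bin_width_s,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
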