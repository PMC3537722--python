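import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ktheta import Alignment

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_alignment() -> Alignment:
    """Three 8-bp sequences with a handful of differences."""
    return Alignment.from_sequences(
        [("s1", "ACGTACGT"), ("s2", "ACGTACGA"), ("s3", "ACGAACGA")]
    )


@pytest.fixture
def two_block_alignment() -> Alignment:
    """Two blocks of identical sequences differing at 40% of sites.

    Every bootstrap resample preserves the block split, so its support is
    100% by construction.
    """
    block1 = "A" * 6 + "C" * 4
    block2 = "G" * 4 + "A" * 2 + "C" * 4
    assert sum(a != b for a, b in zip(block1, block2)) == 4
    recs = [(f"x{i}", block1) for i in range(3)] + [(f"y{i}", block2) for i in range(3)]
    return Alignment.from_sequences(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
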