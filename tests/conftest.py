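import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from yreflank.datasets import TABLE1_SEQUENCES
from yreflank.io_formats import PromoterRecord, PromoterTable


@pytest.fixture()
def rng():
    return np.random.default_rng(20210813)


@pytest.fixture()
def table1_promoters():
    """The six studied 23-mer duplexes as a promoter table (no bins)."""
    return PromoterTable(
        [PromoterRecord(name, seq) for name, seq in TABLE1_SEQUENCES.items()]
    )


def random_base_frame(rng):
    """A uniformly random valid base-pair reference frame."""
    from scipy.spatial.transform import Rotation

    axes = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
    origin = rng.uniform(-20, 20, size=3)
    from yreflank.helical import BaseFrame
    return BaseFrame(origin, axes)
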