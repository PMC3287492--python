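import numpy as np
import pytest

from hmmc.segio import CopyNumberMatrix, SegmentGrid


def make_matrix(values, chroms=None):
    """Build a CopyNumberMatrix from a 2-D array, one segment per column."""
    values = np.asarray(values, dtype=np.float64)
    n, T = values.shape
    if chroms is None:
        chroms = tuple("1" for _ in range(T))
    starts = np.arange(T, dtype=np.int64) * 100 + 1
    grid = SegmentGrid(chromosomes=tuple(chroms), starts=starts, ends=starts + 99)
    return CopyNumberMatrix(
        sample_ids=[f"S{j + 1}" for j in range(n)], grid=grid, values=values
    )


@pytest.fixture
def flat_matrix():
    """4 samples x 6 segments, everything diploid."""
    return make_matrix(np.full((4, 6), 2.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
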