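import numpy as np
import pytest

from oralmgx import synthetic
from oralmgx.qc import ReadPair, ReadPartition


@pytest.fixture
def small_spec():
    return synthetic.CommunitySpec(
        n_species=2, genome_length=1000, shared_segments=[("sp000", "sp001", 100)], seed=7
    )


@pytest.fixture
def worked_partition():
    """The hand-worked profiling instance: A has 4 unique reads and length
    1000, B has 2 unique reads and length 2000, one multi-read hits both."""
    partition = ReadPartition(
        unique={f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(2)},
        multi={"m0": frozenset({"A", "B"})},
    )
    return partition, {"A": 1000, "B": 2000}


def make_pair(id="r", bases_1="ACGT" * 25, q1=40, bases_2=None, q2=None):
    n = len(bases_1)
    bases_2 = bases_2 if bases_2 is not None else bases_1
    quals_1 = np.full(n, q1, dtype=np.uint8) if np.isscalar(q1) else np.asarray(q1, np.uint8)
    quals_2 = (
        np.full(len(bases_2), q2 if q2 is not None else q1, dtype=np.uint8)
        if q2 is None or np.isscalar(q2)
        else np.asarray(q2, np.uint8)
    )
    return ReadPair(id, bases_1, quals_1, bases_2, quals_2)
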