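import numpy as np
import pytest

from topictree.seqio import LocusData


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_locus():
    return LocusData(
        locus_id="toy",
        documents={
            "a": "ACGTACGTA",
            "b": "ACGTACGGA",
            "c": "TTGTACGTA",
        },
    )


@pytest.fixture
def aligned_locus():
    return LocusData(
        locus_id="aln",
        documents={
            "a": "AC-GTACG",
            "b": "ACCGTACG",
            "c": "AC-GTTCG",
        },
        aligned=True,
    )
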