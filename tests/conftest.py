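import numpy as np
import pytest

from smartchar import simulate
from smartchar.edit_quant import AmpliconRef


@pytest.fixture
def layout():
    return simulate.DEFAULT_LAYOUT


@pytest.fixture
def amplicon():
    """120 nt amplicon, 20 nt protospacer at position 41, editing window 4-8.

    Protospacer position 5 (amplicon 45) is an adenine, the canonical planted
    A->G target used across the edit-quantification tests.
    """
    seq = (
        "TCTGGAGCGATTCGAACCAGCGTTCGGATAACCTGTGCAT"
        "GTCAACTCCAATGACTAGGG"
        "TGGAGCCATTAACGGCTTCACCTGAGACTTGGCAACGTTAGCCATTGCAGGATCATCGAT"
    )
    return AmpliconRef(sequence=seq, window=(4, 8), protospacer_start=41, protospacer_len=20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
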