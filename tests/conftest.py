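import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

sys.path.insert(0, str(Path(__file__).parent))  # for reference_values

from mirdiff import MatureMiRNA, QualityRead, load_nymphal_libraries


@pytest.fixture(scope="session")
def nymphal():
    """The bundled two-library N5/N6 expression table (61 miRNAs)."""
    return load_nymphal_libraries()


@pytest.fixture
def small_catalog():
    """Three mature miRNAs with distinct 17-nt seeds (let-7-like first)."""
    return [
        MatureMiRNA("mir-a-5p", "TGAGGTAGTAGGTTGTATAGT"),
        MatureMiRNA("mir-b-3p", "ACCCGTAGATCCGAACTTGTG"),
        MatureMiRNA("mir-c-5p", "CATACTTCTTTACATTCCA" + "TA"),
    ]


@pytest.fixture
def make_read():
    def _make(seq: str, qual=30, read_id: str = "r1") -> QualityRead:
        if isinstance(qual, int):
            qual = [qual] * len(seq)
        return QualityRead(read_id, seq, list(qual))

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
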