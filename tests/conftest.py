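from __future__ import annotations

import numpy as np
import pytest

from miredit.formats_io import Hairpin, MatureInterval, QualityRead


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def hairpin():
    """An 80-nt hairpin with a 5p mature arm at 10..31 and 3p at 50..71."""
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=80))
    return Hairpin(
        "syn-mir-hp",
        seq,
        (MatureInterval("5p", 10, 31), MatureInterval("3p", 50, 71)),
    )


def make_read(read_id: str, sequence: str, phred: int = 40, count: int = 1) -> QualityRead:
    return QualityRead(read_id, sequence, (phred,) * len(sequence), count=count)


@pytest.fixture
def read_factory():
    return make_read
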