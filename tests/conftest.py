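import numpy as np
import pytest

from captureseq.io import SequenceRead

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def make_read(seq: str, read_id: str = "r0", q: int = 30, run: str = "RUN_1") -> SequenceRead:
    return SequenceRead(read_id, seq, [q] * len(seq), run_label=run)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)
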