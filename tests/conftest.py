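import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from nsit.genome_io import SequenceRecord


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_reference(rng):
    """Six ~5 kb random chromosomes.

    Six (12 score slots) is enough for a one-hot score vector to clear the
    z >= 2.326 outlier test: the maximum attainable z is sqrt(n_slots - 1).
    """
    return [
        SequenceRecord(f"chr{c}", random_dna(rng, 5000)) for c in "ABCDEF"
    ]


@pytest.fixture
def fasta_file(tmp_path):
    def _write(content: str, name: str = "test.fa") -> Path:
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write
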