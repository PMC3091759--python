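import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from beskit.io_formats import SequenceRecord

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def fragment_template(rng: np.random.Generator, template: str,
                      n_frags: int, frag_len: tuple[int, int],
                      min_overlap: int) -> list[SequenceRecord]:
    """Cut a template into overlapping fragments tiling it left to right."""
    frags = []
    pos = 0
    i = 0
    while pos < len(template) and len(frags) < n_frags:
        size = int(rng.integers(frag_len[0], frag_len[1] + 1))
        frag = template[pos:pos + size]
        frags.append(SequenceRecord(id=f"f{i}", sequence=frag))
        i += 1
        step = max(1, len(frag) - min_overlap - int(rng.integers(0, 50)))
        pos += step
    return frags


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_929)
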