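from __future__ import annotations

import numpy as np
import pytest

from reconasm.seqio import Assembly, Contig


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome(rng) -> str:
    """A 12-kbp random genome used by hand-constructed fixtures."""
    return random_dna(rng, 12_000)


def make_assembly(label: str, seqs: dict[str, str], truth: str = "unknown") -> Assembly:
    return Assembly(
        label, [Contig(cid, s, source=label, truth=truth) for cid, s in seqs.items()]
    )
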