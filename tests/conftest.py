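from __future__ import annotations

import random

import pytest

from mirquant.libraries import SequenceLibrary
from mirquant.preprocess import UniqueRead


@pytest.fixture
def mature_library() -> SequenceLibrary:
    return SequenceLibrary(
        "toy_mature",
        "mature_miRNA",
        [
            ("mirA", "TGAGGTAGTAGGTTGTATAGTT"),
            ("mirB", "ACCCGTAGATCCGAACTTGTGA"),
            ("mirC", "CATTGCACTTGTCTCGGTCTGA"),
        ],
    )


@pytest.fixture
def hairpin_library(mature_library) -> SequenceLibrary:
    # each hairpin embeds its mature at offset 5 with 5' and 3' genomic context
    entries = []
    rng = random.Random(11)
    for mid, mseq in mature_library.entries:
        up = "".join(rng.choice("ACGT") for _ in range(5))
        down = "".join(rng.choice("ACGT") for _ in range(20))
        entries.append((mid + "-hp", up + mseq + down))
    return SequenceLibrary("toy_hairpin", "hairpin", entries)


@pytest.fixture
def trna_library() -> SequenceLibrary:
    rng = random.Random(5)
    entries = [
        ("trna1", "".join(rng.choice("ACGT") for _ in range(70)) + "CCA"),
        ("trna2", "".join(rng.choice("ACGT") for _ in range(72)) + "CCA"),
    ]
    return SequenceLibrary("toy_trna", "tRNA_mature", entries)


def unique(seq: str, *counts: int) -> UniqueRead:
    return UniqueRead(seq, tuple(counts) or (1,))


@pytest.fixture
def make_unique():
    return unique
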