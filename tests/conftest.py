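from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kelpcoast import HaplotypeTable, LabeledAlignment

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def make_alignment(
    seqs: list[str], localities: list[str], gene: str = "test"
) -> LabeledAlignment:
    ids = [f"s{i + 1}" for i in range(len(seqs))]
    return LabeledAlignment(gene, ids, seqs, dict(zip(ids, localities)))


def make_haplotype_table(
    hap_seqs: dict[str, str], counts: dict[str, dict[str, int]]
) -> HaplotypeTable:
    """counts: locality -> {haplotype_id: count}"""
    ids = list(hap_seqs)
    df = pd.DataFrame(
        [[counts[loc].get(h, 0) for h in ids] for loc in counts],
        index=list(counts),
        columns=ids,
        dtype=int,
    )
    return HaplotypeTable(ids, dict(hap_seqs), df)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)


@pytest.fixture
def tiny_alignment() -> LabeledAlignment:
    return make_alignment(
        ["AAA", "AAA", "AAT", "AAT", "AAT"],
        ["L1", "L1", "L1", "L2", "L2"],
    )
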