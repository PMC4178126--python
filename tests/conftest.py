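from __future__ import annotations

import numpy as np
import pytest

from demarcate import (AlignParams, Dataset, SequenceRecord,
                       make_synthetic_family)
from demarcate.seqio import NUCLEOTIDE, random_nucleotide_sequence


def nt_record(name: str, residues: str) -> SequenceRecord:
    return SequenceRecord(name, residues, NUCLEOTIDE)


def nt_dataset(*pairs: tuple[str, str]) -> Dataset:
    return Dataset([nt_record(n, r) for n, r in pairs], NUCLEOTIDE)


@pytest.fixture(scope="session")
def nt_params() -> AlignParams:
    return AlignParams()


@pytest.fixture(scope="session")
def small_family() -> Dataset:
    """Five related 300-nt sequences."""
    return make_synthetic_family(n=5, length=300, divergence=0.05,
                                 indel_rate=0.002, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140926)


def random_record(name: str, length: int, rng: np.random.Generator) -> SequenceRecord:
    return nt_record(name, random_nucleotide_sequence(length, rng))
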