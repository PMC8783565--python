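"""Shared fixture builders for the test suite.

Random instances are built from a handful of base haplotypes with small
numbers of substitutions and a heavy-tailed abundance distribution, so that
merges actually occur; lengths are mostly modal with some codon-shifted and
some frame-breaking variants to exercise the length-class logic.
"""

from __future__ import annotations

import numpy as np
import pytest

from codonoise import Dataset, SequenceRecord

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    s = list(seq)
    sites = rng.choice(len(s), size=min(n_mut, len(s)), replace=False)
    for i in sites:
        s[i] = BASES[(BASES.index(s[i]) + rng.integers(1, 4)) % 4]
    return "".join(s)


def make_fixture(
    rng: np.random.Generator,
    n: int,
    modal_length: int = 120,
    n_bases: int | None = None,
    frame_breakers: bool = True,
) -> Dataset:
    """A random instance with clustered sequences and skewed abundances."""
    if n_bases is None:
        n_bases = max(3, n // 15)
    bases = [random_dna(rng, modal_length) for _ in range(n_bases)]
    records = []
    seen: set[str] = set()
    i = 0
    while len(records) < n:
        base = bases[rng.integers(0, n_bases)]
        seq = mutate(rng, base, int(rng.integers(0, 5)))
        # some codon-shifted lengths, occasionally frame-breaking
        roll = rng.random()
        if roll < 0.08:
            seq = seq[:-3]
        elif roll < 0.12:
            seq = seq + mutate(rng, base[:3], 1)
        elif frame_breakers and roll < 0.15:
            seq = seq[:-1]
        if seq in seen:
            continue
        seen.add(seq)
        reads = int(np.round(rng.lognormal(3.0, 1.8))) + 1
        records.append(SequenceRecord(id=f"r{i:04d}", seq=seq, total_reads=reads))
        i += 1
    return Dataset(records=records, source_dialect="fasta")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


@pytest.fixture
def small_dataset(rng) -> Dataset:
    return make_fixture(rng, 60)
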