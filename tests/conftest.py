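"""Shared fixtures: small communities, read builders, mapping helpers."""

from __future__ import annotations

import numpy as np
import pytest

from ssuem import (
    CommunityMember,
    MappingPolicy,
    Read,
    ReadPair,
    random_community,
)


def make_read(bases: str, quals=30, rid: str = "r1") -> Read:
    """A read with uniform (or explicit) qualities."""
    if isinstance(quals, int):
        quals = np.full(len(bases), quals, dtype=np.int16)
    return Read(rid, bases, np.asarray(quals, dtype=np.int16))


def make_pair(b1: str, b2: str, quals=30, rid: str = "p1") -> ReadPair:
    return ReadPair(make_read(b1, quals, f"{rid}/1"), make_read(b2, quals, f"{rid}/2"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_community() -> list[CommunityMember]:
    """Three ~400 bp genes at uneven abundances, ~10% pairwise divergence."""
    return random_community(
        [0.6, 0.3, 0.1], gene_len=400, divergence=0.05, seed=42
    )


@pytest.fixture
def default_policy() -> MappingPolicy:
    return MappingPolicy(insert_median=120.0, insert_sd=10.0)


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def mutate_seq(seq: str, n_mut: int, rng) -> str:
    """Substitute exactly n_mut distinct positions with different bases."""
    codes = list(seq)
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        others = [b for b in "ACGT" if b != codes[p]]
        codes[p] = others[rng.integers(3)]
    return "".join(codes)
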