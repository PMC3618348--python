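import numpy as np
import pytest

from plastomekit.model import AnnotatedGenome
from plastomekit.synth import (
    GeneSpec,
    PlastomeSpec,
    default_inventory,
    generate_plastome,
)

NUCS = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(NUCS))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def small_genome() -> AnnotatedGenome:
    """A 30 kb quadripartite genome with a modest gene complement."""
    spec = PlastomeSpec(
        18_000, 4_000, 4_000, default_inventory(10, 4, 2, seed=2), seed=5
    )
    return generate_plastome(spec, "small")


@pytest.fixture(scope="session")
def full_genome() -> AnnotatedGenome:
    """A full-size (135,282 bp) genome with 114 genes, 20 IR-duplicated."""
    spec = PlastomeSpec(79_972, 12_428, 21_441, default_inventory(seed=0), seed=7)
    return generate_plastome(spec, "full")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def unambiguous_deletion_start(seq: str, approx: int, length: int) -> int:
    """First position >= approx where deleting [s, s+length) cannot be
    slid left or right in an optimal alignment (flanking bases differ)."""
    for s in range(approx, len(seq) - length - 2):
        if seq[s - 1] != seq[s + length - 1] and seq[s] != seq[s + length]:
            return s
    raise AssertionError("no unambiguous deletion site found")
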