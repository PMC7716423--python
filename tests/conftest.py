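import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sebarcode import (
    AssignedRead,
    ConsensusSequence,
    End,
    PlateConfig,
    Rank,
    generate_tags,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tags96() -> list[str]:
    return generate_tags(5, 2, 96, seed=0).tags


@pytest.fixture(scope="session")
def config96(tags96) -> PlateConfig:
    return PlateConfig(tags=tags96)


@pytest.fixture()
def small_config() -> PlateConfig:
    """Four wells with short, distinct primers; handy for hand-built reads."""
    # aperiodic primers: neither primer (nor its reverse complement)
    # nearly matches a shifted copy of itself, so interior-scan tests are
    # not confounded by self-similarity
    return PlateConfig(
        tags=["AACGT", "CCTAG", "GGATC", "TTGCA"],
        fwd_primer="AGGCTTACGA",
        rev_primer="CCATGAGTTA",
    )


def make_assigned(
    seq: str, sample: str = "S1", end: End = End.FIVE_PRIME, rid: str = "r"
) -> AssignedRead:
    return AssignedRead(sample, end, seq, [30] * len(seq), rid)


def consensus_from(
    seq: str,
    end: End = End.FIVE_PRIME,
    depth: int = 20,
    rank: Rank = Rank.PRIMARY,
) -> ConsensusSequence:
    """Consensus test double: one-hot column counts at ``depth`` (zero for
    'N' columns)."""
    counts = np.zeros((4, len(seq)), dtype=np.int64)
    for i, c in enumerate(seq):
        if c != "N":
            counts["ACGT".index(c), i] = depth
    return ConsensusSequence(seq, counts, depth, end, rank)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
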