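"""Sample-tag (index) design.

Generates sets of equal-length nucleotide tags whose pairwise Hamming
distance never falls below a minimum (default: 5-bp tags at distance ≥ 2,
enough to survive the single-mismatch tolerance of demultiplexing without
cross-assignment).  Construction is greedy over candidates in
lexicographic order — for length 5 / distance 2 this recovers the full
256-word single-parity code, comfortably above the 96 tags a plate needs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._alphabet import BASES


@dataclass
class TagSet:
    tags: list[str]
    length: int
    min_distance: int
    shortfall: bool = False


def _plain_hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _max_run(seq: str) -> int:
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def generate_tags(
    length: int,
    min_distance: int,
    n_requested: int,
    seed: int = 0,
    shuffle: bool = False,
    max_homopolymer: int | None = None,
    gc_band: tuple[float, float] | None = None,
) -> TagSet:
    """Greedy minimum-distance tag construction.

    Candidates are all 4^length words in lexicographic order (shuffled by
    ``seed`` when ``shuffle`` is set); a candidate is accepted iff its
    Hamming distance to every accepted tag is ≥ ``min_distance``.  Full
    homopolymers (run of ``length``) are excluded by default
    (``max_homopolymer`` = length − 1); an optional GC-content band can
    additionally constrain candidates.  When the space is exhausted
    before ``n_requested`` tags are found, the maximal set is returned
    with ``shortfall`` set.
    """
    if length < 1 or min_distance < 1 or n_requested < 1:
        raise ValueError("length, min_distance and n_requested must be ≥ 1")
    # the default filter only excludes full homopolymers (AAAAA, ...);
    # for 1-2 bp tags such a filter would gut the space, so it is off
    if max_homopolymer is None:
        max_homopolymer = length - 1 if length >= 3 else length
    candidates = ["".join(p) for p in itertools.product(BASES, repeat=length)]
    if shuffle:
        rng = np.random.default_rng(seed)
        rng.shuffle(candidates)
    accepted: list[str] = []
    for cand in candidates:
        if _max_run(cand) > max_homopolymer:
            continue
        if gc_band is not None:
            gc = (cand.count("G") + cand.count("C")) / length
            if not gc_band[0] <= gc <= gc_band[1]:
                continue
        if all(_plain_hamming(cand, t) >= min_distance for t in accepted):
            accepted.append(cand)
            if len(accepted) == n_requested:
                break
    return TagSet(
        tags=accepted,
        length=length,
        min_distance=min_distance,
        shortfall=len(accepted) < n_requested,
    )


def validate_tagset(
    tags: list[str], min_distance: int = 2
) -> tuple[bool, int]:
    """Exhaustive pairwise distance check.

    Returns (ok, minimum pairwise distance found).  With fewer than two
    tags the constraint is vacuous and the tag length is reported as the
    minimum.  Unequal tag lengths are an error.
    """
    if not tags:
        raise ValueError("empty tag set")
    lengths = {len(t) for t in tags}
    if len(lengths) != 1:
        raise ValueError(f"tags of unequal length: {sorted(lengths)}")
    if len(tags) < 2:
        return True, len(tags[0])
    min_found = min(
        _plain_hamming(a, b) for a, b in itertools.combinations(tags, 2)
    )
    return min_found >= min_distance, min_found
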