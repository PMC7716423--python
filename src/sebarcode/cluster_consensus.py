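"""Per-group dereplication, greedy identity clustering and consensus calling.

Within each (sample, end) group the trimmed reads are dereplicated,
clustered abundance-greedily at 98 % identity, and turned into per-column
majority consensuses.  Only sufficiently abundant clusters survive: the
top cluster needs at least ``min_cluster_size`` reads, and the
second-most-abundant cluster is additionally retained — as a candidate
symbiont / parasite co-amplicon — when its abundance strictly exceeds one
tenth of the top cluster's.

Reads from one end of one amplicon are primer-anchored and of uniform
length, so member-to-centroid comparison is positional (ungapped) when
lengths agree; a semi-global edit-distance alignment (edlib) is the
fallback for length differences.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from ._alphabet import encode
from .demultiplex import AssignedRead, End
from .io_formats import PlateConfig

_BASE_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class UniqueSequence:
    """One dereplicated sequence with its abundance and member reads."""

    sequence: str
    count: int
    members: list[AssignedRead]

    @property
    def member_ids(self) -> list[str]:
        return [m.source_read_id for m in self.members]


@dataclass
class ReadCluster:
    centroid: str
    members: list[AssignedRead]
    uniques: list[UniqueSequence]

    @property
    def abundance(self) -> int:
        return len(self.members)


class Rank(enum.Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"


@dataclass
class ConsensusSequence:
    """Per-column majority consensus of a cluster, in centroid coordinates.

    ``column_counts`` is a (4, n_columns) array of A/C/G/T observation
    counts; ``bases[i]`` is the strictly most frequent base of column i,
    or 'N' when the top two counts tie (or the column is uncovered).
    """

    bases: str
    column_counts: np.ndarray
    depth: int
    end: End
    rank: Rank

    def __post_init__(self) -> None:
        if self.column_counts.shape != (4, len(self.bases)):
            raise ValueError("column_counts shape does not match bases")

    def reverse_complement(self) -> "ConsensusSequence":
        """Consensus in the opposite orientation: bases reverse-
        complemented, count rows swapped A<->T / C<->G and columns
        reversed."""
        from ._alphabet import reverse_complement as rc

        flipped = self.column_counts[[3, 2, 1, 0], :][:, ::-1].copy()
        return ConsensusSequence(
            bases=rc(self.bases),
            column_counts=flipped,
            depth=self.depth,
            end=self.end,
            rank=self.rank,
        )


def dereplicate(reads: Sequence[AssignedRead]) -> list[UniqueSequence]:
    """Group exactly identical sequences; sorted by count descending,
    ties broken lexicographically by sequence."""
    by_seq: dict[str, list[AssignedRead]] = {}
    for read in reads:
        by_seq.setdefault(read.insert_bases, []).append(read)
    uniques = [
        UniqueSequence(seq, len(members), members)
        for seq, members in by_seq.items()
    ]
    uniques.sort(key=lambda u: (-u.count, u.sequence))
    return uniques


def pairwise_identity(a: str, b: str) -> float:
    """Alignment identity between two sequences, in [0, 1].

    Equal lengths: positional (end-gap-free global) identity, matching
    columns over length.  Unequal lengths: semi-global edit distance d of
    the shorter inside the longer (edlib infix mode); identity is
    1 − d / len(shorter), clipped at 0.  Symmetric by construction.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if len(a) == len(b):
        ai, bi = encode(a), encode(b)
        return float((ai == bi).sum()) / len(a)
    short, long_ = (a, b) if len(a) < len(b) else (b, a)
    d = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
    return max(0.0, 1.0 - d / len(short))


def greedy_cluster(
    uniques: Sequence[UniqueSequence], threshold: float
) -> list[ReadCluster]:
    """Abundance-greedy centroid clustering.

    Scans dereplicated sequences in abundance order; each joins the first
    existing centroid (in creation order) with identity ≥ threshold, else
    founds a new cluster with itself as centroid.  Output is sorted by
    abundance descending (tie: centroid lexicographic), which makes the
    procedure fully deterministic.
    """
    clusters: list[ReadCluster] = []
    for unique in uniques:
        for cluster in clusters:
            if pairwise_identity(unique.sequence, cluster.centroid) >= threshold:
                cluster.members.extend(unique.members)
                cluster.uniques.append(unique)
                break
        else:
            clusters.append(
                ReadCluster(unique.sequence, list(unique.members), [unique])
            )
    clusters.sort(key=lambda c: (-c.abundance, c.centroid))
    return clusters


def _place_counts(counts: np.ndarray, centroid: str, seq: str, weight: int) -> None:
    """Add ``weight`` observations of ``seq`` into centroid-coordinate
    ``counts``.  Equal lengths are positional; otherwise the sequence is
    globally aligned to the centroid and bases are projected onto
    centroid columns (insertions relative to the centroid are dropped)."""
    if len(seq) == len(centroid):
        idx = encode(seq)
        valid = idx < 4
        counts[idx[valid], np.flatnonzero(valid)] += weight
        return
    result = edlib.align(seq, centroid, mode="NW", task="path")
    col = 0
    pos = 0
    for length, op in _parse_cigar(result["cigar"]):
        if op in "=X":
            for k in range(length):
                row = _BASE_ROW.get(seq[pos + k])
                if row is not None:
                    counts[row, col + k] += weight
            col += length
            pos += length
        elif op == "D":  # gap in query: centroid columns uncovered
            col += length
        elif op == "I":  # insertion in query: no centroid column
            pos += length


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    out = []
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            out.append((int(num), c))
            num = ""
    return out


def _wildcard_identity(a: str, b: str) -> float:
    """Positional identity with 'N' matching anything (for comparing
    reads against consensus strings, which may carry N at tie columns);
    falls back to alignment identity for unequal lengths."""
    if len(a) != len(b):
        return pairwise_identity(a, b)
    ai, bi = encode(a), encode(b)
    matches = (ai == bi) | (ai == 4) | (bi == 4)
    return float(matches.sum()) / len(a)


def refine_clusters(
    clusters: list[ReadCluster], threshold: float
) -> list[ReadCluster]:
    """One centroid-refinement pass over a greedy clustering.

    Greedy clustering centres each cluster on a single observed read; at
    low depth an error-rich centroid fragments what is really one
    sequence family.  This pass rebuilds each cluster around its
    majority consensus and re-assigns every dereplicated sequence to the
    best-matching consensus (identity ≥ threshold, 'N' wildcard), which
    re-absorbs fragments while leaving well-separated families — e.g. a
    70 %-identity co-amplicon — untouched.  Sequences matching no
    consensus are greedily re-clustered among themselves.  Deterministic.
    """
    if len(clusters) <= 1:
        return clusters
    consensuses = []
    for cluster in clusters:
        counts = np.zeros((4, len(cluster.centroid)), dtype=np.int64)
        for unique in cluster.uniques:
            _place_counts(counts, cluster.centroid, unique.sequence, unique.count)
        consensuses.append(_majority_bases(counts))
    uniques = sorted(
        (u for c in clusters for u in c.uniques),
        key=lambda u: (-u.count, u.sequence),
    )
    buckets: list[list[UniqueSequence]] = [[] for _ in consensuses]
    orphans: list[UniqueSequence] = []
    for unique in uniques:
        best_i, best_id = -1, -1.0
        for i, cons in enumerate(consensuses):
            ident = _wildcard_identity(unique.sequence, cons)
            if ident > best_id:
                best_i, best_id = i, ident
        if best_id >= threshold:
            buckets[best_i].append(unique)
        else:
            orphans.append(unique)
    refined = [
        ReadCluster(
            centroid=consensuses[i],
            members=[m for u in bucket for m in u.members],
            uniques=bucket,
        )
        for i, bucket in enumerate(buckets)
        if bucket
    ]
    refined.extend(greedy_cluster(orphans, threshold))
    refined.sort(key=lambda c: (-c.abundance, c.centroid))
    return refined


def build_consensus(
    cluster: ReadCluster, end: End, rank: Rank = Rank.PRIMARY
) -> ConsensusSequence:
    """Per-column majority consensus over all member reads.

    Column i emits the base whose count strictly exceeds every other
    base's count; exact ties (and uncovered columns) emit 'N'.
    """
    if not cluster.members:
        raise ValueError("cannot build a consensus of an empty cluster")
    n = len(cluster.centroid)
    counts = np.zeros((4, n), dtype=np.int64)
    for unique in cluster.uniques:
        _place_counts(counts, cluster.centroid, unique.sequence, unique.count)
    bases = _majority_bases(counts)
    return ConsensusSequence(bases, counts, cluster.abundance, end, rank)


def _majority_bases(counts: np.ndarray) -> str:
    order = np.sort(counts, axis=0)
    top = order[-1]
    runner = order[-2]
    winner = np.argmax(counts, axis=0)
    chars = np.array(list("ACGT"))[winner]
    chars[(top == runner) | (top == 0)] = "N"
    return "".join(chars)


def select_clusters(
    clusters: Sequence[ReadCluster], config: PlateConfig, end: End
) -> tuple[ConsensusSequence | None, ConsensusSequence | None]:
    """Apply the abundance-retention rules to a sorted cluster list.

    Primary: consensus of the top cluster when its abundance reaches
    ``min_cluster_size``.  Secondary: consensus of the second cluster when
    its abundance both strictly exceeds top/10 and reaches
    ``min_cluster_size``.
    """
    primary = secondary = None
    if clusters and clusters[0].abundance >= config.min_cluster_size:
        primary = build_consensus(clusters[0], end, Rank.PRIMARY)
        if len(clusters) > 1:
            second = clusters[1]
            if (
                second.abundance > clusters[0].abundance * config.secondary_ratio
                and second.abundance >= config.min_cluster_size
            ):
                secondary = build_consensus(second, end, Rank.SECONDARY)
    return primary, secondary


def cluster_group(
    reads: Sequence[AssignedRead], config: PlateConfig, end: End
) -> tuple[ConsensusSequence | None, ConsensusSequence | None, list[ReadCluster]]:
    """Dereplicate → greedy cluster → refine → select for one
    (sample, end) group."""
    clusters = greedy_cluster(dereplicate(reads), config.cluster_identity)
    clusters = refine_clusters(clusters, config.cluster_identity)
    primary, secondary = select_clusters(clusters, config, end)
    return primary, secondary, clusters
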