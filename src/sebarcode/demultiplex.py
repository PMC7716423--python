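"""Demultiplexing of tagged amplicon reads.

Every read is expected to start with a 5-bp sample tag followed by either
the forward primer (a 5′-end read) or the reverse primer (a 3′-end read).
Assignment compares the read prefix against every configured tag and both
primers, tolerating a per-region mismatch budget (default: one mismatch in
the tag, one in the primer).  A read is assigned only when exactly one
(tag, primer) candidate fits; ties are conservatively discarded as
ambiguous.

Two artifact scans run alongside assignment:

* **Chimeras** — PCR products spliced from two templates carry a primer
  sequence at an interior read position.  Any occurrence of either primer
  or its reverse complement starting after the anchored tag region marks
  the read as chimeric, and this verdict overrides assignment.
* **NuMTs** — short nuclear copies of mitochondrial DNA co-amplify and,
  being shorter than one read, place the reverse complement of the
  *opposite* primer downstream on the same read.  When the implied insert
  is shorter than the configured threshold (default 300 bp) the read is
  flagged NUMT rather than chimeric and excluded from clustering.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from ._alphabet import (
    encode,
    hamming,
    primer_match_table,
    reverse_complement,
    scan_mismatches,
)
from .io_formats import PlateConfig, SequenceRead

__all__ = [
    "End", "AssignClass", "AssignedRead", "AssignOutcome", "AssignReport",
    "Demultiplexer", "hamming", "match_tagged_primer", "detect_chimera",
    "detect_numt", "demultiplex_plate",
]


class End(enum.Enum):
    FIVE_PRIME = "for"
    THREE_PRIME = "rev"

    @property
    def opposite(self) -> "End":
        return End.THREE_PRIME if self is End.FIVE_PRIME else End.FIVE_PRIME


class AssignClass(enum.Enum):
    ASSIGNED = "assigned"
    UNASSIGNED = "unassigned"
    CHIMERA = "chimera"
    NUMT = "numt"


@dataclass
class AssignedRead:
    """A read placed in its (sample, end) group with tag and primer
    trimmed; ``insert_bases`` is pure barcode sequence."""

    sample_id: str
    end: End
    insert_bases: str
    insert_quals: list[int]
    source_read_id: str

    def __post_init__(self) -> None:
        if len(self.insert_bases) != len(self.insert_quals):
            raise ValueError("insert bases/quals length mismatch")


@dataclass
class AssignOutcome:
    class_: AssignClass
    detail: str
    assigned: AssignedRead | None = None


@dataclass
class AssignReport:
    n_input: int = 0
    n_assigned: int = 0
    n_unassigned: int = 0
    n_chimera: int = 0
    n_numt: int = 0
    group_counts: dict[tuple[str, End], int] = field(default_factory=dict)

    def check(self) -> None:
        assert self.n_input == (
            self.n_assigned + self.n_unassigned + self.n_chimera + self.n_numt
        )
        assert sum(self.group_counts.values()) == self.n_assigned

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("category\tcount\n")
            handle.write(f"input\t{self.n_input}\n")
            handle.write(f"assigned\t{self.n_assigned}\n")
            handle.write(f"unassigned\t{self.n_unassigned}\n")
            handle.write(f"chimera\t{self.n_chimera}\n")
            handle.write(f"numt\t{self.n_numt}\n")
            for (sample, end), count in sorted(
                self.group_counts.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
            ):
                handle.write(f"group:{sample}_{end.value}\t{count}\n")


class Demultiplexer:
    """Precomputed matcher for one plate configuration.

    Tag comparison and primer scanning are vectorised over encoded reads;
    the interior scan is exhaustive over all start positions for both
    primers and their reverse complements.
    """

    def __init__(self, config: PlateConfig):
        self.config = config
        self.tag_len = config.tag_length
        self.tags = np.stack([encode(t) for t in config.tags])
        self.samples = config.samples
        self.anchored = {
            End.FIVE_PRIME: primer_match_table(config.fwd_primer),
            End.THREE_PRIME: primer_match_table(config.rev_primer),
        }
        # interior-scan variants; the rc of the opposite primer doubles as
        # the NuMT signature on an assigned read
        self.interior = {
            "fwd": primer_match_table(config.fwd_primer),
            "rev": primer_match_table(config.rev_primer),
            "rc_fwd": primer_match_table(reverse_complement(config.fwd_primer)),
            "rc_rev": primer_match_table(reverse_complement(config.rev_primer)),
        }
        self.numt_variant = {End.FIVE_PRIME: "rc_rev", End.THREE_PRIME: "rc_fwd"}

    # -- anchored matching ------------------------------------------------
    def _candidates(self, idx: np.ndarray) -> list[tuple[int, End]]:
        L = self.tag_len
        if idx.size < L:
            return []
        tag_mm = (self.tags != idx[:L]).sum(axis=1)
        ok_tags = np.flatnonzero(tag_mm <= self.config.index_mismatch_budget)
        if ok_tags.size == 0:
            return []
        out: list[tuple[int, End]] = []
        for end, table in self.anchored.items():
            m = table.shape[0]
            if idx.size < L + m:
                continue
            window = idx[L : L + m]
            mm = m - int(table[np.arange(m), window].sum())
            if mm <= self.config.primer_mismatch_budget:
                out.extend((int(t), end) for t in ok_tags)
        return out

    # -- interior scan ----------------------------------------------------
    def _interior_hits(self, idx: np.ndarray) -> list[tuple[str, int]]:
        L = self.tag_len
        hits: list[tuple[str, int]] = []
        for name, table in self.interior.items():
            mm = scan_mismatches(idx, table)
            for pos in np.flatnonzero(mm <= self.config.primer_mismatch_budget):
                if pos > L:
                    hits.append((name, int(pos)))
        return hits

    # -- per-read classification ------------------------------------------
    def classify(self, read: SequenceRead) -> AssignOutcome:
        cfg = self.config
        idx = encode(read.bases)
        candidates = self._candidates(idx)
        hits = self._interior_hits(idx)

        numt_positions: list[int] = []
        if len(candidates) == 1:
            _, end = candidates[0]
            primer_len = self.anchored[end].shape[0]
            insert_start = self.tag_len + primer_len
            variant = self.numt_variant[end]
            numt_positions = [
                p for v, p in hits
                if v == variant
                and p >= insert_start
                and p - insert_start < cfg.numt_max_insert
            ]
            chimera_hits = [
                (v, p) for v, p in hits
                if not (v == variant and p in numt_positions)
            ]
        else:
            chimera_hits = hits

        if chimera_hits:
            v, p = chimera_hits[0]
            return AssignOutcome(
                AssignClass.CHIMERA, f"interior primer {v} at position {p}"
            )
        if not candidates:
            return AssignOutcome(
                AssignClass.UNASSIGNED, "no tag/primer match within budgets"
            )
        if len(candidates) > 1:
            return AssignOutcome(
                AssignClass.UNASSIGNED,
                f"ambiguous: {len(candidates)} (tag, primer) candidates",
            )
        tag_i, end = candidates[0]
        insert_start = self.tag_len + self.anchored[end].shape[0]
        if numt_positions:
            insert_len = numt_positions[0] - insert_start
            return AssignOutcome(
                AssignClass.NUMT,
                f"opposite primer at insert position {insert_len} "
                f"(< {cfg.numt_max_insert} bp)",
            )
        assigned = AssignedRead(
            sample_id=self.samples[tag_i],
            end=end,
            insert_bases=read.bases[insert_start:],
            insert_quals=list(read.quals[insert_start:]),
            source_read_id=read.read_id,
        )
        return AssignOutcome(AssignClass.ASSIGNED, "ok", assigned)


def match_tagged_primer(read: SequenceRead, config: PlateConfig) -> AssignOutcome:
    """Classify a single read (convenience wrapper; builds a fresh
    Demultiplexer — use the class directly for bulk work)."""
    return Demultiplexer(config).classify(read)


def detect_chimera(read: SequenceRead, config: PlateConfig) -> bool:
    """True when a primer (or its reverse complement) occurs after the
    anchored tag region, excluding occurrences explained by the NuMT
    geometry of an otherwise-assignable read."""
    return Demultiplexer(config).classify(read).class_ is AssignClass.CHIMERA


def detect_numt(assigned: AssignedRead, config: PlateConfig) -> bool:
    """True when the reverse complement of the opposite-end primer occurs
    in the trimmed insert with an implied insert length below the NuMT
    threshold."""
    opposite = (
        config.rev_primer if assigned.end is End.FIVE_PRIME else config.fwd_primer
    )
    table = primer_match_table(reverse_complement(opposite))
    mm = scan_mismatches(encode(assigned.insert_bases), table)
    positions = np.flatnonzero(mm <= config.primer_mismatch_budget)
    return bool(np.any(positions < config.numt_max_insert))


def demultiplex_plate(
    reads: Iterable[SequenceRead], config: PlateConfig
) -> tuple[dict[tuple[str, End], list[AssignedRead]], AssignReport]:
    """Partition a filtered read stream into (sample, end) groups.

    Group keys cover the full cross product of configured samples and the
    two amplicon ends (empty groups are present with zero reads), so a
    96-tag plate always yields 192 groups.
    """
    demux = Demultiplexer(config)
    groups: dict[tuple[str, End], list[AssignedRead]] = {
        (sample, end): [] for sample in config.samples for end in End
    }
    report = AssignReport(
        group_counts={key: 0 for key in groups}
    )
    for read in reads:
        report.n_input += 1
        outcome = demux.classify(read)
        if outcome.class_ is AssignClass.ASSIGNED:
            assert outcome.assigned is not None
            key = (outcome.assigned.sample_id, outcome.assigned.end)
            groups[key].append(outcome.assigned)
            report.group_counts[key] += 1
            report.n_assigned += 1
        elif outcome.class_ is AssignClass.CHIMERA:
            report.n_chimera += 1
        elif outcome.class_ is AssignClass.NUMT:
            report.n_numt += 1
        else:
            report.n_unassigned += 1
    report.check()
    return groups, report
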