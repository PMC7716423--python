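"""FASTQ/FASTA I/O and the plate configuration.

All file readers accept plain or gzip-compressed paths transparently.
FASTQ qualities follow the Phred-33 convention (ASCII code − 33); scores
above 60 are clamped with a warning to stay inside the printable range.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._alphabet import IUPAC

MAX_PHRED = 60

# Folmer primers (LCO1490 / HCO2198), the standard animal COI barcode pair.
DEFAULT_FWD_PRIMER = "GGTCAACAAATCATAAAGATATTGG"
DEFAULT_REV_PRIMER = "TAAACTTCAGGGTGACCAAAAAATCA"


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class SequenceRead:
    """One FASTQ record: identifier, bases and per-base Phred scores."""

    read_id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)


def read_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """Stream SequenceReads from a (optionally gzipped) Phred-33 FASTQ file.

    Records are yielded one at a time (constant memory per record).  A
    malformed record — bases/quality length mismatch, truncated block,
    missing '+' separator — raises ValueError naming the record index.
    Phred scores above 60 are clamped to 60 with a warning; scores below
    0 (ASCII below '!') are a hard error.
    """
    with _open_text(path) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record #{index}: {exc}") from exc
            quals = [ord(c) - 33 for c in qual]
            if any(q < 0 for q in quals):
                raise ValueError(
                    f"malformed FASTQ record #{index}: quality character below '!'"
                )
            if any(q > MAX_PHRED for q in quals):
                warnings.warn(
                    f"record #{index}: Phred score above {MAX_PHRED} clamped",
                    stacklevel=2,
                )
                quals = [min(q, MAX_PHRED) for q in quals]
            yield SequenceRead(title.split()[0], seq.upper(), quals)
            index += 1


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> None:
    """Write Phred-33 FASTQ (gzipped when the path ends in .gz)."""
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            handle.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA, wrapped at 80 columns.

    Duplicate ids are rejected.
    """
    seen: set[str] = set()
    for rid, _ in records:
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r}")
        seen.add(rid)
    with _open_text(path, "wt") as handle:
        for rid, seq in records:
            handle.write(f">{rid}\n")
            for start in range(0, len(seq), 80):
                handle.write(seq[start : start + 80] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Load a FASTA file as (header, sequence) pairs (full header kept)."""
    from Bio import SeqIO

    with _open_text(path) as handle:
        return [(rec.description, str(rec.seq).upper())
                for rec in SeqIO.parse(handle, "fasta")]


# ---------------------------------------------------------------------------
# plate configuration
# ---------------------------------------------------------------------------

@dataclass
class PlateConfig:
    """Tags, primers, the tag→sample map, and every pipeline threshold.

    Threshold defaults follow the published SE400 barcoding protocol:
    reads with expected error above 10 are discarded; one mismatch is
    tolerated in the 5-bp index and one in the primer; groups are
    clustered at 98 % identity with a minimum cluster size of 5; a
    secondary cluster is kept when larger than 1/10 of the top one; the
    5′/3′ consensus pair must overlap by ≥80 bp at ≥95 % identity; the
    merged barcode must exceed 650 bp and be supported by ≥10 reads per
    end to be reported; co-amplicons with an implied insert under 300 bp
    are flagged as putative NuMTs.
    """

    tags: list[str]
    sample_map: dict[str, str] = field(default_factory=dict)
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER
    max_expected_errors: float = 10.0
    index_mismatch_budget: int = 1
    primer_mismatch_budget: int = 1
    cluster_identity: float = 0.98
    min_cluster_size: int = 5
    secondary_ratio: float = 0.1
    min_report_reads: int = 10
    min_overlap: int = 80
    min_overlap_identity: float = 0.95
    min_assembly_length: int = 650
    numt_max_insert: int = 300
    genetic_code: int = 5  # invertebrate mitochondrial

    def __post_init__(self) -> None:
        if not self.tags:
            raise ValueError("at least one tag is required")
        self.tags = [t.upper() for t in self.tags]
        lengths = {len(t) for t in self.tags}
        if len(lengths) != 1:
            raise ValueError(f"tags of unequal length: {sorted(lengths)}")
        dupes = sorted({t for t in self.tags if self.tags.count(t) > 1})
        if dupes:
            raise ValueError(f"duplicate tags: {dupes}")
        bad_tags = sorted({t for t in self.tags if any(c not in "ACGT" for c in t)})
        if bad_tags:
            raise ValueError(f"tags must be plain ACGT: {bad_tags}")
        for name in ("fwd_primer", "rev_primer"):
            primer = getattr(self, name).upper()
            setattr(self, name, primer)
            bad = sorted({c for c in primer if c not in IUPAC})
            if bad:
                raise ValueError(f"non-IUPAC characters in {name}: {bad}")
        if not self.sample_map:
            width = len(str(len(self.tags)))
            self.sample_map = {
                t: f"S{i + 1:0{width}d}" for i, t in enumerate(self.tags)
            }
        unknown = sorted(set(self.sample_map) - set(self.tags))
        if unknown:
            raise ValueError(f"sample_map references unknown tags: {unknown}")
        missing = [t for t in self.tags if t not in self.sample_map]
        if missing:
            raise ValueError(f"tags without a sample id: {missing}")
        samples = list(self.sample_map.values())
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids in sample_map")
        for name in ("cluster_identity", "secondary_ratio", "min_overlap_identity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("index_mismatch_budget", "primer_mismatch_budget",
                     "min_cluster_size", "min_report_reads", "min_overlap",
                     "min_assembly_length", "numt_max_insert"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if self.max_expected_errors < 0:
            raise ValueError("max_expected_errors must be ≥ 0")

    @property
    def tag_length(self) -> int:
        return len(self.tags[0])

    @property
    def samples(self) -> list[str]:
        """Sample ids in tag order."""
        return [self.sample_map[t] for t in self.tags]

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with _open_text(path, "wt") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)


_THRESHOLD_KEYS = {
    "max_expected_errors", "index_mismatch_budget", "primer_mismatch_budget",
    "cluster_identity", "min_cluster_size", "secondary_ratio",
    "min_report_reads", "min_overlap", "min_overlap_identity",
    "min_assembly_length", "numt_max_insert", "genetic_code",
}


def load_plate_config(path: str | Path) -> PlateConfig:
    """Load and validate a plate configuration from a YAML file.

    Schema (all threshold keys optional, defaults as in PlateConfig)::

        tags: [ACGTC, TGCAA, ...]
        sample_map: {ACGTC: A01, TGCAA: A02}   # optional; default S01..
        fwd_primer: GGTCAACAAATCATAAAGATATTGG  # optional (Folmer LCO1490)
        rev_primer: TAAACTTCAGGGTGACCAAAAAATCA # optional (Folmer HCO2198)
        max_expected_errors: 10
        ...
    """
    with _open_text(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise ValueError(f"plate config {path}: expected a YAML mapping")
    known = {"tags", "sample_map", "fwd_primer", "rev_primer"} | _THRESHOLD_KEYS
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"plate config {path}: unknown keys {unknown}")
    if "tags" not in data:
        raise ValueError(f"plate config {path}: 'tags' is required")
    return PlateConfig(**data)
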