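"""Local best-hit classification of barcode assemblies.

Queries are classified against a user-supplied reference FASTA rather
than a remote barcode database, keeping the pipeline deterministic and
network-free.  Reference headers carry an optional semicolon-delimited
lineage::

    >ref001;lineage=Animalia;Arthropoda;Insecta;Lepidoptera;Erebidae;Arctia;Arctia caja

Hits are ranked by alignment identity (shorter sequence aligned
semi-globally inside the longer via edlib) with an 8-mer prefilter to
skip hopeless references on larger databases.  Identity bands follow the
usual barcoding reading: ≥98 % is a species-level candidate, 91.4–98 %
genus/family level.

Two consumers sit on top of the search: an end-consistency check that
classifies the non-overlapping 5′ and 3′ parts of one assembly
separately and compares their lineages (a disagreement at family level
suggests an inter-sample chimera), and a symbiont classifier for
secondary consensuses (Wolbachia / fungi co-amplicons).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

from .assemble import BarcodeAssembly
from .cluster_consensus import ConsensusSequence, pairwise_identity
from .io_formats import PlateConfig, read_fasta

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
SPECIES_LEVEL_IDENTITY = 0.98
GENUS_LEVEL_IDENTITY = 0.914

_KMER = 8


@dataclass
class TaxonomyHit:
    query_id: str
    reference_id: str
    identity: float
    aligned_len: int
    lineage: list[str]

    @property
    def band(self) -> str:
        if self.identity >= SPECIES_LEVEL_IDENTITY:
            return "species"
        if self.identity >= GENUS_LEVEL_IDENTITY:
            return "genus/family"
        return "weak"


class SymbiontLabel(enum.Enum):
    WOLBACHIA = "WOLBACHIA"
    FUNGI = "FUNGI"
    OTHER = "OTHER"
    UNCLASSIFIED = "UNCLASSIFIED"


def _parse_header(header: str) -> tuple[str, list[str]]:
    ref_id, _, rest = header.partition(";")
    lineage: list[str] = []
    if rest.startswith("lineage="):
        lineage = [t.strip() for t in rest[len("lineage="):].split(";") if t.strip()]
    return ref_id.strip(), lineage


class ReferenceDB:
    """In-memory reference FASTA with an 8-mer index for candidate
    prefiltering."""

    def __init__(self, records: list[tuple[str, str]]):
        if not records:
            raise ValueError("empty reference database")
        self.ids: list[str] = []
        self.lineages: list[list[str]] = []
        self.seqs: list[str] = []
        self._kmers: list[set[str]] = []
        for header, seq in records:
            ref_id, lineage = _parse_header(header)
            self.ids.append(ref_id)
            self.lineages.append(lineage)
            self.seqs.append(seq)
            self._kmers.append(
                {seq[i : i + _KMER] for i in range(len(seq) - _KMER + 1)}
            )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceDB":
        return cls(read_fasta(path))

    def __len__(self) -> int:
        return len(self.ids)

    def candidates(self, query: str) -> list[int]:
        """Alignment candidates for a query.

        Small databases (≤ 200 entries) are aligned exhaustively; above
        that, references sharing at least one 8-mer with the query are
        prefiltered (falling back to the whole database when nothing
        shares, so a best hit is always defined)."""
        if len(self.ids) <= 200:
            return list(range(len(self.ids)))
        qk = {query[i : i + _KMER] for i in range(len(query) - _KMER + 1)}
        shared = [i for i, ks in enumerate(self._kmers) if qk & ks]
        return shared if shared else list(range(len(self.ids)))


def local_best_hits(
    query: str, db: "ReferenceDB | str | Path", n: int = 5,
    query_id: str = "query",
) -> list[TaxonomyHit]:
    """Top-n references by alignment identity, ordered identity
    descending then reference id (deterministic).  ``db`` may be a
    ReferenceDB or a path to a reference FASTA."""
    if not isinstance(db, ReferenceDB):
        db = ReferenceDB.from_fasta(db)
    if len(db) == 0:
        raise ValueError("empty reference database")
    if not query:
        raise ValueError("empty query")
    hits = []
    for i in db.candidates(query):
        ref = db.seqs[i]
        identity = pairwise_identity(query, ref)
        hits.append(
            TaxonomyHit(
                query_id=query_id,
                reference_id=db.ids[i],
                identity=identity,
                aligned_len=min(len(query), len(ref)),
                lineage=list(db.lineages[i]),
            )
        )
    hits.sort(key=lambda h: (-h.identity, h.reference_id))
    return hits[:n]


def end_consistency_check(
    assembly: BarcodeAssembly,
    db: ReferenceDB,
    config: PlateConfig,
    rank: str = "family",
) -> bool:
    """Classify the non-overlap 5′ part and the non-overlap 3′ part of a
    PASS assembly separately and compare lineages down to ``rank``
    (default family).  A mismatch flags a possible inter-sample chimera.
    """
    if assembly.len_5p == 0 or assembly.overlap_len == 0:
        raise ValueError("end_consistency_check needs a merged assembly")
    depth = RANKS.index(rank) + 1
    part5 = assembly.sequence[: assembly.len_5p - assembly.overlap_len]
    part3 = assembly.sequence[assembly.len_5p :]
    lineages = []
    for part in (part5, part3):
        best = local_best_hits(part, db, n=1, query_id=assembly.sample_id)[0]
        if not best.lineage:
            raise ValueError(
                f"no lineage on reference {best.reference_id!r}"
            )
        lineages.append(best.lineage[:depth])
    return lineages[0] == lineages[1]


def classify_secondary(
    secondary: ConsensusSequence,
    symbiont_db: ReferenceDB,
    config: PlateConfig,
    min_identity: float = 0.8,
    min_aligned: int = 100,
) -> SymbiontLabel:
    """Label a secondary (co-amplicon) consensus against a curated
    symbiont database.

    Requires read support of at least ``config.min_report_reads``.
    The label comes from the best hit's lineage when identity ≥ 0.8 over
    ≥ 100 aligned bases; anything weaker is UNCLASSIFIED.
    """
    if secondary.depth < config.min_report_reads:
        raise ValueError(
            f"secondary consensus below min_report_reads "
            f"({secondary.depth} < {config.min_report_reads})"
        )
    best = local_best_hits(secondary.bases, symbiont_db, n=1)[0]
    if best.identity < min_identity or best.aligned_len < min_aligned:
        return SymbiontLabel.UNCLASSIFIED
    labels = {t.lower() for t in best.lineage} | {best.reference_id.lower()}
    if any("wolbachia" in t for t in labels):
        return SymbiontLabel.WOLBACHIA
    if any(t == "fungi" or "fungi" in t for t in labels):
        return SymbiontLabel.FUNGI
    return SymbiontLabel.OTHER
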