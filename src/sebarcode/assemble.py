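"""Full-length barcode assembly from the 5′ and 3′ consensus pair.

The 3′ consensus is reverse-complemented into barcode orientation and the
two sequences are joined through their shared middle region: candidate
overlap lengths are scored by ungapped identity ('N' is a wildcard), the
best-scoring overlap is accepted when it spans at least ``min_overlap``
bases at identity ≥ ``min_overlap_identity``.  Disagreeing overlap
columns are resolved by combined base frequency from both ends' cluster
column counts.  A merged sequence is reported as a barcode only when it
translates without internal stop codons under the invertebrate
mitochondrial genetic code, exceeds the minimum length (> 650 bp by
default), and both ends are supported by enough reads.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from ._alphabet import encode, is_iupac
from ._alphabet import reverse_complement as _rc
from .cluster_consensus import ConsensusSequence
from .io_formats import PlateConfig


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (ambiguity codes included)."""
    if not is_iupac(seq):
        bad = sorted({c for c in seq.upper() if c not in "ACGTRYSWKMBDHVN"})
        raise ValueError(f"non-IUPAC characters: {bad}")
    return _rc(seq)


class AssemblyStatus(enum.Enum):
    PASS = "PASS"
    FAIL_NO_OVERLAP = "FAIL_NO_OVERLAP"
    FAIL_IDENTITY = "FAIL_IDENTITY"
    FAIL_STOP_CODON = "FAIL_STOP_CODON"
    FAIL_LENGTH = "FAIL_LENGTH"
    FAIL_LOW_DEPTH = "FAIL_LOW_DEPTH"


@dataclass
class BarcodeAssembly:
    """A merged (or failed) per-sample barcode with its QC trail."""

    sample_id: str
    sequence: str
    overlap_len: int
    overlap_identity: float
    depth_5p: int
    depth_3p: int
    frame: int | None
    status: AssemblyStatus
    detail: str = ""
    len_5p: int = 0
    len_3p: int = 0

    @property
    def reported(self) -> bool:
        return self.status is AssemblyStatus.PASS


def _overlap_identity(s5: np.ndarray, s3: np.ndarray, k: int) -> float:
    """Ungapped identity of the length-k suffix of s5 vs prefix of s3;
    'N' (code 4) in either sequence matches anything."""
    a = s5[len(s5) - k :]
    b = s3[:k]
    matches = (a == b) | (a == 4) | (b == 4)
    return float(matches.sum()) / k


def _best_overlap(
    five: ConsensusSequence, three_rc: ConsensusSequence, config: PlateConfig
) -> tuple[int, float] | None:
    """Best candidate overlap over all k in [min_overlap, min(len5, len3)],
    regardless of the identity threshold; None when no candidate k exists."""
    s5 = encode(five.bases)
    s3 = encode(three_rc.bases)
    k_max = min(len(s5), len(s3))
    if k_max < config.min_overlap:
        return None
    best_k, best_id = 0, -1.0
    for k in range(config.min_overlap, k_max + 1):
        ident = _overlap_identity(s5, s3, k)
        if ident > best_id or (ident == best_id and k > best_k):
            best_k, best_id = k, ident
    return best_k, best_id


def find_overlap(
    five: ConsensusSequence, three_rc: ConsensusSequence, config: PlateConfig
) -> tuple[int, float] | None:
    """Locate the 5′/3′ junction.

    Scans every overlap length k from min(len5, len3) down to
    ``min_overlap`` and returns the (k, identity) maximising identity
    (ties broken toward the longer overlap), or None when no candidate
    reaches ``min_overlap_identity``.  ``three_rc`` must already be in
    barcode orientation.
    """
    best = _best_overlap(five, three_rc, config)
    if best is None or best[1] < config.min_overlap_identity:
        return None
    return best


def merge_consensus(
    five: ConsensusSequence, three_rc: ConsensusSequence, overlap_len: int
) -> str:
    """Join the two consensuses through an accepted overlap.

    Non-overlap segments are copied verbatim.  Where overlap columns
    disagree, the two ends' column counts are summed and the base with
    the larger combined count wins; an exact tie emits 'N'.
    """
    l5 = len(five.bases)
    start5 = l5 - overlap_len
    pieces = [five.bases[:start5]]
    for j in range(overlap_len):
        b5 = five.bases[start5 + j]
        b3 = three_rc.bases[j]
        if b5 == b3:
            pieces.append(b5)
            continue
        combined = five.column_counts[:, start5 + j] + three_rc.column_counts[:, j]
        order = np.sort(combined)
        if order[-1] == order[-2] or order[-1] == 0:
            pieces.append("N")
        else:
            pieces.append("ACGT"[int(np.argmax(combined))])
    pieces.append(three_rc.bases[overlap_len:])
    return "".join(pieces)


# -- translation --------------------------------------------------------

def _codon_maps(table_id: int) -> tuple[dict[str, str], frozenset[str]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


def translate_check(
    seq: str, config: PlateConfig
) -> tuple[bool, int | None]:
    """Check for an open reading frame among the three forward frames.

    Translates complete codons under the configured genetic code
    (default: invertebrate mitochondrial, table 5); codons containing 'N'
    translate to 'X' and never count as stops; the trailing partial codon
    is ignored.  Passes when at least one frame has no internal stop
    codon (a stop in the final complete codon is tolerated); the reported
    frame is the lowest passing one.
    """
    seq = seq.upper()
    bad = sorted({c for c in seq if c not in "ACGTN"})
    if bad:
        raise ValueError(f"translate_check: non-ACGTN characters {bad}")
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    forward, stops = _codon_maps(config.genetic_code)
    for frame in range(3):
        codons = [
            seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)
        ]
        internal = codons[:-1]
        if not any(c in stops for c in internal if "N" not in c):
            return True, frame
    return False, None


def assemble_sample(
    sample_id: str,
    five: ConsensusSequence | None,
    three: ConsensusSequence | None,
    config: PlateConfig,
) -> BarcodeAssembly:
    """Run the full merge-and-validate chain for one sample.

    Gate order: both ends present → overlap found → overlap identity →
    translation → length → per-end read support; the status records the
    first failing gate.  Only PASS assemblies are reported.
    """
    depth_5p = five.depth if five else 0
    depth_3p = three.depth if three else 0

    def fail(status: AssemblyStatus, detail: str, sequence: str = "",
             overlap_len: int = 0, identity: float = 0.0,
             frame: int | None = None) -> BarcodeAssembly:
        return BarcodeAssembly(
            sample_id, sequence, overlap_len, identity, depth_5p, depth_3p,
            frame, status, detail,
            len_5p=len(five.bases) if five else 0,
            len_3p=len(three.bases) if three else 0,
        )

    if five is None or three is None:
        missing = "5'" if five is None else "3'"
        return fail(AssemblyStatus.FAIL_NO_OVERLAP, f"{missing} end missing")

    three_rc = three.reverse_complement()
    best = _best_overlap(five, three_rc, config)
    if best is None:
        return fail(
            AssemblyStatus.FAIL_NO_OVERLAP,
            f"consensus shorter than min_overlap ({config.min_overlap} bp)",
        )
    overlap_len, identity = best
    if identity < config.min_overlap_identity:
        return fail(
            AssemblyStatus.FAIL_IDENTITY,
            f"best overlap {overlap_len} bp at identity {identity:.3f} "
            f"< {config.min_overlap_identity}",
            overlap_len=overlap_len, identity=identity,
        )
    merged = merge_consensus(five, three_rc, overlap_len)
    ok, frame = translate_check(merged, config)
    if not ok:
        return fail(
            AssemblyStatus.FAIL_STOP_CODON, "stop codons in all frames",
            merged, overlap_len, identity,
        )
    if len(merged) <= config.min_assembly_length:
        return fail(
            AssemblyStatus.FAIL_LENGTH,
            f"length {len(merged)} ≤ {config.min_assembly_length}",
            merged, overlap_len, identity, frame,
        )
    if min(depth_5p, depth_3p) < config.min_report_reads:
        return fail(
            AssemblyStatus.FAIL_LOW_DEPTH,
            f"read support {min(depth_5p, depth_3p)} < {config.min_report_reads}",
            merged, overlap_len, identity, frame,
        )
    return BarcodeAssembly(
        sample_id, merged, overlap_len, identity, depth_5p, depth_3p,
        frame, AssemblyStatus.PASS, "ok",
        len_5p=len(five.bases), len_3p=len(three.bases),
    )
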