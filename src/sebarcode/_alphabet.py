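"""Nucleotide alphabet utilities shared across the pipeline.

Reads are plain {A,C,G,T,N}; primers and consensus sequences may carry the
full IUPAC degeneracy alphabet.  Sequences are encoded to small integer
arrays (A=0, C=1, G=2, T=3, N/other=4) so that tag/primer scanning can be
vectorised with numpy.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

BASES = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# char-code -> index lookup (everything unknown, incl. N, maps to 4)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def is_iupac(seq: str) -> bool:
    return all(c in IUPAC for c in seq.upper())


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string.

    Raises ValueError on characters outside the IUPAC alphabet.
    """
    try:
        return "".join(COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in sequence") from None


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 indices (A=0,C=1,G=2,T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode(idx: np.ndarray) -> str:
    return "".join("ACGTN"[i] for i in idx)


def primer_match_table(primer: str) -> np.ndarray:
    """Boolean table (len(primer), 5): entry [i, b] is True when read base
    index ``b`` is accepted by primer position ``i``.

    Degenerate primer codes accept every base they denote; a read 'N'
    (index 4) never matches -- reads containing N are filtered upstream,
    this is purely defensive.
    """
    primer = primer.upper()
    table = np.zeros((len(primer), 5), dtype=bool)
    for i, c in enumerate(primer):
        try:
            allowed = IUPAC[c]
        except KeyError:
            raise ValueError(f"non-IUPAC character {c!r} in primer") from None
        for b in allowed:
            table[i, _BASE_INDEX[b]] = True
    return table


def scan_mismatches(read_idx: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Mismatch count of a primer match-table against every start position
    of an encoded read; returns an array of length len(read) - len(primer) + 1
    (empty when the read is shorter than the primer)."""
    m = table.shape[0]
    if read_idx.size < m:
        return np.empty(0, dtype=np.intp)
    windows = sliding_window_view(read_idx, m)  # (n-m+1, m)
    matches = table[np.arange(m)[None, :], windows]
    return m - matches.sum(axis=1)


def hamming(a: str, b: str) -> int:
    """IUPAC-aware Hamming distance between a pattern ``a`` (may be
    degenerate) and a read-space string ``b``.

    A degenerate code in ``a`` matches any base it denotes; 'N' in ``b``
    mismatches everything.  Strings must be of equal length.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    mm = 0
    for ca, cb in zip(a.upper(), b.upper()):
        allowed = IUPAC.get(ca)
        if allowed is None:
            raise ValueError(f"non-IUPAC character {ca!r}")
        if cb not in allowed or cb == "N":
            mm += 1
    return mm
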