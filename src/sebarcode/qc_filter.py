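"""Read-level quality control.

A read is discarded when it contains any ambiguous base ('N') or when its
expected error count exceeds the configured cutoff.  The expected error of
a read is the sum over its bases of the error probability implied by each
Phred score,

    E* = Σ_i 10^(−Q_i / 10),

i.e. the expected number of wrong base calls in the read.  With the
default cutoff of 10 a read is removed only when E* is strictly greater
than 10; a read at exactly the cutoff is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .io_formats import MAX_PHRED, PlateConfig, SequenceRead

# 10^(-q/10) for q = 0..MAX_PHRED; quality clamping upstream guarantees
# every score indexes this table.
_ERROR_PROB = [10.0 ** (-q / 10.0) for q in range(MAX_PHRED + 1)]


def expected_errors(quals: Sequence[int]) -> float:
    """Expected number of erroneous bases implied by a Phred vector.

    Empty input yields 0.0.  Negative qualities are rejected.
    """
    total = 0.0
    for q in quals:
        if q < 0:
            raise ValueError(f"negative Phred score {q}")
        total += _ERROR_PROB[q] if q <= MAX_PHRED else 10.0 ** (-q / 10.0)
    return total


@dataclass
class FilterReport:
    """Accounting of one filtering pass; every input read is counted under
    exactly one of kept / removed-ambiguous / removed-expected-error."""

    n_input: int = 0
    n_kept: int = 0
    n_removed_ambiguous: int = 0
    n_removed_ee: int = 0

    def check(self) -> None:
        assert self.n_input == (
            self.n_kept + self.n_removed_ambiguous + self.n_removed_ee
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("n_input\tn_kept\tn_removed_ambiguous\tn_removed_ee\n")
            handle.write(
                f"{self.n_input}\t{self.n_kept}\t"
                f"{self.n_removed_ambiguous}\t{self.n_removed_ee}\n"
            )


def filter_reads(
    reads: Iterable[SequenceRead], config: PlateConfig
) -> tuple[Iterator[SequenceRead], FilterReport]:
    """Filter a read stream; returns (kept-read iterator, report).

    Kept reads preserve input order.  The ambiguous-base check runs first,
    so a read with both an 'N' and a high expected error is counted as
    ambiguous only.  The report is complete once the iterator is
    exhausted.
    """
    report = FilterReport()

    def _kept() -> Iterator[SequenceRead]:
        for read in reads:
            report.n_input += 1
            if "N" in read.bases:
                report.n_removed_ambiguous += 1
            elif expected_errors(read.quals) > config.max_expected_errors:
                report.n_removed_ee += 1
            else:
                report.n_kept += 1
                yield read

    return _kept(), report
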