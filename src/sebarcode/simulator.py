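"""Synthetic SE400 amplicon-plate generator with per-read ground truth.

The generator emulates the data-generating process of tagged-amplicon
COI barcoding on a single-end 400 bp run:

* each well holds a coding-frame-clean barcode template (600–720 bp)
  flanked by a 5-bp tag and the forward/reverse primers;
* ``depth_per_end`` reads are taken from each amplicon end — the 5′ read
  is the first 400 bases of the tagged amplicon, the 3′ read the reverse
  complement of its last 400 bases — so the two read sets share the
  amplicon middle;
* base qualities decay linearly from ``q_start`` to ``q_end`` across the
  read and substitution errors are drawn per base from the written
  quality (no indels by default);
* PCR chimeras (an extra primer copy at an interior position), short
  NuMT co-amplicons (both primers on one read, insert < 300 bp),
  divergent symbiont co-amplicons at a fraction of the target depth, and
  blank wells receiving a trickle of another well's reads are injected at
  configurable rates.

Everything is reproducible from the spec seed, and every emitted read is
recorded in a truth table with its well, end and class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._alphabet import reverse_complement
from .assemble import translate_check
from .io_formats import PlateConfig, SequenceRead

_BASES = np.array(list("ACGT"))


class ReadClass(enum.Enum):
    TARGET = "TARGET"
    CHIMERA = "CHIMERA"
    NUMT = "NUMT"
    SYMBIONT = "SYMBIONT"
    BLANK_NOISE = "BLANK_NOISE"


@dataclass
class SimPlateSpec:
    """Study conditions for one simulated plate.

    Defaults reflect a realistic SE400 barcoding run: a 96-well plate at
    50 reads per amplicon end, qualities decaying Phred 38 → 15 across
    the read, 5 % chimeric reads, 2 % NuMT reads with 120–290 bp inserts,
    and symbiont co-amplicons (70 % identity to the host) in 8 % of wells
    at one fifth of the target depth.  Blank wells receive a 6-read
    trickle per end — visible cross-talk, but below the 10-read reporting
    floor.
    """

    n_samples: int = 96
    template_length_range: tuple[int, int] = (600, 720)
    read_length: int = 400
    depth_per_end: int = 50
    quality_model: tuple[int, int] = (38, 15)
    per_base_error: float | None = None
    chimera_rate: float = 0.05
    numt_rate: float = 0.02
    numt_insert_range: tuple[int, int] = (120, 290)
    symbiont_rate: float = 0.08
    symbiont_depth_fraction: float = 0.2
    symbiont_identity: float = 0.70
    blank_wells: list[str] = field(default_factory=list)
    blank_noise_reads: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.chimera_rate, self.numt_rate, self.symbiont_rate,
                     self.symbiont_depth_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class TruthRecord:
    read_id: str
    well: str
    end: str  # "for" / "rev"
    read_class: ReadClass
    detail: str = ""


@dataclass
class SimTruth:
    reads: dict[str, TruthRecord] = field(default_factory=dict)
    templates: dict[str, str] = field(default_factory=dict)
    symbionts: dict[str, str] = field(default_factory=dict)
    numts: dict[str, str] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("read_id\twell\tend\tclass\tdetail\n")
            for rec in self.reads.values():
                handle.write(
                    f"{rec.read_id}\t{rec.well}\t{rec.end}\t"
                    f"{rec.read_class.value}\t{rec.detail}\n"
                )


def make_template(length: int, seed: int | np.random.Generator) -> str:
    """Random template with no stop codon in frame 0 (invertebrate
    mitochondrial code): codons are rejection-sampled from the 62
    non-stop codons, the trailing partial codon is uniform."""
    if length < 3:
        raise ValueError("template length must be ≥ 3")
    rng = seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed)
    )
    from Bio.Data import CodonTable

    stops = set(CodonTable.unambiguous_dna_by_id[5].stop_codons)
    codons = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in stops
    ]
    n_codons, tail = divmod(length, 3)
    picks = rng.integers(0, len(codons), size=n_codons)
    seq = "".join(codons[i] for i in picks)
    if tail:
        seq += "".join(_BASES[rng.integers(0, 4, size=tail)])
    return seq


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute a ``divergence`` fraction of positions to a different base."""
    arr = np.array(list(seq))
    n_mut = int(round(divergence * len(seq)))
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


class _PlateBuilder:
    def __init__(self, spec: SimPlateSpec, config: PlateConfig):
        if spec.n_samples > len(config.tags):
            raise ValueError(
                f"spec requests {spec.n_samples} wells but the plate config "
                f"has only {len(config.tags)} tags"
            )
        min_template = spec.template_length_range[0]
        flank = config.tag_length + max(
            len(config.fwd_primer), len(config.rev_primer)
        )
        if spec.read_length > min_template + 2 * flank:
            raise ValueError(
                "infeasible geometry: read length exceeds the shortest "
                "tagged amplicon"
            )
        self.spec = spec
        self.config = config
        self.rng = np.random.default_rng(spec.seed)
        self.reads: list[SequenceRead] = []
        self.truth = SimTruth()
        self._serial = 0
        # linear Phred decay across the read
        q_start, q_end = spec.quality_model
        self.profile = np.rint(
            np.linspace(q_start, q_end, spec.read_length)
        ).astype(int)
        if spec.per_base_error is None:
            self.error_prob = 10.0 ** (-self.profile / 10.0)
        else:
            self.error_prob = np.full(spec.read_length, spec.per_base_error)

    # ------------------------------------------------------------------
    def _amplicon(self, tag: str, insert: str) -> str:
        cfg = self.config
        return (
            tag + cfg.fwd_primer + insert
            + reverse_complement(cfg.rev_primer) + reverse_complement(tag)
        )

    def _raw_read(self, amplicon: str, end: str) -> str:
        R = self.spec.read_length
        if end == "for":
            raw = amplicon[:R]
        else:
            raw = reverse_complement(amplicon[-R:])
        if len(raw) < R:  # short amplicon: pad with adapter-like random tail
            pad = "".join(_BASES[self.rng.integers(0, 4, size=R - len(raw))])
            raw += pad
        return raw

    def _emit(self, raw: str, well: str, end: str,
              read_class: ReadClass, detail: str = "") -> None:
        """Apply the position-dependent error model and record the read."""
        arr = np.array(list(raw))
        err = self.rng.random(len(arr)) < self.error_prob[: len(arr)]
        for p in np.flatnonzero(err):
            choices = [b for b in "ACGT" if b != arr[p]]
            arr[p] = choices[self.rng.integers(0, 3)]
        read_id = f"sim{self._serial:07d}"
        self._serial += 1
        self.reads.append(
            SequenceRead(read_id, "".join(arr), list(self.profile[: len(arr)]))
        )
        self.truth.reads[read_id] = TruthRecord(
            read_id, well, end, read_class, detail
        )

    # ------------------------------------------------------------------
    def _chimera_read(self, tag: str, template: str, other: str,
                      end: str) -> tuple[str, int]:
        """Splice two templates with a fresh anchored-primer copy at the
        junction; returns (raw read, interior primer start position)."""
        cfg = self.config
        R = self.spec.read_length
        primer = cfg.fwd_primer if end == "for" else cfg.rev_primer
        donor_a = template if end == "for" else reverse_complement(template)
        donor_b = other if end == "for" else reverse_complement(other)
        head = tag + primer
        seg_a_len = int(self.rng.integers(60, 220))
        seg_a_len = min(seg_a_len, max(10, R - len(head) - len(primer) - 40))
        junction = len(head) + seg_a_len
        remainder = R - junction - len(primer)
        start_b = int(self.rng.integers(0, max(1, len(donor_b) - remainder)))
        raw = (
            head + donor_a[:seg_a_len] + primer
            + donor_b[start_b : start_b + remainder]
        )
        return raw[:R], junction

    def _well_reads(self, well: str, tag: str, template: str,
                    symbiont: str | None, templates: Sequence[str]) -> None:
        spec = self.spec
        numt_insert: str | None = None
        for end in ("for", "rev"):
            for _ in range(spec.depth_per_end):
                u = self.rng.random()
                if u < spec.chimera_rate:
                    other = templates[self.rng.integers(0, len(templates))]
                    raw, pos = self._chimera_read(tag, template, other, end)
                    self._emit(raw, well, end, ReadClass.CHIMERA,
                               f"primer_pos={pos}")
                elif u < spec.chimera_rate + spec.numt_rate:
                    if numt_insert is None:
                        lo, hi = spec.numt_insert_range
                        numt_len = int(self.rng.integers(lo, hi + 1))
                        numt_insert = _mutate(
                            template[:numt_len], 0.20, self.rng
                        )
                        self.truth.numts[well] = numt_insert
                    amp = self._amplicon(tag, numt_insert)
                    self._emit(self._raw_read(amp, end), well, end,
                               ReadClass.NUMT,
                               f"insert_len={len(numt_insert)}")
                else:
                    amp = self._amplicon(tag, template)
                    self._emit(self._raw_read(amp, end), well, end,
                               ReadClass.TARGET)
            if symbiont is not None:
                n_sym = int(round(
                    spec.symbiont_depth_fraction * spec.depth_per_end
                ))
                amp = self._amplicon(tag, symbiont)
                for _ in range(n_sym):
                    self._emit(self._raw_read(amp, end), well, end,
                               ReadClass.SYMBIONT)

    def build(self) -> tuple[list[SequenceRead], SimTruth]:
        spec, cfg = self.spec, self.config
        wells = cfg.samples[: spec.n_samples]
        tags = cfg.tags[: spec.n_samples]
        blanks = set(spec.blank_wells)
        unknown = blanks - set(wells)
        if unknown:
            raise ValueError(f"blank_wells not on the plate: {sorted(unknown)}")

        lo, hi = spec.template_length_range
        occupied: list[tuple[str, str, str, str | None]] = []
        for well, tag in zip(wells, tags):
            if well in blanks:
                continue
            length = int(self.rng.integers(lo, hi + 1))
            template = make_template(length, self.rng)
            self.truth.templates[well] = template
            symbiont = None
            if self.rng.random() < spec.symbiont_rate:
                symbiont = _mutate(
                    template, 1.0 - spec.symbiont_identity, self.rng
                )
                self.truth.symbionts[well] = symbiont
            occupied.append((well, tag, template, symbiont))

        templates = [t for _, _, t, _ in occupied]
        for well, tag, template, symbiont in occupied:
            self._well_reads(well, tag, template, symbiont, templates)

        # blank wells: a trickle of some occupied well's template carrying
        # the blank's own tag (tag hopping / pipetting cross-talk)
        for well, tag in zip(wells, tags):
            if well not in blanks:
                continue
            if not occupied:
                continue
            donor = occupied[self.rng.integers(0, len(occupied))]
            for end in ("for", "rev"):
                amp = self._amplicon(tag, donor[2])
                for _ in range(spec.blank_noise_reads):
                    self._emit(self._raw_read(amp, end), well, end,
                               ReadClass.BLANK_NOISE,
                               f"donor={donor[0]}")
        return self.reads, self.truth


def simulate_plate(
    spec: SimPlateSpec, config: PlateConfig
) -> tuple[list[SequenceRead], SimTruth]:
    """Generate one plate of reads plus its ground truth.

    Fully deterministic for a given (spec.seed, config); templates pass
    ``translate_check`` in frame 0 by construction.
    """
    return _PlateBuilder(spec, config).build()


def _self_check(template: str, config: PlateConfig) -> None:  # pragma: no cover
    ok, frame = translate_check(template, config)
    assert ok and frame == 0
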