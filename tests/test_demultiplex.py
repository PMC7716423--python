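import numpy as np
import pytest

from sebarcode import (
    AssignClass,
    AssignedRead,
    Demultiplexer,
    End,
    PlateConfig,
    ReadClass,
    SequenceRead,
    SimPlateSpec,
    demultiplex_plate,
    detect_chimera,
    detect_numt,
    hamming,
    match_tagged_primer,
    reverse_complement,
    simulate_plate,
)

from .conftest import random_seq


def _read(bases, rid="r"):
    return SequenceRead(rid, bases, [30] * len(bases))


class TestHamming:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGTA", "ACGTA", 0),
            ("AAAAA", "TTTTT", 5),
            ("R", "A", 0),  # R = A or G
            ("R", "C", 1),
            ("A", "N", 1),  # N in the read never matches
        ],
    )
    def test_examples(self, a, b, expected):
        assert hamming(a, b) == expected

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            hamming("AC", "ACG")


class TestAnchoredMatching:
    def test_exact_tag_and_forward_primer(self, small_config):
        rng = np.random.default_rng(0)
        insert = random_seq(rng, 100)
        tag = small_config.tags[3]
        read = _read(tag + small_config.fwd_primer + insert)
        out = match_tagged_primer(read, small_config)
        assert out.class_ is AssignClass.ASSIGNED
        assert out.assigned.sample_id == small_config.sample_map[tag]
        assert out.assigned.end is End.FIVE_PRIME
        assert out.assigned.insert_bases == insert  # tag+primer trimmed

    def test_reverse_primer_goes_to_three_prime(self, small_config):
        rng = np.random.default_rng(1)
        read = _read(small_config.tags[0] + small_config.rev_primer + random_seq(rng, 80))
        out = match_tagged_primer(read, small_config)
        assert out.class_ is AssignClass.ASSIGNED
        assert out.assigned.end is End.THREE_PRIME

    def test_one_mismatch_in_each_region_tolerated(self, small_config):
        rng = np.random.default_rng(2)
        tag = list(small_config.tags[0])
        tag[0] = "G" if tag[0] != "G" else "A"  # distance from other tags stays >= 1
        primer = list(small_config.fwd_primer)
        primer[3] = "A" if primer[3] != "A" else "C"
        read = _read("".join(tag) + "".join(primer) + random_seq(rng, 60))
        out = match_tagged_primer(read, small_config)
        assert out.class_ is AssignClass.ASSIGNED

    def test_two_tag_mismatches_unassigned(self, small_config):
        rng = np.random.default_rng(3)
        tag = "AAAAA"  # >= 2 mismatches from every configured tag
        assert all(hamming(t, tag) >= 2 for t in small_config.tags)
        read = _read(tag + small_config.fwd_primer + random_seq(rng, 60))
        assert match_tagged_primer(read, small_config).class_ is AssignClass.UNASSIGNED

    def test_ambiguous_tag_tie_unassigned(self):
        # two tags at distance 2; a prefix one mismatch from both is ambiguous
        cfg = PlateConfig(
            tags=["AACGT", "TTCGT"], fwd_primer="AGGCTTACGA", rev_primer="CCATGAGTTA"
        )
        rng = np.random.default_rng(4)
        read = _read("ATCGT" + cfg.fwd_primer + random_seq(rng, 60))
        out = match_tagged_primer(read, cfg)
        assert out.class_ is AssignClass.UNASSIGNED
        assert "ambiguous" in out.detail


class TestChimeraAndNumt:
    def test_interior_forward_primer_is_chimera(self, small_config):
        rng = np.random.default_rng(5)
        cfg = small_config
        head = cfg.tags[0] + cfg.fwd_primer
        bases = head + random_seq(rng, 200 - len(head)) + cfg.fwd_primer
        bases += random_seq(rng, 400 - len(bases))
        assert detect_chimera(_read(bases), cfg) is True
        assert match_tagged_primer(_read(bases), cfg).class_ is AssignClass.CHIMERA

    def test_primer_only_at_anchored_position_is_not_chimera(self, small_config):
        rng = np.random.default_rng(6)
        read = _read(
            small_config.tags[0] + small_config.fwd_primer + random_seq(rng, 300)
        )
        assert detect_chimera(read, small_config) is False

    def test_numt_geometry_is_not_chimera(self, small_config):
        """rc(reverse primer) downstream of a proper 5' start is the NuMT
        signature, not a chimera."""
        rng = np.random.default_rng(7)
        cfg = small_config
        insert = random_seq(rng, 250) + reverse_complement(cfg.rev_primer)
        bases = cfg.tags[0] + cfg.fwd_primer + insert
        bases += random_seq(rng, 400 - len(bases))
        read = _read(bases)
        assert detect_chimera(read, cfg) is False
        assert match_tagged_primer(read, cfg).class_ is AssignClass.NUMT

    def test_detect_numt_short_insert(self, small_config):
        rng = np.random.default_rng(8)
        insert = random_seq(rng, 250) + reverse_complement(small_config.rev_primer)
        insert += random_seq(rng, 80)
        assigned = AssignedRead("S1", End.FIVE_PRIME, insert, [30] * len(insert), "r")
        assert detect_numt(assigned, small_config) is True

    def test_detect_numt_full_length_target(self, small_config):
        rng = np.random.default_rng(9)
        assigned = AssignedRead(
            "S1", End.FIVE_PRIME, random_seq(rng, 370), [30] * 370, "r"
        )
        assert detect_numt(assigned, small_config) is False

    def test_insert_at_threshold_not_numt(self, small_config):
        """An implied insert of exactly numt_max_insert is not flagged."""
        from dataclasses import replace

        cfg = replace(small_config, numt_max_insert=200)
        rng = np.random.default_rng(10)
        insert = random_seq(rng, 200) + reverse_complement(cfg.rev_primer)
        assigned = AssignedRead("S1", End.FIVE_PRIME, insert, [30] * len(insert), "r")
        assert detect_numt(assigned, cfg) is False


class TestPlatePartition:
    def test_single_read_single_group(self, small_config):
        rng = np.random.default_rng(11)
        read = _read(small_config.tags[0] + small_config.fwd_primer + random_seq(rng, 60))
        groups, report = demultiplex_plate([read], small_config)
        assert len(groups) == 8  # 4 samples x 2 ends, empty groups included
        key = (small_config.samples[0], End.FIVE_PRIME)
        assert len(groups[key]) == 1
        assert report.group_counts[key] == 1
        assert sum(report.group_counts.values()) == 1

    def test_partition_property_on_simulated_plate(self, config96):
        spec = SimPlateSpec(
            n_samples=8, depth_per_end=20, template_length_range=(658, 658),
            chimera_rate=0.1, numt_rate=0.05, symbiont_rate=0.3, seed=3,
        )
        reads, _ = simulate_plate(spec, config96)
        groups, report = demultiplex_plate(reads, config96)
        report.check()
        assert report.n_input == len(reads)
        placed = sum(len(v) for v in groups.values())
        assert placed == report.n_assigned

    def test_error_free_plate_fully_assigned_to_truth(self, config96):
        spec = SimPlateSpec(
            n_samples=6, depth_per_end=10, template_length_range=(658, 658),
            per_base_error=0.0, chimera_rate=0.0, numt_rate=0.0,
            symbiont_rate=0.0, seed=4,
        )
        reads, truth = simulate_plate(spec, config96)
        demux = Demultiplexer(config96)
        for read in reads:
            out = demux.classify(read)
            rec = truth.reads[read.read_id]
            assert out.class_ is AssignClass.ASSIGNED
            assert out.assigned.sample_id == rec.well
            assert out.assigned.end.value == rec.end

    def test_simulated_chimeras_with_exact_primer_all_flagged(self, config96):
        spec = SimPlateSpec(
            n_samples=4, depth_per_end=30, template_length_range=(658, 658),
            per_base_error=0.0, chimera_rate=0.3, numt_rate=0.0,
            symbiont_rate=0.0, seed=5,
        )
        reads, truth = simulate_plate(spec, config96)
        demux = Demultiplexer(config96)
        n_chim = 0
        for read in reads:
            if truth.reads[read.read_id].read_class is ReadClass.CHIMERA:
                n_chim += 1
                assert demux.classify(read).class_ is AssignClass.CHIMERA
        assert n_chim > 0


# --------------------------------------------------------------------------
# brute-force oracle equivalence on short reads
# --------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}


def _mm(pattern, text):
    return sum(
        1 for p, t in zip(pattern, text) if t == "N" or t not in _IUPAC[p]
    )


def _oracle_classify(read, cfg):
    """Independent re-statement of the assignment rules: try every
    (tag, primer, position) combination with plain loops."""
    L = len(cfg.tags[0])
    bases = read.bases
    candidates = []
    for ti, tag in enumerate(cfg.tags):
        if len(bases) < L or _mm(tag, bases[:L]) > cfg.index_mismatch_budget:
            continue
        for end, primer in (
            (End.FIVE_PRIME, cfg.fwd_primer),
            (End.THREE_PRIME, cfg.rev_primer),
        ):
            if len(bases) >= L + len(primer) and (
                _mm(primer, bases[L : L + len(primer)])
                <= cfg.primer_mismatch_budget
            ):
                candidates.append((ti, end))
    variants = {
        "fwd": cfg.fwd_primer,
        "rev": cfg.rev_primer,
        "rc_fwd": reverse_complement(cfg.fwd_primer),
        "rc_rev": reverse_complement(cfg.rev_primer),
    }
    hits = []
    for name, primer in variants.items():
        for pos in range(L + 1, len(bases) - len(primer) + 1):
            if _mm(primer, bases[pos : pos + len(primer)]) <= cfg.primer_mismatch_budget:
                hits.append((name, pos))
    numt = []
    if len(candidates) == 1:
        _, end = candidates[0]
        primer_len = len(cfg.fwd_primer if end is End.FIVE_PRIME else cfg.rev_primer)
        start = L + primer_len
        want = "rc_rev" if end is End.FIVE_PRIME else "rc_fwd"
        numt = [
            p for v, p in hits
            if v == want and p >= start and p - start < cfg.numt_max_insert
        ]
        chimera = [(v, p) for v, p in hits if not (v == want and p in numt)]
    else:
        chimera = hits
    if chimera:
        return AssignClass.CHIMERA, None
    if len(candidates) != 1:
        return AssignClass.UNASSIGNED, None
    if numt:
        return AssignClass.NUMT, None
    ti, end = candidates[0]
    return AssignClass.ASSIGNED, (cfg.samples[ti], end)


def test_oracle_equivalence_on_random_short_reads(small_config):
    cfg = small_config
    rng = np.random.default_rng(42)
    demux = Demultiplexer(cfg)
    rc_rev = reverse_complement(cfg.rev_primer)
    seen = set()
    for trial in range(400):
        n = int(rng.integers(20, 101))
        bases = list(random_seq(rng, n))
        kind = trial % 5
        if kind >= 1 and n >= 40:
            tag = cfg.tags[int(rng.integers(0, 4))]
            head = tag + cfg.fwd_primer
            bases[: len(head)] = list(head)
            if kind == 2:  # sprinkle mismatches
                for _ in range(int(rng.integers(0, 4))):
                    p = int(rng.integers(0, len(head)))
                    bases[p] = "ACGT"[int(rng.integers(0, 4))]
            if kind == 3:  # interior primer copy
                pos = int(rng.integers(6, n - len(cfg.fwd_primer) + 1))
                bases[pos : pos + len(cfg.fwd_primer)] = list(cfg.fwd_primer)
            if kind == 4:  # NuMT-style rc(rev) downstream
                pos = int(rng.integers(15, n - len(rc_rev) + 1))
                bases[pos : pos + len(rc_rev)] = list(rc_rev)
        read = _read("".join(bases), rid=f"t{trial}")
        expected_class, expected_target = _oracle_classify(read, cfg)
        out = demux.classify(read)
        assert out.class_ is expected_class, (trial, read.bases)
        seen.add(expected_class)
        if expected_class is AssignClass.ASSIGNED:
            assert (out.assigned.sample_id, out.assigned.end) == expected_target
    # the generator must have exercised every outcome class
    assert seen == set(AssignClass)
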