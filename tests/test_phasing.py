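"""PHAS locus detection: register scan, hypergeometric tail, triggers."""

import math

import pytest

from srnascape import phasing
from srnascape._seqs import revcomp
from srnascape.phasing import (
    PhasLocus,
    apply_exclusion,
    assign_trigger,
    detect_phas_loci,
    phas_conservation,
    phasing_pvalue,
    scan_phase_windows,
)


def enumeration_pvalue(n_positions, phase_slots, occupied, phased):
    """Independent oracle: exact hypergeometric tail via integer arithmetic."""
    total = math.comb(n_positions, occupied)
    acc = 0
    for i in range(phased, min(occupied, phase_slots) + 1):
        acc += math.comb(phase_slots, i) * math.comb(
            n_positions - phase_slots, occupied - i
        )
    return acc / total


class TestPvalue:
    def test_zero_phased_is_certain(self):
        assert phasing_pvalue(210, 10, 5, 0) == 1.0

    def test_small_case_exact_fraction(self):
        p = phasing_pvalue(40, 2, 2, 2)
        assert p == pytest.approx(1 / math.comb(40, 2), rel=1e-12)

    @pytest.mark.parametrize(
        "args",
        [(210, 10, 10, 9), (210, 10, 10, 10), (120, 10, 20, 5), (63, 3, 7, 2)],
    )
    def test_matches_enumeration_oracle(self, args):
        assert phasing_pvalue(*args) == pytest.approx(
            enumeration_pvalue(*args), rel=1e-9
        )

    def test_monotone_in_phased(self):
        prev = 1.1
        for phased in range(0, 11):
            p = phasing_pvalue(210, 10, 12, phased)
            assert p <= prev + 1e-15
            prev = p

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            phasing_pvalue(210, 10, 5, 8)  # phased > occupied


class TestScan:
    def test_perfect_register(self):
        placements = [("chr1", p, "+") for p in (0, 21, 42)]
        windows = scan_phase_windows(placements, 21)
        chrom, anchor, occ, phased, n_pos, p = windows[0]
        assert (occ, phased) == (3, 3)

    def test_off_register_reads_not_phased(self):
        placements = [("chr1", p, "+") for p in (0, 10, 33)]
        windows = scan_phase_windows(placements, 21, min_depth=1)
        by_anchor = {w[1]: w for w in windows}
        assert by_anchor[0][3] == 1  # only the anchor itself on register

    def test_min_depth_drops_two_position_windows(self):
        placements = [("chr1", p, "+") for p in (0, 21)]
        assert scan_phase_windows(placements, 21) == []

    def test_antisense_offset_convention_stable(self):
        """Moving a read to the opposite strand with the 2-nt offset leaves
        the phased count unchanged."""
        sense = [("chr1", p, "+") for p in (0, 21, 42, 63)]
        mixed = sense[:3] + [("chr1", 63 - phasing.ANTISENSE_OFFSET, "-")]
        ws = scan_phase_windows(sense, 21)[0]
        wm = scan_phase_windows(mixed, 21)[0]
        assert (ws[2], ws[3]) == (wm[2], wm[3])

    def test_detection_merges_overlapping_windows(self):
        placements = [("chr1", k * 21, "+") for k in range(12)]
        loci = detect_phas_loci(placements, 21)
        assert len(loci) == 1
        assert loci[0].p_value < 1e-5


class TestTrigger:
    def _genome_with_site(self, trigger):
        left = "ACGTTGCA" * 10
        right = "TGCAACGT" * 10
        site = revcomp(trigger)
        genome = {"chr1": left + site + right}
        start = len(left) + len(site)
        locus = PhasLocus(
            locus_id="p1", chrom="chr1", start=start, end=start + 210,
            cycle=21, n_positions=210, occupied_positions=10,
            phased_positions=10, p_value=1e-9,
        )
        return genome, locus

    def test_perfect_site_found(self):
        trigger = "ACGGTTACGGTTACGGTTACTT"
        genome, locus = self._genome_with_site(trigger)
        hit = assign_trigger(locus, {"miR2118": trigger}, genome)
        assert hit is not None
        assert hit[0] == "miR2118" and hit[1] == 22

    def test_no_site_returns_none(self):
        genome = {"chr1": "A" * 400}
        locus = PhasLocus(
            locus_id="p1", chrom="chr1", start=100, end=310, cycle=21,
            n_positions=210, occupied_positions=10, phased_positions=10,
            p_value=1e-9,
        )
        assert assign_trigger(locus, {"miR2118": "ACGGTTACGGTTACGGTTACTT"}, genome) is None

    def test_tie_prefers_five_prime_most_site(self):
        trigger = "ACGGTTACGGTTACGGTTACTT"
        site = revcomp(trigger)
        genome = {"chr1": "T" * 30 + site + "T" * 10 + site + "T" * 200}
        locus = PhasLocus(
            locus_id="p1", chrom="chr1", start=52, end=262, cycle=21,
            n_positions=210, occupied_positions=10, phased_positions=10,
            p_value=1e-9,
        )
        hit = assign_trigger(locus, {"miR2118": trigger}, genome)
        assert hit[2] == 30  # the earlier of the two equal-score sites


class TestExclusion:
    def _locus(self, trigger, length):
        locus = PhasLocus(
            locus_id="p", chrom="chr1", start=100, end=310, cycle=24,
            n_positions=240, occupied_positions=8, phased_positions=8,
            p_value=1e-8,
        )
        locus.trigger = trigger
        locus.trigger_length = length
        return locus

    def test_retrotransposon_and_mir171a_excluded(self):
        locus = self._locus("miR171a", 22)
        te = [("chr1", 50, 400, "retrotransposon")]
        assert apply_exclusion(locus, te)
        assert locus.exclusion_reason == "retrotransposon+miR170/171a"

    def test_other_trigger_kept(self):
        locus = self._locus("miR2275", 22)
        te = [("chr1", 50, 400, "retrotransposon")]
        assert not apply_exclusion(locus, te)

    def test_no_te_overlap_kept(self):
        locus = self._locus("miR171a", 22)
        te = [("chr2", 50, 400, "retrotransposon")]
        assert not apply_exclusion(locus, te)


class TestConservation:
    def _locus(self, trigger, phasirnas):
        locus = PhasLocus(
            locus_id="p", chrom="chr1", start=0, end=210, cycle=21,
            n_positions=210, occupied_positions=10, phased_positions=10,
            p_value=1e-9,
        )
        locus.trigger = trigger
        locus.phasirnas = phasirnas
        return locus

    def test_identical_loci_conserved(self):
        seqs = ["ACGTACGTACGTACGTACGTA", "TTGGCCAATTGGCCAATTGGC"]
        assert phas_conservation(self._locus("miR2118", seqs), self._locus("miR2118", seqs))

    def test_single_similar_pair_insufficient(self):
        a = ["ACGTACGTACGTACGTACGTA", "TTGGCCAATTGGCCAATTGGC"]
        b = ["ACGTACGTACGTACGTACGTA", "GGGGGGGGGGGGGGGGGGGGG"]
        assert not phas_conservation(self._locus("miR2118", a), self._locus("miR2118", b))

    def test_different_triggers_never_conserved(self):
        seqs = ["ACGTACGTACGTACGTACGTA", "TTGGCCAATTGGCCAATTGGC"]
        assert not phas_conservation(self._locus("miR2118", seqs), self._locus("miR2275", seqs))


class TestPipelinePhas:
    def test_all_planted_loci_accepted(self, default_run, truth):
        found = default_run.phas_loci
        for p in truth.phas:
            hits = [
                l for l in found
                if l.chrom == p.chrom and l.cycle == p.cycle
                and l.start < p.end and p.start < l.end
            ]
            assert hits, p.locus_id
            assert hits[0].p_value < 1e-5

    def test_triggers_assigned_correctly(self, default_run, truth):
        found = default_run.phas_loci
        for p in truth.phas:
            hits = [
                l for l in found
                if l.chrom == p.chrom and l.cycle == p.cycle
                and l.start < p.end and p.start < l.end
            ]
            assert hits[0].trigger == p.trigger
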