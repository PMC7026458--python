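"""miRNA discovery: clustering, gates, canonical selection, known/novel."""

import pandas as pd
import pytest

from srnascape import discovery
from srnascape._seqs import revcomp
from srnascape.discovery import MirnaLocus, Window, evaluate_duplex
from srnascape.preprocess import ReadSet


def readset_with_placements(placements, counts):
    """Build a minimal filtered ReadSet from (seq -> [(chrom, start, strand)])."""
    frame = pd.DataFrame({"lib1": pd.Series(counts, dtype=int)})
    info = pd.DataFrame({"library_id": ["lib1"], "tissue": ["t"], "replicate": 1})
    rs = ReadSet(counts=frame, library_info=info)
    rs.alignments = {
        seq: [(c, s, strand, 0) for c, s, strand in places]
        for seq, places in placements.items()
    }
    rs.status = pd.Series("pass", index=frame.index)
    return rs


class TestClustering:
    def test_nearby_reads_merge(self):
        a, b = "A" * 21, "C" * 21
        rs = readset_with_placements(
            {a: [("chr1", 100, "+")], b: [("chr1", 126, "+")]}, {a: 5, b: 5}
        )
        windows, _ = discovery.cluster_candidates(rs)
        assert len(windows) == 1

    def test_distant_reads_split(self):
        a, b = "A" * 21, "C" * 21
        rs = readset_with_placements(
            {a: [("chr1", 100, "+")], b: [("chr1", 600, "+")]}, {a: 5, b: 5}
        )
        windows, _ = discovery.cluster_candidates(rs)
        assert len(windows) == 2

    def test_overlong_cluster_discarded(self):
        seqs = {}
        counts = {}
        base = "ACGTACGTACGTACGTACGTA"
        for i in range(5):
            seq = base[:-1] + "ACGTA"[i]
            seqs[seq] = [("chr1", 100 + i * 95, "+")]
            counts[seq] = 3
        rs = readset_with_placements(seqs, counts)
        windows, discarded = discovery.cluster_candidates(rs)
        assert discarded == 1
        assert windows == []

    def test_opposite_strand_reads_not_merged_but_attached(self):
        a, b = "A" * 21, "C" * 21
        rs = readset_with_placements(
            {a: [("chr1", 100, "+")], b: [("chr1", 110, "-")]}, {a: 5, b: 5}
        )
        windows, _ = discovery.cluster_candidates(rs)
        plus = [w for w in windows if w.strand == "+"][0]
        assert b in plus.antisense_reads


class TestStrandBias:
    def _window(self, sense, anti):
        w = Window(chrom="chr1", start=0, end=100, strand="+")
        for i, (seq, _) in enumerate(sense.items()):
            w.sense_reads[seq] = (10 + i, 0)
        for i, (seq, _) in enumerate(anti.items()):
            w.antisense_reads[seq] = (10 + i, 0)
        return w, pd.Series({**sense, **anti})

    def test_pure_sense_is_one(self):
        w, counts = self._window({"A" * 21: 10}, {})
        assert discovery.strand_bias(w, counts) == 1.0

    def test_ninety_ten_meets_threshold(self):
        w, counts = self._window({"A" * 21: 9}, {"C" * 21: 1})
        assert discovery.strand_bias(w, counts) == pytest.approx(0.9)

    def test_eighty_twenty_fails_threshold(self):
        w, counts = self._window({"A" * 21: 8}, {"C" * 21: 2})
        assert discovery.strand_bias(w, counts) == pytest.approx(0.8)
        assert discovery.strand_bias(w, counts) < discovery.MIN_STRAND_BIAS

    def test_empty_window_rejected(self):
        w = Window(chrom="chr1", start=0, end=10, strand="+")
        with pytest.raises(ValueError):
            discovery.strand_bias(w, pd.Series(dtype=float))


class TestCanonicalSelection:
    def test_most_abundant_wins(self):
        w = Window(chrom="chr1", start=0, end=100, strand="+")
        w.sense_reads = {"AAAA": (10, 0), "CCCC": (30, 0)}
        mature, _ = discovery.select_canonical(w, pd.Series({"AAAA": 100, "CCCC": 40}))
        assert mature == "AAAA"

    def test_tie_broken_towards_five_prime(self):
        w = Window(chrom="chr1", start=0, end=100, strand="+")
        w.sense_reads = {"AAAA": (30, 0), "CCCC": (10, 0)}
        mature, start = discovery.select_canonical(
            w, pd.Series({"AAAA": 100, "CCCC": 100})
        )
        assert (mature, start) == ("CCCC", 10)


class TestDuplex:
    def test_perfect_duplex(self):
        mature = "ACGTACGTACGTACGTACGTA"
        # full complement, standard 2-nt 3' overhangs
        star = revcomp(mature)
        ok, mm, bulges = evaluate_duplex(mature, star)
        assert ok and mm == 0 and bulges == 0

    def test_six_mismatches_fail(self):
        mature = "ACGTACGTACGTACGTACGTA"
        star = list(revcomp(mature))
        # six non-pairing substitutions spread across the duplex interior;
        # the replacement base can never pair the opposing mature base
        for pos in (3, 6, 9, 12, 15, 17):
            partner = mature[len(mature) - 1 - pos]
            star[pos] = {"A": "C", "C": "A", "G": "G", "T": "C"}[partner]
        ok, mm, bulges = evaluate_duplex(mature, "".join(star))
        assert mm >= 6 and not ok

    def test_four_asymmetric_bulges_fail(self):
        mature = "ACGTACGTACGTACGTACGTA"
        star = revcomp(mature)
        # delete four spread bases from the star: four one-sided gaps
        bulged = star[:3] + star[4:8] + star[9:13] + star[14:18] + star[19:]
        ok, mm, bulges = evaluate_duplex(mature, bulged)
        assert bulges >= 4 and not ok

    def test_overlapping_intervals_error(self):
        with pytest.raises(ValueError, match="overlap"):
            evaluate_duplex("ACGT" * 5, "ACGT" * 5, (10, 31), (25, 46))


class TestKnownNovel:
    def _locus(self, mature):
        return MirnaLocus(
            locus_id="x", chrom="chr1", start=0, end=100, strand="+",
            structure=".", mature=mature, mature_start=10, arm="5p",
            star="A" * 21, star_start=60, star_supported=True,
            strand_bias=1.0, abundance_bias=1.0,
            duplex_mismatches=0, asymmetric_bulges=0,
        )

    def test_exact_match_is_known(self):
        locus = self._locus("ACGTACGTACGTACGTACGTA")
        assert discovery.classify_known_novel(locus, {"ref": locus.mature}) == "known"

    def test_three_mismatches_is_novel(self):
        mature = "ACGTACGTACGTACGTACGTA"
        ref = "TTTTACGTACGTACGTACGTA"  # 3 substitutions
        locus = self._locus(mature)
        assert discovery.classify_known_novel(locus, {"ref": ref}) == "novel"

    def test_empty_reference_all_novel(self):
        locus = self._locus("ACGTACGTACGTACGTACGTA")
        assert discovery.classify_known_novel(locus, {}) == "novel"


class TestEndToEnd:
    def test_accepted_loci_satisfy_all_gates(self, default_run):
        for locus in default_run.loci:
            assert locus.precursor_length <= 300
            assert locus.strand_bias >= 0.9
            assert locus.abundance_bias >= 0.75
            assert locus.duplex_mismatches <= 5
            assert locus.asymmetric_bulges <= 3

    def test_planted_recovery_rate(self, default_run, truth, truth_to_discovered):
        assert len(truth_to_discovered) >= 0.9 * len(truth.mirna)

    def test_no_contaminant_only_windows_accepted(self, default_run, truth):
        planted = set()
        for m in truth.mirna:
            planted.add((m.chrom, m.start, m.end))
        for locus in default_run.loci:
            hit = any(
                locus.chrom == c and locus.start < e and s < locus.end
                for c, s, e in planted
            )
            assert hit, (locus.chrom, locus.start, locus.end)
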