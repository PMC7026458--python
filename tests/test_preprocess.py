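"""Read collapsing, alignment, TPM normalisation and the filter cascade."""

import numpy as np
import pandas as pd
import pytest

from srnascape import preprocess
from srnascape._seqs import revcomp
from srnascape.preprocess import FilterParams, GenomeIndex, ReadSet


def make_readset(counts: dict, libraries=("lib1",)) -> ReadSet:
    frame = pd.DataFrame(counts).T
    frame.columns = list(libraries)
    info = pd.DataFrame(
        {"library_id": list(libraries), "tissue": list(libraries), "replicate": 1}
    )
    return ReadSet(counts=frame.astype(int), library_info=info)


class TestCollapse:
    def test_distinct_sequences_counted(self):
        rs = preprocess.collapse_reads({"lib1": ["ACGU", "ACGU", "ACGA"]})
        assert rs.counts.loc["ACGT", "lib1"] == 2  # U unified to T
        assert rs.counts.loc["ACGA", "lib1"] == 1

    def test_shared_sequence_across_libraries(self):
        rs = preprocess.collapse_reads(
            {"a": ["ACGT"], "b": ["ACGT"], "c": ["ACGT"]}
        )
        assert rs.counts.shape == (1, 3)
        assert (rs.counts.loc["ACGT"] == 1).all()

    def test_ambiguous_bases_dropped_with_tally(self):
        rs = preprocess.collapse_reads({"a": ["ACGT", "ACNT"]})
        assert "ACNT" not in rs.counts.index
        assert rs.n_dropped_ambiguous == 1

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            rs = preprocess.collapse_reads({})
        assert rs.counts.empty


class TestAlignment:
    genome = {"chr1": "TTTTTTTGGGCCCAAATTTCCCGGGACGTACGTACGTTTTTTTTT"}

    def test_exact_substring_aligns_with_zero_mismatches(self):
        idx = GenomeIndex(self.genome)
        read = self.genome["chr1"][7:28]
        hits = idx.align(read)
        assert ("chr1", 7, "+", 0) in hits

    def test_one_substitution_allowed(self):
        idx = GenomeIndex(self.genome)
        read = list(self.genome["chr1"][7:28])
        read[10] = "A" if read[10] != "A" else "C"
        hits = idx.align("".join(read))
        assert ("chr1", 7, "+", 1) in hits

    def test_two_substitutions_unaligned(self):
        idx = GenomeIndex(self.genome)
        read = list(self.genome["chr1"][7:28])
        for pos in (5, 15):
            read[pos] = "A" if read[pos] != "A" else "C"
        assert idx.align("".join(read)) == []

    def test_reverse_strand_hit_reported(self):
        idx = GenomeIndex(self.genome)
        read = revcomp(self.genome["chr1"][7:28])
        hits = idx.align(read)
        assert ("chr1", 7, "-", 0) in hits


class TestTPM:
    def test_simple_scaling(self):
        genome = {"chr1": "A" * 5 + "CGTACGTACGTACGTACGTAC" + "T" * 5}
        read = genome["chr1"][5:26]
        rs = make_readset({read: {"lib1": 5}})
        preprocess.align_reads(rs, genome)
        preprocess.tpm_normalize(rs)
        # the only read is the whole library: 5 / 5 * 1e6
        assert rs.tpm.loc[read, "lib1"] == pytest.approx(1_000_000.0)

    def test_tpm_identity_per_library(self, small_sim):
        from srnascape import simulate

        libs, info = simulate.generate_libraries(small_sim)
        rs = preprocess.collapse_reads(libs, info)
        preprocess.align_reads(rs, small_sim.genome)
        preprocess.tpm_normalize(rs)
        lengths = rs.counts.index.str.len()
        in_denom = np.array(
            [bool(rs.alignments[q]) for q in rs.counts.index]
        ) & np.asarray((lengths >= 18) & (lengths <= 26))
        sums = rs.tpm[in_denom].sum(axis=0)
        assert np.allclose(sums, 1_000_000.0)

    def test_zero_mapped_library_flagged(self):
        rs = make_readset({"ACGTACGTACGTACGTACGTA": {"lib1": 3}})
        rs.alignments = {"ACGTACGTACGTACGTACGTA": []}
        with pytest.warns(UserWarning, match="zero mapped"):
            preprocess.tpm_normalize(rs)
        assert rs.tpm.isna().all().all()


class TestFilterCascade:
    def _prepared(self, counts, genome, blacklist=None):
        rs = make_readset(counts)
        preprocess.align_reads(rs, genome)
        preprocess.tpm_normalize(rs)
        preprocess.filter_reads(rs, blacklist or {})
        return rs

    def test_irregular_size_removed(self):
        genome = {"chr1": "GGAACCTTGGAACCTTGGAACCTTGGAACCTT"}
        short = genome["chr1"][:17]
        ok = genome["chr1"][:21]
        rs = self._prepared({short: {"lib1": 500}, ok: {"lib1": 500}}, genome)
        assert rs.status[short] == "size"
        assert rs.status[ok] == "pass"

    def test_repetitive_hits_removed(self):
        unit = "ACGGTTCAACGGTTCAACGGT"
        genome = {"chr1": ("ACGGTTCA" * 60) + "TTTTTTTTTTGGCCGGAATTCCGGTT"}
        other = genome["chr1"][-21:]
        rs = self._prepared({unit: {"lib1": 400}, other: {"lib1": 400}}, genome)
        assert len(rs.alignments[unit]) > 20
        assert rs.status[unit] == "repetitive"
        assert rs.status[other] == "pass"

    def test_structural_blacklist_match_removed(self):
        genome = {"chr1": "TTGCAGCAGCAGTTACGATCGATCGGGCCCAAATTTGGGCCCTTAA"}
        read = genome["chr1"][2:24]
        rs = self._prepared(
            {read: {"lib1": 1000}}, genome, blacklist={"trna1": genome["chr1"][:30]}
        )
        assert rs.status[read] == "structural"

    def test_low_abundance_predicate(self):
        # retained iff total > 100 TPM AND max library > 10 TPM
        genome = {"chr1": "AATTGGCCAATTGGCCAATTGGCCAATTGGCCAACCGGTTAA"}
        a = genome["chr1"][0:21]
        b = genome["chr1"][21:42]
        counts = pd.DataFrame(
            {"lib1": {a: 12, b: 99_988 - 9}, "lib2": {a: 138, b: 99_862 - 138 + 9}}
        ).fillna(0).astype(int)
        info = pd.DataFrame(
            {"library_id": ["lib1", "lib2"], "tissue": ["t1", "t2"], "replicate": 1}
        )
        rs = ReadSet(counts=counts, library_info=info)
        preprocess.align_reads(rs, genome)
        preprocess.tpm_normalize(rs)
        preprocess.filter_reads(rs, {})
        # read a: total 150 TPM, max-library 138 TPM -> both conditions met
        assert rs.tpm.loc[a].sum() > 100
        assert rs.status[a] == "pass"

    def test_unaligned_read_flagged(self):
        genome = {"chr1": "GGAACCTTGGAACCTTGGAACCTTGGAACCTT"}
        rs = self._prepared({"TGCATGCATGCATGCATGCAT": {"lib1": 100}}, genome)
        assert rs.status["TGCATGCATGCATGCATGCAT"] == "unaligned"

    def test_cascade_is_idempotent(self):
        genome = {"chr1": "GGAACCTTGGAACCTTGGAACCTTGGAACCTT"}
        rs = self._prepared(
            {genome["chr1"][:17]: {"lib1": 5}, genome["chr1"][:21]: {"lib1": 995}},
            genome,
        )
        first = rs.status.copy()
        preprocess.filter_reads(rs, {})
        pd.testing.assert_series_equal(first, rs.status)

    def test_every_record_has_exactly_one_status(self, default_run):
        status = default_run.reads.status
        assert status.notna().all()
        assert set(status.unique()) <= {
            "pass", "size", "structural", "low_abundance", "repetitive", "unaligned"
        }

    def test_clean_planted_matures_all_pass(self, default_run, truth):
        reads = default_run.reads
        for m in truth.mirna:
            assert reads.status[m.mature] == "pass", m.locus_id
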