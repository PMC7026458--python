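"""Read collapsing, genome alignment, TPM normalisation and the filter cascade.

The filter cascade removes, in fixed order: irregular sizes (retaining
18-26 nt), structural RNAs (tRNA/rRNA/snRNA/snoRNA blacklist, matched with
at most one substitution), low-abundance reads, and highly repetitive reads
(more than 20 genomic placements).  A read is retained by the abundance
filter iff its total abundance exceeds 100 TPM AND its maximum per-library
abundance exceeds 10 TPM — i.e. both aggregate and single-library support
are required.

Alignment reports every genomic placement with at most one substitution
(no indels) on either strand, found with a pigeonhole seed index: any
<=1-substitution placement of a read leaves either its first or its last
``k`` bases exact, so exact seed hits of both ends enumerate all candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seqs import hamming, revcomp, to_dna

MIN_LEN = 18
MAX_LEN = 26
MAX_HITS = 20
MIN_TOTAL_TPM = 100.0
MIN_LIB_TPM = 10.0

FILTER_ORDER = ["size", "unaligned", "structural", "low_abundance", "repetitive"]


@dataclass
class FilterParams:
    min_len: int = MIN_LEN
    max_len: int = MAX_LEN
    max_hits: int = MAX_HITS
    min_total_tpm: float = MIN_TOTAL_TPM
    min_lib_tpm: float = MIN_LIB_TPM
    # TPM denominator: alignments of size-passing reads only (default) or of
    # all aligned reads
    tpm_denominator: str = "size_pass"


@dataclass
class ReadSet:
    """Collapsed reads with per-library counts and derived annotations."""

    counts: pd.DataFrame  # index: sequence; columns: library ids
    library_info: pd.DataFrame  # library_id / tissue / replicate
    n_dropped_ambiguous: int = 0
    alignments: dict[str, list[tuple[str, int, str, int]]] = field(default_factory=dict)
    tpm: pd.DataFrame | None = None
    mapped_totals: pd.Series | None = None
    status: pd.Series | None = None
    attrition: pd.DataFrame | None = None

    @property
    def sequences(self) -> pd.Index:
        return self.counts.index

    def passing(self) -> pd.Index:
        if self.status is None:
            raise RuntimeError("filters have not been applied")
        return self.status.index[self.status == "pass"]

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def tissue_mean_tpm(self) -> pd.DataFrame:
        """Replicate-mean TPM per tissue (columns ordered as first seen)."""
        if self.tpm is None:
            raise RuntimeError("TPM has not been computed")
        lib2tissue = self.library_info.set_index("library_id")["tissue"]
        grouped = self.tpm.T.groupby(self.tpm.columns.map(lib2tissue), sort=False).mean().T
        return grouped


def collapse_reads(
    libraries: dict[str, pd.Series | dict | list],
    library_info: pd.DataFrame | None = None,
) -> ReadSet:
    """Collapse per-library sequences into one record per distinct read.

    ``libraries`` maps library id to either a Series/dict of sequence ->
    count, or a plain list of (possibly repeated) sequences.  T and U are
    unified; sequences containing other ambiguity codes are dropped and
    tallied.
    """
    if not libraries:
        warnings.warn("no libraries provided; returning empty read set")
    cols = {}
    dropped = 0
    for lib_id, data in libraries.items():
        if isinstance(data, (list, tuple)):
            data = pd.Series(data).value_counts()
        s = pd.Series(data, dtype=float)
        s.index = s.index.map(to_dna)
        s = s.groupby(level=0).sum()
        ok = np.array([set(q) <= set("ACGT") for q in s.index], dtype=bool)
        dropped += int((~ok).sum())
        cols[lib_id] = s[ok]
    counts = pd.DataFrame(cols).fillna(0).astype(int).sort_index()
    if library_info is None:
        library_info = pd.DataFrame(
            {"library_id": list(libraries), "tissue": list(libraries), "replicate": 1}
        )
    return ReadSet(counts=counts, library_info=library_info,
                   n_dropped_ambiguous=dropped)


class GenomeIndex:
    """Exact k-mer index supporting all <=1-substitution placements."""

    def __init__(self, genome: dict[str, str], seed_len: int = 7):
        self.genome = {c: to_dna(s) for c, s in genome.items()}
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, int]]] = {}
        k = seed_len
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i))

    def _candidates(self, query: str):
        k = self.seed_len
        n = len(query)
        seen = set()
        for offset, seed in ((0, query[:k]), (n - k, query[n - k :])):
            for chrom, pos in self._index.get(seed, ()):  # exact seed hits
                start = pos - offset
                if start >= 0 and (chrom, start) not in seen:
                    seen.add((chrom, start))
                    yield chrom, start

    def align(self, seq: str, max_mismatch: int = 1) -> list[tuple[str, int, str, int]]:
        """All placements of ``seq`` with <= ``max_mismatch`` substitutions.

        Returns (chrom, start, strand, n_mismatch) with 0-based half-open
        starts on the forward strand.
        """
        seq = to_dna(seq)
        n = len(seq)
        if n < self.seed_len:
            return []
        hits = []
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            for chrom, start in self._candidates(query):
                ref = self.genome[chrom][start : start + n]
                if len(ref) < n:
                    continue
                d = hamming(query, ref, limit=max_mismatch)
                if d <= max_mismatch:
                    hits.append((chrom, start, strand, d))
        hits.sort()
        return hits


def align_reads(reads: ReadSet, genome: dict[str, str] | GenomeIndex) -> ReadSet:
    """Attach every <=1-mismatch genomic placement to each read."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    reads.alignments = {seq: index.align(seq) for seq in reads.sequences}
    return reads


def tpm_normalize(reads: ReadSet, params: FilterParams | None = None) -> ReadSet:
    """Compute per-library TPM: count x 1e6 / library mapped total.

    The mapped total counts aligned reads only; by default reads outside the
    retained size range are additionally excluded from the denominator so
    that length junk does not deflate TPM (switchable via
    ``params.tpm_denominator``).  Libraries with a zero mapped total are
    flagged with NaN TPM and excluded from downstream means.
    """
    params = params or FilterParams()
    aligned = reads.counts.index.map(lambda q: bool(reads.alignments.get(q)))
    in_denom = pd.Series(aligned, index=reads.counts.index)
    if params.tpm_denominator == "size_pass":
        lengths = reads.counts.index.str.len()
        in_denom &= pd.Series(
            (lengths >= params.min_len) & (lengths <= params.max_len),
            index=reads.counts.index,
        )
    totals = reads.counts[in_denom].sum(axis=0)
    if (totals == 0).any():
        zeros = list(totals.index[totals == 0])
        warnings.warn(f"libraries with zero mapped reads excluded from TPM: {zeros}")
    with np.errstate(divide="ignore", invalid="ignore"):
        reads.tpm = reads.counts * 1_000_000 / totals.replace(0, np.nan)
    reads.mapped_totals = totals
    return reads


def _matches_blacklist(seq: str, blacklist: dict[str, str], max_mismatch: int = 1) -> bool:
    n = len(seq)
    for ref in blacklist.values():
        ref = to_dna(ref)
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(ref) - n + 1):
                if hamming(strand_seq, ref[i : i + n], limit=max_mismatch) <= max_mismatch:
                    return True
    return False


def filter_reads(
    reads: ReadSet,
    blacklist: dict[str, str] | None = None,
    params: FilterParams | None = None,
) -> ReadSet:
    """Assign each read a single filter status, in fixed cascade order.

    Order: size -> unaligned -> structural -> low_abundance -> repetitive.
    A per-stage attrition table is stored on the read set.
    """
    params = params or FilterParams()
    blacklist = blacklist or {}
    if reads.tpm is None:
        raise RuntimeError("run tpm_normalize before filtering")
    status = pd.Series("pass", index=reads.counts.index, dtype=object)
    lengths = reads.counts.index.str.len()
    bad_size = (lengths < params.min_len) | (lengths > params.max_len)
    status[np.asarray(bad_size)] = "size"

    live = status == "pass"
    unaligned = pd.Series(
        [not reads.alignments.get(q) for q in reads.counts.index],
        index=reads.counts.index,
    )
    status[live & unaligned] = "unaligned"

    live = status == "pass"
    structural = pd.Series(
        [live[q] and _matches_blacklist(q, blacklist) for q in reads.counts.index],
        index=reads.counts.index,
    )
    status[live & structural] = "structural"

    live = status == "pass"
    total_tpm = reads.tpm.sum(axis=1)
    max_lib_tpm = reads.tpm.max(axis=1)
    retained = (total_tpm > params.min_total_tpm) & (max_lib_tpm > params.min_lib_tpm)
    status[live & ~retained] = "low_abundance"

    live = status == "pass"
    hits = pd.Series(
        {q: len(reads.alignments.get(q, ())) for q in reads.counts.index}
    )
    status[live & (hits > params.max_hits)] = "repetitive"

    reads.status = status
    tally = status.value_counts()
    reads.attrition = pd.DataFrame(
        {
            "stage": FILTER_ORDER + ["pass"],
            "removed": [int(tally.get(s, 0)) for s in FILTER_ORDER]
            + [int(tally.get("pass", 0))],
        }
    )
    return reads


def preprocess(
    libraries: dict[str, pd.Series],
    library_info: pd.DataFrame,
    genome: dict[str, str] | GenomeIndex,
    blacklist: dict[str, str] | None = None,
    params: FilterParams | None = None,
) -> ReadSet:
    """Full cascade: collapse -> align -> TPM -> filter."""
    reads = collapse_reads(libraries, library_info)
    align_reads(reads, genome)
    tpm_normalize(reads, params)
    filter_reads(reads, blacklist, params)
    return reads
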