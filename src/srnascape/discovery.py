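"""miRNA precursor discovery from filtered, aligned small-RNA reads.

Candidate windows are strand-specific read clusters (merge gap 200 nt,
flank 20 nt, precursors capped at 300 nt).  Each window must clear five
gates to become an accepted locus:

* precursor length <= 300 nt;
* strand bias  (sense / total reads)          >= 0.9;
* abundance bias ((mature + star + isomiRs) / sense) >= 0.75;
* mature/star duplex mismatches <= 5;
* asymmetric bulges in the duplex <= 3.

The canonical mature is the most abundant read in the window (ties broken
towards the 5'-most read); the star is the most abundant opposite-arm read
whose duplex geometry shows the standard 2-nt 3' overhang (tolerance
+-1 nt), or is inferred from the predicted structure when unsupported by
reads.  Known/novel status is decided by comparing the mature against a
reference set of annotated matures with at most two mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seqs import hamming, revcomp
from .folding import fold, pair_table
from .isomir import classify_isomir

MERGE_GAP = 200
FLANK = 20
MAX_PRECURSOR = 300
MIN_STRAND_BIAS = 0.9
MIN_ABUNDANCE_BIAS = 0.75
MAX_DUPLEX_MISMATCH = 5
MAX_ASYM_BULGES = 3


@dataclass
class Window:
    chrom: str
    start: int
    end: int
    strand: str
    # sequence -> (placement start, mismatches) for sense placements inside
    sense_reads: dict[str, tuple[int, int]] = field(default_factory=dict)
    antisense_reads: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MirnaLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    structure: str
    mature: str
    mature_start: int
    arm: str  # 5p / 3p
    star: str
    star_start: int
    star_supported: bool
    strand_bias: float
    abundance_bias: float
    duplex_mismatches: int
    asymmetric_bulges: int
    status: str = "novel"  # known / novel
    context: str = "UI"
    attributed: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def precursor_length(self) -> int:
        return self.end - self.start


def cluster_candidates(reads, max_gap: int = MERGE_GAP, flank: int = FLANK,
                       max_len: int = MAX_PRECURSOR):
    """Merge sense placements of passing reads into candidate windows.

    Returns ``(windows, n_discarded)`` where discarded windows exceeded the
    precursor cap after flank extension.  Antisense placements overlapping a
    window are attached for the strand-bias computation.
    """
    placements = []  # (chrom, strand, start, end, seq, nm)
    for seq in reads.passing():
        for chrom, start, strand, nm in reads.alignments[seq]:
            placements.append((chrom, strand, start, start + len(seq), seq, nm))
    placements.sort()

    windows: list[Window] = []
    n_discarded = 0
    current = None
    for chrom, strand, start, end, seq, nm in placements:
        if (
            current is not None
            and chrom == current.chrom
            and strand == current.strand
            and start <= current.end + max_gap
        ):
            current.end = max(current.end, end)
            current.sense_reads.setdefault(seq, (start, nm))
        else:
            if current is not None:
                windows.append(current)
            current = Window(chrom=chrom, start=start, end=end, strand=strand)
            current.sense_reads[seq] = (start, nm)
    if current is not None:
        windows.append(current)

    kept = []
    for w in windows:
        w.start = max(0, w.start - flank)
        w.end = w.end + flank
        if w.length > max_len:
            n_discarded += 1
            continue
        kept.append(w)

    # attach antisense placements overlapping each kept window
    by_loc: dict[tuple[str, str], list] = {}
    for chrom, strand, start, end, seq, nm in placements:
        by_loc.setdefault((chrom, strand), []).append((start, end, seq, nm))
    for w in kept:
        other = "-" if w.strand == "+" else "+"
        for start, end, seq, nm in by_loc.get((w.chrom, other), ()):  # small lists
            if start < w.end and end > w.start:
                w.antisense_reads.setdefault(seq, (start, nm))
    return kept, n_discarded


def strand_bias(window: Window, counts: pd.Series) -> float:
    """sense / (sense + antisense), on raw counts pooled over libraries."""
    sense = sum(counts[s] for s in window.sense_reads)
    anti = sum(counts[s] for s in window.antisense_reads)
    if sense + anti == 0:
        raise ValueError("window has no reads")
    return sense / (sense + anti)


def select_canonical(window: Window, counts: pd.Series) -> tuple[str, int]:
    """Most abundant sense read; ties broken towards the 5'-most placement."""
    best = min(
        window.sense_reads.items(),
        key=lambda kv: (-counts[kv[0]], kv[1][0], kv[0]),
    )
    return best[0], best[1][0]


def evaluate_duplex(
    mature: str,
    star: str,
    mature_iv: tuple[int, int] | None = None,
    star_iv: tuple[int, int] | None = None,
) -> tuple[bool, int, int]:
    """Score the mature/star duplex geometry.

    The two strands are aligned antiparallel by a small dynamic program
    maximising Watson-Crick/G:U pairs (ties resolved towards gap-free
    alignments).  Aligned columns that cannot pair count as mismatches;
    interior maximal gap runs — unpaired bases on one strand only — count
    as asymmetric bulges.  Terminal overhangs (the Dicer 2-nt ends) are
    not penalised.  Returns (pass, mismatches, bulges); raises if the two
    precursor intervals are supplied and overlap.

    The duplex is scored on the strand sequences directly rather than read
    off the global precursor fold: a maximum-pairing structure realises a
    duplex mismatch as two compensating single-base bulges whenever the
    shifted register gains a pair, which would systematically overcount
    bulges.
    """
    if mature_iv is not None and star_iv is not None:
        (a0, a1), (b0, b1) = sorted([mature_iv, star_iv])
        if a1 > b0:
            raise ValueError("mature and star intervals overlap")
    from ._seqs import PAIRABLE, to_dna

    a = to_dna(mature)
    b = to_dna(star)[::-1]  # antiparallel: walk the star 3' -> 5'
    n, m = len(a), len(b)
    # a bulge pair (two one-sided gaps) must cost more than one gained pair,
    # otherwise every mismatch whose shifted register pairs by chance is
    # realised as two compensating bulges
    gap = -0.6
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    move = [[0] * (m + 1) for _ in range(n + 1)]  # 0 diag, 1 up(gap in b), 2 left
    for i in range(1, n + 1):
        score[i][0] = i * gap
        move[i][0] = 1
    for j in range(1, m + 1):
        score[0][j] = j * gap
        move[0][j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            pair = 1.0 if (a[i - 1], b[j - 1]) in PAIRABLE else 0.0
            cands = (
                (score[i - 1][j - 1] + pair, 0),
                (score[i - 1][j] + gap, 1),
                (score[i][j - 1] + gap, 2),
            )
            score[i][j], move[i][j] = max(cands, key=lambda c: (c[0], -c[1]))
    # traceback into alignment columns: 'p' pair, 'x' mismatch, 'a'/'b' gap
    cols = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == 0:
            cols.append("p" if (a[i - 1], b[j - 1]) in PAIRABLE else "x")
            i, j = i - 1, j - 1
        elif mv == 1:
            cols.append("a")
            i -= 1
        else:
            cols.append("b")
            j -= 1
    cols.reverse()
    # trim terminal overhangs (leading/trailing gap-or-mismatch runs carry
    # no duplex information; Dicer products overhang by 2 nt at each end)
    lo, hi = 0, len(cols)
    while lo < hi and cols[lo] != "p":
        lo += 1
    while hi > lo and cols[hi - 1] != "p":
        hi -= 1
    interior = cols[lo:hi]
    mismatches = interior.count("x")
    bulges = 0
    prev = None
    for c in interior:
        if c in ("a", "b") and c != prev:
            bulges += 1
        prev = c if c in ("a", "b") else None
    if not interior:
        return False, len(mature), 0
    ok = mismatches <= MAX_DUPLEX_MISMATCH and bulges <= MAX_ASYM_BULGES
    return ok, mismatches, bulges


def infer_star(structure: str, mature_iv: tuple[int, int], length: int) -> tuple[int, int] | None:
    """Expected star interval from structure, with a 2-nt 3' overhang.

    For an in-register stem pairing position i with N-1-i, the star 5' end
    sits at the partner of the mature's third-to-last base; if that base is
    unpaired, nearby anchors are tried with the register shift corrected.
    """
    partners = pair_table(structure)
    m0, m1 = mature_iv
    for probe in (m1 - 3, m1 - 4, m1 - 2, m1 - 5):
        j = partners.get(probe)
        if j is not None:
            s0 = j + (probe - (m1 - 3))
            if s0 < 0:
                return None
            return s0, s0 + length
    return None


def analyze_window(
    window: Window,
    counts: pd.Series,
    genome: dict[str, str],
    locus_id: str,
    min_strand_bias: float = MIN_STRAND_BIAS,
    min_abundance_bias: float = MIN_ABUNDANCE_BIAS,
) -> MirnaLocus | None:
    """Run all gates on one candidate window; None if any gate fails."""
    sb = strand_bias(window, counts)
    if sb < min_strand_bias:
        return None
    prec = genome[window.chrom][window.start : window.end]
    if window.strand == "-":
        prec = revcomp(prec)
    if len(prec) < 50:
        return None
    structure = fold(prec)

    mature, mstart_g = select_canonical(window, counts)

    def to_prec(gpos: int, length: int) -> tuple[int, int]:
        if window.strand == "+":
            lo = gpos - window.start
        else:
            lo = window.end - (gpos + length)
        return lo, lo + length

    m_iv = to_prec(mstart_g, len(mature))
    star_iv = infer_star(structure, m_iv, len(mature))
    if star_iv is None:
        return None

    # star support: most abundant opposite-arm read starting within +-1 of
    # the structure-implied star 5' end
    star_seq, star_start_g, supported = None, None, False
    cands = []
    for seq, (gstart, nm) in window.sense_reads.items():
        iv = to_prec(gstart, len(seq))
        if abs(iv[0] - star_iv[0]) <= 1 and seq != mature:
            cands.append((seq, gstart))
    if cands:
        star_seq, star_start_g = min(
            cands, key=lambda kv: (-counts[kv[0]], kv[1], kv[0])
        )
        star_iv = to_prec(star_start_g, len(star_seq))
        supported = True
    else:
        s0, s1 = star_iv
        if s0 < 0 or s1 > len(prec):
            return None
        star_seq = prec[s0:s1]
        star_start_g = (
            window.start + s0 if window.strand == "+" else window.end - s1
        )

    lo_m, lo_s = sorted([m_iv, star_iv])
    if lo_m[1] > lo_s[0]:
        return None  # arms overlap: not a canonical hairpin layout
    ok, mism, bulges = evaluate_duplex(mature, star_seq)
    if not ok:
        return None

    # abundance bias: mature + star + isomiR-classifiable reads over sense
    sense_total = sum(counts[s] for s in window.sense_reads)
    attributed: dict[str, float] = {}
    for seq, (gstart, nm) in window.sense_reads.items():
        if seq == mature or seq == star_seq:
            attributed[seq] = float(counts[seq])
            continue
        offset5 = (
            gstart - mstart_g if window.strand == "+"
            else (mstart_g + len(mature)) - (gstart + len(seq))
        )
        rec = classify_isomir(seq, mature, prec, m_iv[0], offset5=offset5)
        if rec is not None and rec.classes:
            attributed[seq] = float(counts[seq])
    ab = sum(attributed.values()) / sense_total if sense_total else 0.0
    if ab < min_abundance_bias:
        return None

    arm = "5p" if m_iv[0] < star_iv[0] else "3p"
    return MirnaLocus(
        locus_id=locus_id,
        chrom=window.chrom,
        start=window.start,
        end=window.end,
        strand=window.strand,
        structure=structure,
        mature=mature,
        mature_start=mstart_g,
        arm=arm,
        star=star_seq,
        star_start=star_start_g,
        star_supported=supported,
        strand_bias=sb,
        abundance_bias=ab,
        duplex_mismatches=mism,
        asymmetric_bulges=bulges,
        attributed=attributed,
    )


def classify_known_novel(locus: MirnaLocus, reference_matures: dict[str, str],
                         max_mismatch: int = 2) -> str:
    """'known' iff the mature matches a reference mature with <=2 mismatches."""
    for name, ref in reference_matures.items():
        if len(ref) == len(locus.mature) and hamming(
            locus.mature, ref, limit=max_mismatch
        ) <= max_mismatch:
            locus.status = "known"
            return "known"
    locus.status = "novel"
    return "novel"


def discover_loci(
    reads,
    genome: dict[str, str],
    reference_matures: dict[str, str] | None = None,
    **gate_kwargs,
) -> tuple[list[MirnaLocus], dict]:
    """End-to-end discovery: cluster, gate, and label known/novel."""
    counts = reads.total_counts()
    windows, n_discarded = cluster_candidates(reads)
    loci = []
    for i, w in enumerate(windows):
        locus = analyze_window(w, counts, genome, f"locus{i:04d}", **gate_kwargs)
        if locus is not None:
            loci.append(locus)
    for locus in loci:
        classify_known_novel(locus, reference_matures or {})
    stats = {
        "n_windows": len(windows),
        "n_discarded_long": n_discarded,
        "n_accepted": len(loci),
    }
    return loci, stats


def loci_table(loci: list[MirnaLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": l.locus_id, "chrom": l.chrom, "start": l.start,
                "end": l.end, "strand": l.strand, "mature": l.mature,
                "mature_start": l.mature_start, "arm": l.arm, "star": l.star,
                "strand_bias": l.strand_bias, "abundance_bias": l.abundance_bias,
                "duplex_mismatches": l.duplex_mismatches,
                "asymmetric_bulges": l.asymmetric_bulges,
                "status": l.status, "context": l.context,
            }
            for l in loci
        ]
    )
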