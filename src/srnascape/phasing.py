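"""Phased-siRNA (PHAS) locus detection.

Small RNAs of exactly the cycle length (21 or 24 nt) are scanned in sliding
windows of ten cycles.  Within a window anchored at an occupied position,
distinct read 5' starts are tallied and those falling on the anchor's
register (start = anchor mod cycle) are "phased".  Significance is the
hypergeometric tail probability of drawing at least the observed number of
phased positions when the occupied positions were placed at random among
the window's positions; windows need at least three distinct phased
positions (minDepth) and P < 1e-5 to be accepted, and overlapping accepted
windows are merged into loci carrying the minimum window p-value.

Trigger miRNAs are assigned by a complementarity scan of the locus ends
(at most 4 mispairs, G:U counted half), and loci that both overlap a
retrotransposon and are triggered by 22-nt miR170/miR171a are excluded:
such loci are epigenetically activated siRNA sources, not canonical
phasiRNA producers.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from ._seqs import WOBBLE, hamming, revcomp, to_dna

WINDOW_CYCLES = 10
MIN_DEPTH = 3  # distinct phased positions
MAX_P = 1e-5
ANTISENSE_OFFSET = 2  # Dicer duplex 2-nt 3' overhang
TRIGGER_MAX_MISPAIR = 4.0
EXCLUDED_TRIGGERS = ("miR170", "miR171a")
EXCLUDED_TRIGGER_LEN = 22


@dataclass
class PhasLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    cycle: int
    n_positions: int
    occupied_positions: int
    phased_positions: int
    p_value: float
    trigger: str | None = None
    trigger_length: int | None = None
    trigger_site: int | None = None
    excluded: bool = False
    exclusion_reason: str | None = None
    phasirnas: list[str] | None = None


def phasing_pvalue(n_positions: int, phase_slots: int, occupied: int, phased: int) -> float:
    """Hypergeometric upper-tail probability of >= ``phased`` register hits.

    ``n_positions`` positions in the window, ``phase_slots`` of them on the
    register, ``occupied`` distinct read starts, ``phased`` of which hit
    the register.
    """
    if not (0 <= phased <= min(occupied, phase_slots) and occupied <= n_positions
            and phase_slots <= n_positions):
        raise ValueError("inconsistent phasing counts")
    return float(hypergeom.sf(phased - 1, n_positions, phase_slots, occupied))


def effective_positions(
    placements: list[tuple[str, int, str]], cycle: int
) -> dict[str, set[int]]:
    """Distinct 5'-start positions per chromosome, strands merged.

    Antisense reads are shifted by the 2-nt duplex offset so that sense and
    antisense products of one register coincide.
    """
    by_chrom: dict[str, set[int]] = {}
    for chrom, start, strand in placements:
        pos = start if strand == "+" else start + ANTISENSE_OFFSET
        by_chrom.setdefault(chrom, set()).add(pos)
    return by_chrom


def scan_phase_windows(
    placements: list[tuple[str, int, str]],
    cycle: int,
    window_cycles: int = WINDOW_CYCLES,
    min_depth: int = MIN_DEPTH,
) -> list[tuple[str, int, int, int, int, float]]:
    """Slide cycle-register windows over read placements.

    ``placements`` are (chrom, start, strand) of reads of exactly ``cycle``
    nt.  Every occupied position anchors one window of ``window_cycles``
    cycles.  Returns (chrom, anchor, occupied, phased, n_positions, p) for
    windows meeting ``min_depth`` distinct phased positions.
    """
    span = window_cycles * cycle
    results = []
    for chrom, positions in sorted(effective_positions(placements, cycle).items()):
        ordered = sorted(positions)
        for anchor in ordered:
            in_window = [p for p in ordered if anchor <= p < anchor + span]
            phased = sum(1 for p in in_window if (p - anchor) % cycle == 0)
            if phased < min_depth:
                continue
            p = phasing_pvalue(span, window_cycles, len(in_window), phased)
            results.append((chrom, anchor, len(in_window), phased, span, p))
    return results


def detect_phas_loci(
    placements: list[tuple[str, int, str]],
    cycle: int,
    max_p: float = MAX_P,
    window_cycles: int = WINDOW_CYCLES,
    min_depth: int = MIN_DEPTH,
    id_prefix: str = "phas",
) -> list[PhasLocus]:
    """Accepted, merged PHAS loci for one cycle length."""
    windows = scan_phase_windows(placements, cycle, window_cycles, min_depth)
    accepted = [w for w in windows if w[5] < max_p]
    accepted.sort(key=lambda w: (w[0], w[1]))
    loci: list[PhasLocus] = []
    span = window_cycles * cycle
    for chrom, anchor, occ, phased, n_pos, p in accepted:
        if loci and loci[-1].chrom == chrom and anchor <= loci[-1].end:
            cur = loci[-1]
            cur.end = max(cur.end, anchor + span)
            if p < cur.p_value:
                cur.p_value = p
                cur.occupied_positions = occ
                cur.phased_positions = phased
        else:
            loci.append(
                PhasLocus(
                    locus_id=f"{id_prefix}{cycle}_{len(loci):03d}",
                    chrom=chrom,
                    start=anchor,
                    end=anchor + span,
                    cycle=cycle,
                    n_positions=n_pos,
                    occupied_positions=occ,
                    phased_positions=phased,
                    p_value=p,
                )
            )
    return loci


def _mispair_score(mirna: str, site: str) -> float:
    """Mispair score of a miRNA against a genomic target site.

    The miRNA pairs antiparallel to the site: base k of the miRNA against
    base L-1-k of the site.  Watson-Crick scores 0, G:U wobble 0.5, any
    other combination 1.
    """
    m = to_dna(mirna)
    s = to_dna(site)
    rc = revcomp(m)  # rc[i] is the WC partner expected at site position i
    score = 0.0
    for i, (expected, actual) in enumerate(zip(rc, s)):
        if actual == expected:
            continue
        mb = m[len(m) - 1 - i]
        score += 0.5 if (mb, actual) in WOBBLE else 1.0
    return score


def assign_trigger(
    locus: PhasLocus,
    mirnas: dict[str, str],
    genome: dict[str, str],
    max_mispair: float = TRIGGER_MAX_MISPAIR,
) -> tuple[str, int, int] | None:
    """Best complementary miRNA site within +-2 cycles of the locus ends.

    Returns (miRNA id, miRNA length, site start) or None.  Lower mispair
    score wins; ties go to the 5'-most site.
    """
    chrom = genome[locus.chrom]
    margin = 2 * locus.cycle
    regions = [
        (max(0, locus.start - margin), locus.start + margin),
        (max(0, locus.end - margin), locus.end + margin),
    ]
    best = None  # (score, site_start, name, length)
    for name, mat in sorted(mirnas.items()):
        L = len(mat)
        for lo, hi in regions:
            for s in range(lo, min(hi, len(chrom) - L + 1)):
                site = chrom[s : s + L]
                score = _mispair_score(mat, site)
                if score <= max_mispair:
                    key = (score, s, name)
                    if best is None or key < (best[0], best[1], best[2]):
                        best = (score, s, name, L)
    if best is None:
        return None
    locus.trigger = best[2]
    locus.trigger_length = best[3]
    locus.trigger_site = best[1]
    return best[2], best[3], best[1]


def apply_exclusion(
    locus: PhasLocus,
    te_intervals: list[tuple[str, int, int, str]],
) -> bool:
    """Flag easiRNA-like loci: retrotransposon overlap AND a 22-nt
    miR170/miR171a trigger.  Both conditions are required."""
    retro = any(
        chrom == locus.chrom and s < locus.end and e > locus.start
        and cls.lower().startswith("retro")
        for chrom, s, e, cls in te_intervals
    )
    trig = locus.trigger or ""
    trig_hit = (
        any(trig.startswith(t) or t in trig for t in EXCLUDED_TRIGGERS)
        and locus.trigger_length == EXCLUDED_TRIGGER_LEN
    )
    locus.excluded = bool(retro and trig_hit)
    locus.exclusion_reason = "retrotransposon+miR170/171a" if locus.excluded else None
    return locus.excluded


def phas_conservation(
    locus_a: PhasLocus, locus_b: PhasLocus, max_mismatch: int = 2, min_pairs: int = 2
) -> bool:
    """Conserved iff same trigger and >=2 cross-locus phasiRNA pairs match
    with at most two mismatches."""
    if locus_a.trigger is None or locus_a.trigger != locus_b.trigger:
        return False
    if not locus_a.phasirnas or not locus_b.phasirnas:
        return False
    n_pairs = 0
    used_b: set[int] = set()
    for a in locus_a.phasirnas:
        for bi, b in enumerate(locus_b.phasirnas):
            if bi in used_b or len(a) != len(b):
                continue
            if hamming(a, b, limit=max_mismatch) <= max_mismatch:
                used_b.add(bi)
                n_pairs += 1
                break
    return n_pairs >= min_pairs
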