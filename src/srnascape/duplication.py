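"""Genomic context, duplication status and singleton/duplicate ratio tests.

Loci are placed into one of three genomic contexts with fixed precedence —
protein-coding gene (PCG) over transposable element (TE) over unclassified
intergenic (UI) — by simple interval overlap (one shared base suffices).

Two loci form a conserved pair when their mature sequences differ by at
most two substitutions.  A conserved pair on one chromosome separated by
less than 200 kb is a tandem duplication; a pair whose members fall in the
two intervals of one synteny block is a syntenic duplication.  Everything
else is a singleton.

The ratio test compares a category's singleton/duplicate split against a
reference (genome-wide) split with a 2x2 Pearson chi-square, one degree of
freedom, no continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2

from ._seqs import hamming

TANDEM_MAX_DISTANCE = 200_000
CONSERVED_MAX_MISMATCH = 2


@dataclass
class SyntenyBlock:
    chrom_a: str
    start_a: int  # 0-based half-open internally
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    block_id: str


@dataclass
class DuplicationCall:
    locus_id: str
    context: str = "UI"
    status: str = "singleton"  # singleton / duplicate
    mechanism: str = "none"  # tandem / syntenic / none
    partners: list[str] = field(default_factory=list)
    pair_distance: int | None = None


@dataclass
class RatioTest:
    category: str
    singletons: int
    duplicates: int
    ratio: float
    chi2: float
    p: float


def read_synteny(path) -> list[SyntenyBlock]:
    """Parse a synteny-block TSV (1-based inclusive coordinates on file)."""
    blocks = []
    with open(path) as fh:
        header = fh.readline()
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"malformed synteny file at line {ln}: {line!r}")
            try:
                ca, sa, ea, cb, sb, eb, bid = (
                    parts[0], int(parts[1]), int(parts[2]),
                    parts[3], int(parts[4]), int(parts[5]), parts[6],
                )
            except ValueError as exc:
                raise ValueError(f"malformed synteny file at line {ln}: {exc}") from exc
            if ea < sa or eb < sb:
                raise ValueError(f"degenerate block interval at line {ln}")
            blocks.append(SyntenyBlock(ca, sa - 1, ea, cb, sb - 1, eb, bid))
    return blocks


def genomic_context(
    chrom: str,
    start: int,
    end: int,
    pcg_trees: dict[str, IntervalTree],
    te_trees: dict[str, IntervalTree],
) -> str:
    """Context with precedence PCG > TE > UI; overlap of >=1 base counts."""
    if chrom in pcg_trees and pcg_trees[chrom].overlap(start, end):
        return "PCG"
    if chrom in te_trees and te_trees[chrom].overlap(start, end):
        return "TE"
    return "UI"


def build_trees(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        chrom, s, e = iv[0], iv[1], iv[2]
        trees.setdefault(chrom, IntervalTree()).addi(max(0, s), e)
    return trees


def find_conserved_pairs(
    loci: pd.DataFrame, max_mismatch: int = CONSERVED_MAX_MISMATCH
) -> list[tuple[str, str]]:
    """All locus pairs whose matures match with <=2 substitutions.

    ``loci`` needs columns locus_id and mature.  Matures of unequal length
    do not pair (substitutions only, no indels).
    """
    ids = loci["locus_id"].tolist()
    matures = loci["mature"].tolist()
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = matures[i], matures[j]
            if len(a) != len(b):
                continue
            if hamming(a, b, limit=max_mismatch) <= max_mismatch:
                pairs.append((ids[i], ids[j]))
    return pairs


def classify_duplication(
    loci: pd.DataFrame,
    pairs: list[tuple[str, str]],
    blocks: list[SyntenyBlock],
    pcg_intervals=(),
    te_intervals=(),
    tandem_max: int = TANDEM_MAX_DISTANCE,
) -> dict[str, DuplicationCall]:
    """One DuplicationCall per locus.

    A conserved pair is tandem when same-chromosome with an end-to-end gap
    below ``tandem_max``; syntenic when its members fall in the two
    intervals of one block.  A locus in any qualifying pair is a duplicate;
    tandem takes precedence over syntenic for the mechanism label.
    ``loci`` needs columns locus_id / chrom / start / end.
    """
    pcg_trees = build_trees(pcg_intervals)
    te_trees = build_trees(te_intervals)
    by_id = loci.set_index("locus_id")
    calls = {
        lid: DuplicationCall(
            locus_id=lid,
            context=genomic_context(
                row["chrom"], int(row["start"]), int(row["end"]), pcg_trees, te_trees
            ),
        )
        for lid, row in by_id.iterrows()
    }

    def gap(a, b) -> int | None:
        if a["chrom"] != b["chrom"]:
            return None
        return max(int(b["start"]) - int(a["end"]), int(a["start"]) - int(b["end"]), 0)

    def in_block(a, b) -> bool:
        for blk in blocks:
            fwd = (
                a["chrom"] == blk.chrom_a and blk.start_a < a["end"] and a["start"] < blk.end_a
                and b["chrom"] == blk.chrom_b and blk.start_b < b["end"] and b["start"] < blk.end_b
            )
            rev = (
                b["chrom"] == blk.chrom_a and blk.start_a < b["end"] and b["start"] < blk.end_a
                and a["chrom"] == blk.chrom_b and blk.start_b < a["end"] and a["start"] < blk.end_b
            )
            if fwd or rev:
                return True
        return False

    for lid_a, lid_b in pairs:
        a, b = by_id.loc[lid_a], by_id.loc[lid_b]
        d = gap(a, b)
        tandem = d is not None and d < tandem_max
        syntenic = in_block(a, b)
        if not (tandem or syntenic):
            continue
        mech = "tandem" if tandem else "syntenic"
        for lid, other in ((lid_a, lid_b), (lid_b, lid_a)):
            call = calls[lid]
            call.status = "duplicate"
            if call.mechanism != "tandem":
                call.mechanism = mech
            call.partners.append(other)
            if tandem:
                call.pair_distance = d
    return calls


def ratio_chisq(
    category_singletons: int,
    category_duplicates: int,
    reference_singletons: int,
    reference_duplicates: int,
    category: str = "",
) -> RatioTest:
    """Pearson chi-square on [[cs, cd], [rs, rd]], df=1, no correction."""
    obs = [
        [category_singletons, category_duplicates],
        [reference_singletons, reference_duplicates],
    ]
    if any(v < 0 for row in obs for v in row):
        raise ValueError("counts must be nonnegative")
    n = sum(sum(row) for row in obs)
    row_sums = [sum(row) for row in obs]
    col_sums = [obs[0][0] + obs[1][0], obs[0][1] + obs[1][1]]
    if n == 0 or 0 in row_sums or 0 in col_sums:
        raise ValueError("chi-square undefined: a margin (expected cell) is zero")
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = row_sums[i] * col_sums[j] / n
            stat += (obs[i][j] - e) ** 2 / e
    p = float(chi2.sf(stat, df=1))
    ratio = (
        category_singletons / category_duplicates
        if category_duplicates
        else float("inf")
    )
    return RatioTest(
        category=category,
        singletons=category_singletons,
        duplicates=category_duplicates,
        ratio=ratio,
        chi2=stat,
        p=p,
    )
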