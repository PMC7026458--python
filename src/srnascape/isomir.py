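"""Classification of mature-miRNA sequence variants (isomiRs).

Reads attributed to a locus are compared against the canonical mature,
anchored through their genomic placement, and assigned to one or more of
seven classes: 5' trimming, 5' addition, 3' trimming, 3' addition,
non-templated 3' addition, seed SNP (substitution at mature positions 2-8,
5'-anchored) and tail SNP (substitution elsewhere).  End shifts beyond
+-4 nt mark a read as a distinct small RNA rather than an isomiR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seqs import to_rna

ISOMIR_CLASSES = [
    "5p_trimming", "5p_addition", "3p_trimming",
    "3p_addition", "3p_nt_addition", "seed_snp", "tail_snp",
]

SEED_RANGE = (2, 8)  # 1-based, inclusive, 5'-anchored
MAX_END_OFFSET = 4
MAX_SUBSTITUTIONS = 2


@dataclass
class IsomiRRecord:
    read: str
    locus_id: str | None
    classes: frozenset[str]
    offset5: int  # + = trimmed, - = extended, relative to the canonical 5' end
    offset3: int  # + = extended, - = trimmed, relative to the canonical 3' end
    substitutions: list[int] = field(default_factory=list)  # 1-based mature positions

    @property
    def is_canonical(self) -> bool:
        return not self.classes and self.offset5 == 0 and self.offset3 == 0


def _best_anchor(read: str, template: str) -> int | None:
    """Placement of ``read`` in ``template`` minimising substitutions.

    Ties prefer the placement closest to the canonical register (smallest
    absolute shift is resolved by the caller passing a centred template).
    """
    n, m = len(read), len(template)
    best, best_cost = None, None
    for s in range(0, m - n + 1):
        cost = sum(1 for a, b in zip(read, template[s : s + n]) if a != b)
        if best_cost is None or cost < best_cost:
            best, best_cost = s, cost
    return best


def classify_isomir(
    read: str,
    canonical: str,
    template: str,
    canonical_pos: int,
    locus_id: str | None = None,
    offset5: int | None = None,
    seed_range: tuple[int, int] = SEED_RANGE,
    max_end_offset: int = MAX_END_OFFSET,
) -> IsomiRRecord | None:
    """Classify one read against the canonical mature of its locus.

    ``template`` is the genomic (precursor) sequence in the sense
    orientation of the locus and ``canonical_pos`` the 0-based start of the
    canonical within it.  ``offset5`` — the read's placement shift relative
    to the canonical 5' end — is normally taken from the genomic alignment;
    when absent it is inferred by a minimal-substitution anchoring.
    Classification is a pure function of these arguments.  Returns None for
    reads that are not attributable (end shift beyond ``max_end_offset`` or
    more than two internal substitutions).
    """
    if offset5 is None:
        s = _best_anchor(read, template)
        if s is None:
            return None
        offset5 = s - canonical_pos
    offset3 = offset5 + len(read) - len(canonical)
    if abs(offset5) > max_end_offset or abs(offset3) > max_end_offset:
        return None
    start = canonical_pos + offset5
    if start < 0 or start + len(read) > len(template):
        return None

    classes: set[str] = set()
    if offset5 > 0:
        classes.add("5p_trimming")
    elif offset5 < 0:
        classes.add("5p_addition")
    if offset3 < 0:
        classes.add("3p_trimming")
    elif offset3 > 0:
        ext = read[len(read) - offset3 :]
        tmpl = template[canonical_pos + len(canonical) : canonical_pos + len(canonical) + offset3]
        if ext == tmpl:
            classes.add("3p_addition")
        else:
            classes.add("3p_nt_addition")

    # internal substitutions are relative to the CANONICAL sequence (which
    # need not equal the template at every position, e.g. at a duplicated
    # locus whose canonical carries a variant base), over the overlap of the
    # read with the canonical span; 3'-extension bases are classified above
    # and are never SNPs
    subs: list[int] = []
    lo_seed, hi_seed = seed_range
    for c in range(max(0, offset5), min(len(canonical), offset5 + len(read))):
        if read[c - offset5] != canonical[c]:
            subs.append(c + 1)  # 1-based mature coordinate
    if len(subs) > MAX_SUBSTITUTIONS:
        return None
    for rel in subs:
        if lo_seed <= rel <= hi_seed:
            classes.add("seed_snp")
        else:
            classes.add("tail_snp")

    return IsomiRRecord(
        read=read,
        locus_id=locus_id,
        classes=frozenset(classes),
        offset5=offset5,
        offset3=offset3,
        substitutions=subs,
    )


def end_composition(
    records: list[IsomiRRecord], weights: dict[str, float] | None = None
) -> pd.DataFrame:
    """Terminal-nucleotide frequencies per class and end.

    Returns a tidy frame with columns class / end (5p, 3p) / A / C / G / U,
    each row's frequencies summing to 1.  Records carrying several classes
    contribute to each.
    """
    if not records:
        return pd.DataFrame(columns=["class", "end", "A", "C", "G", "U"])
    tallies: dict[tuple[str, str], dict[str, float]] = {}
    for rec in records:
        w = 1.0 if weights is None else weights.get(rec.read, 0.0)
        rna = to_rna(rec.read)
        for cls in rec.classes:
            for end, base in (("5p", rna[0]), ("3p", rna[-1])):
                d = tallies.setdefault((cls, end), {b: 0.0 for b in "ACGU"})
                d[base] += w
    rows = []
    for (cls, end), d in sorted(tallies.items()):
        total = sum(d.values())
        row = {"class": cls, "end": end}
        row.update({b: (d[b] / total if total else 0.0) for b in "ACGU"})
        rows.append(row)
    return pd.DataFrame(rows)


def isomir_context_correlation(
    isomir_abundance: pd.DataFrame,
    locus_abundance: pd.DataFrame,
    contexts: pd.Series,
) -> pd.Series:
    """Per-context Pearson correlation of isomiR vs locus abundance.

    Both frames are loci x samples; within each genomic context (PCG, TE,
    UI) abundances are summed over loci and the two per-sample vectors are
    correlated.  Requires at least three samples; contexts whose vectors
    are constant yield NaN.
    """
    if isomir_abundance.shape[1] < 3:
        raise ValueError("need at least three samples for a correlation")
    out = {}
    for ctx in sorted(contexts.unique()):
        loci = contexts.index[contexts == ctx]
        a = isomir_abundance.loc[isomir_abundance.index.intersection(loci)].sum(axis=0)
        b = locus_abundance.loc[locus_abundance.index.intersection(loci)].sum(axis=0)
        if a.std() == 0 or b.std() == 0:
            out[ctx] = float("nan")
        else:
            out[ctx] = float(np.corrcoef(a, b)[0, 1])
    return pd.Series(out, name="pearson_r")
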