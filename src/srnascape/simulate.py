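"""Synthetic multi-tissue small-RNA study with known ground truth.

Builds a toy genome with planted miRNA hairpin loci (inside protein-coding
genes, transposons, or intergenic space), phased-siRNA (PHAS) loci with 21-
or 24-nt registers, tandem and syntenic duplicate locus pairs, embedded
structural-RNA sequences, and multi-library read tables across a panel of
tissues.  Every planted feature is recorded in a ground-truth table so that
locus discovery, isomiR classification, specificity calling, phasing
detection and duplication analysis can all be validated against what was
actually put in.

The generator is fully deterministic: one root seed, with per-library child
streams derived by fixed arithmetic so that adding libraries does not
perturb earlier ones.

What is emulated: hairpin-derived mature/star/isomiR read clouds with
tissue-biased abundance, exact phasing registers, contaminating structural
and degradation fragments.  What is NOT emulated: sequencing error beyond
the planted substitutions, adapter read-through, or quality scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seqs import revcomp
from .isomir import ISOMIR_CLASSES

TISSUES_14 = [
    "seedling", "leaf", "ear", "silk", "tassel", "anther", "pollen",
    "seed", "embryo", "endosperm", "stalk", "sam", "meiocyte", "root",
]

# tissues in which PHAS loci are expressed (reproductive panel)
PHAS_TISSUES = [("anther", "meiocyte"), ("ear", "tassel")]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass
class SimConfig:
    """Study design of the synthetic experiment.

    Defaults describe the reference conditions: a 14-tissue panel with two
    libraries per tissue, 100 planted miRNA loci of which 20 are one-hot
    tissue-specific, ten 21-nt and ten 24-nt PHAS loci, five tandem and five
    syntenic duplicate pairs, 10% contaminating reads and a per-class isomiR
    rate of 2%.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 300_000
    n_tissues: int = 14
    libraries_per_tissue: int = 2
    n_mirna_loci: int = 100
    n_tissue_specific: int = 20
    n_phas21: int = 10
    n_phas24: int = 10
    n_tandem_pairs: int = 5
    n_syntenic_pairs: int = 5
    contamination_fraction: float = 0.10
    isomir_rate: float = 0.02
    depth_per_library: int = 100_000
    # geometry of planted hairpins
    arm_length: int = 60
    loop_length: int = 15
    mature_length: int = 21
    phas_cycles: int = 10
    # star-arm positions (relative to the mature 5' end) carrying injected
    # duplex mismatches; spread so no 21-nt antisense window is within one
    # substitution of perfect self-complementarity
    duplex_mismatch_offsets: tuple[int, ...] = (3, 10, 17)
    # abundance model
    mature_weight: float = 1400.0  # per-locus weight, split across tissues
    star_fraction: float = 0.10
    phasirna_weight: float = 100.0  # per phased read, per expressing tissue
    dirichlet_concentration: float = 5.0

    def validate(self) -> None:
        counts = [
            self.n_chromosomes, self.chrom_length, self.n_tissues,
            self.libraries_per_tissue, self.n_mirna_loci,
            self.n_tissue_specific, self.n_phas21, self.n_phas24,
            self.n_tandem_pairs, self.n_syntenic_pairs, self.depth_per_library,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be nonnegative")
        if self.n_tissue_specific > self.n_mirna_loci:
            raise ValueError("n_tissue_specific cannot exceed n_mirna_loci")
        if 2 * (self.n_tandem_pairs + self.n_syntenic_pairs) > max(
            0, self.n_mirna_loci - self.n_tissue_specific
        ):
            raise ValueError("not enough broad loci to host the requested duplicate pairs")
        if not 0 <= self.contamination_fraction <= 1:
            raise ValueError("contamination_fraction must lie in [0, 1]")
        if not 0 <= self.isomir_rate <= 1 / len(ISOMIR_CLASSES):
            raise ValueError("isomir_rate per class must lie in [0, 1/7]")
        if self.n_chromosomes == 0 and self.n_mirna_loci > 0:
            raise ValueError("cannot place loci on a genome with zero chromosomes")

    @property
    def tissues(self) -> list[str]:
        base = TISSUES_14
        if self.n_tissues <= len(base):
            return base[: self.n_tissues]
        return base + [f"tissue{i}" for i in range(len(base), self.n_tissues)]

    @property
    def precursor_length(self) -> int:
        return 2 * self.arm_length + self.loop_length


@dataclass
class MirnaTruth:
    locus_id: str
    chrom: str
    start: int  # 0-based half-open precursor interval
    end: int
    strand: str
    mature: str
    mature_start: int
    star: str
    star_start: int
    context: str  # PCG / TE / UI
    profile: np.ndarray = field(repr=False)
    specific: bool = False
    target_tissue: str | None = None
    dup_label: str = "singleton"  # singleton / tandem / syntenic
    partner_id: str | None = None


@dataclass
class PhasTruth:
    locus_id: str
    chrom: str
    start: int
    end: int
    cycle: int
    phased_positions: list[int]
    phasirnas: list[str]
    trigger: str
    trigger_seq: str
    trigger_site_start: int
    tissues: tuple[str, ...]


@dataclass
class GroundTruth:
    mirna: list[MirnaTruth]
    phas: list[PhasTruth]
    pcg_intervals: list[tuple[str, int, int]]
    te_intervals: list[tuple[str, int, int, str]]  # last field: TE class
    synteny_blocks: list[tuple[str, int, int, str, int, int, str]]
    blacklist: dict[str, str]
    triggers: dict[str, str]

    def mirna_by_id(self) -> dict[str, MirnaTruth]:
        return {m.locus_id: m for m in self.mirna}


@dataclass
class SyntheticGenome:
    config: SimConfig
    genome: dict[str, str]
    truth: GroundTruth


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, pos: int) -> str:
    alt = [b for b in "ACGT" if b != seq[pos]]
    return seq[:pos] + alt[rng.integers(0, 3)] + seq[pos + 1 :]


class _SlotAllocator:
    """Hands out evenly spaced, non-overlapping placement slots per chromosome."""

    def __init__(self, config: SimConfig, slot_size: int = 2200, margin: int = 5000):
        self.config = config
        self.slot_size = slot_size
        self.margin = margin
        self.next_slot = [0] * config.n_chromosomes
        self.capacity = max(0, (config.chrom_length - 2 * margin) // slot_size)

    def take(self, chrom_idx: int) -> int:
        slot = self.next_slot[chrom_idx]
        if slot >= self.capacity:
            short = slot - self.capacity + 1
            raise ValueError(
                f"chromosome {chrom_idx} too short: {short} more slot(s) of "
                f"{self.slot_size} bp needed to host the requested loci"
            )
        self.next_slot[chrom_idx] += 1
        return self.margin + slot * self.slot_size


def _build_hairpin(
    rng: np.random.Generator, config: SimConfig
) -> tuple[str, int, str, int, str]:
    """Return (precursor, mature_offset, mature, star_offset, star).

    The precursor is an inverted repeat around a loop.  Real precursors are
    not perfectly self-complementary, and that matters: a perfect stem would
    let every read align antisense onto the opposite arm, which no genuine
    hairpin read does.  Three substitutions are therefore injected into the
    star-side arm, opposite fixed mature positions, spread so that any
    mature-sized antisense window across the duplex carries at least two of
    them (killing spurious one-mismatch antisense self-alignments) while
    the mature/star duplex stays within the acceptance geometry
    (mismatches <= 5, asymmetric bulges <= 3).  The star keeps the standard
    2-nt 3' overhang.
    """
    k, t, lm = config.arm_length, config.loop_length, config.mature_length
    arm = _random_seq(rng, k)
    a = int(rng.integers(15, k - lm - 4))  # mature offset inside the 5' arm
    # fix the templated base just 3' of the mature to C so that a planted
    # non-templated 3' addition (A) is never accidentally templated
    arm = arm[: a + lm] + "C" + arm[a + lm + 1 :]
    precursor = arm + _random_seq(rng, t) + revcomp(arm)
    n = len(precursor)
    mature = precursor[a : a + lm]
    star_start = n - a - lm + 2  # pairs mature[2:] with a 2-nt 3' overhang
    for off in config.duplex_mismatch_offsets:
        precursor = _mutate(rng, precursor, n - 1 - (a + off))
    star = precursor[star_start : star_start + lm]
    return precursor, a, mature, star_start, star


def generate_genome(config: SimConfig) -> SyntheticGenome:
    """Build the genome, annotations and ground truth for ``config``."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chroms = {c: list(_random_seq(rng, config.chrom_length)) for c in chrom_names}
    alloc = _SlotAllocator(config)
    tissues = config.tissues

    mirna: list[MirnaTruth] = []
    pcg_iv: list[tuple[str, int, int]] = []
    te_iv: list[tuple[str, int, int, str]] = []
    blocks: list[tuple[str, int, int, str, int, int, str]] = []

    n = config.n_mirna_loci
    specific_ids = set(range(config.n_tissue_specific))
    tandem_members: dict[int, int] = {}
    syntenic_members: dict[int, int] = {}
    base = config.n_tissue_specific
    for p in range(config.n_tandem_pairs):
        i, j = base + 2 * p, base + 2 * p + 1
        tandem_members[i], tandem_members[j] = j, i
    base += 2 * config.n_tandem_pairs
    for p in range(config.n_syntenic_pairs):
        i, j = base + 2 * p, base + 2 * p + 1
        syntenic_members[i], syntenic_members[j] = j, i

    contexts = ["PCG", "TE", "UI"]
    te_classes = ["retrotransposon", "DNA"]

    # first pass: build hairpins and decide placement chromosome
    hairpins = []
    for i in range(n):
        if i in tandem_members and tandem_members[i] < i:
            # tandem partner: copy the earlier hairpin, 1 substitution in the mature
            src = hairpins[tandem_members[i]]
            prec, a, mat, s0, star = src
            pos = a + 5
            prec = _mutate(rng, prec, pos)
            mat = prec[a : a + config.mature_length]
            hairpins.append((prec, a, mat, s0, prec[s0 : s0 + config.mature_length]))
        elif i in syntenic_members and syntenic_members[i] < i:
            src = hairpins[syntenic_members[i]]
            prec, a, mat, s0, star = src
            prec = _mutate(rng, prec, a + 11)
            mat = prec[a : a + config.mature_length]
            hairpins.append((prec, a, mat, s0, prec[s0 : s0 + config.mature_length]))
        else:
            hairpins.append(_build_hairpin(rng, config))

    for i in range(n):
        prec, a, mat, s0, star = hairpins[i]
        if i in tandem_members:
            chrom_idx = 0
        elif i in syntenic_members:
            chrom_idx = 0 if syntenic_members[i] > i else min(1, config.n_chromosomes - 1)
        else:
            chrom_idx = i % config.n_chromosomes
        chrom = chrom_names[chrom_idx]
        start = alloc.take(chrom_idx)
        end = start + len(prec)
        chroms[chrom][start:end] = list(prec)
        context = contexts[i % 3]
        if context == "PCG":
            pcg_iv.append((chrom, start - 300, end + 300))
        elif context == "TE":
            te_iv.append((chrom, start - 100, end + 100, te_classes[i % 2]))
        dup_label = "tandem" if i in tandem_members else (
            "syntenic" if i in syntenic_members else "singleton"
        )
        partner = tandem_members.get(i, syntenic_members.get(i))
        truth = MirnaTruth(
            locus_id=f"mir{i:04d}",
            chrom=chrom,
            start=start,
            end=end,
            strand="+",
            mature=mat,
            mature_start=start + a,
            star=star,
            star_start=start + s0,
            context=context,
            profile=np.zeros(len(tissues)),
            dup_label=dup_label,
            partner_id=f"mir{partner:04d}" if partner is not None else None,
        )
        mirna.append(truth)

    # synteny blocks around the syntenic pairs
    for bi, (i, j) in enumerate(sorted((i, j) for i, j in syntenic_members.items() if i < j)):
        a_, b_ = mirna[i], mirna[j]
        blocks.append(
            (a_.chrom, a_.start - 500, a_.end + 500,
             b_.chrom, b_.start - 500, b_.end + 500, f"block{bi:02d}")
        )

    # expression profiles
    for i, m in enumerate(mirna):
        if i in specific_ids:
            t = i % len(tissues)
            profile = np.zeros(len(tissues))
            profile[t] = 1.0
            m.specific = True
            m.target_tissue = tissues[t]
            m.profile = profile
        elif m.partner_id is not None and int(m.partner_id[3:]) < i:
            m.profile = mirna[int(m.partner_id[3:])].profile  # duplicates share profile
        else:
            m.profile = rng.dirichlet(
                np.full(len(tissues), config.dirichlet_concentration)
            )

    # triggers and PHAS loci
    triggers = {
        "miR2118": _random_seq(rng, 22),
        "miR2275": _random_seq(rng, 22),
    }
    phas: list[PhasTruth] = []
    phas_spec = [(21, config.n_phas21, "miR2118"), (24, config.n_phas24, "miR2275")]
    # PHAS loci express in reproductive tissue pairs when present; small
    # panels fall back to the last tissues of the configured list
    phas_panels = [p for p in PHAS_TISSUES if all(t in tissues for t in p)]
    if not phas_panels and tissues:
        phas_panels = [tuple(tissues[-2:])]
    pi = 0
    for cycle, count, trig in phas_spec:
        for _ in range(count):
            chrom_idx = pi % config.n_chromosomes
            chrom = chrom_names[chrom_idx]
            site_len = len(triggers[trig])
            body = config.phas_cycles * cycle
            # slot holds the trigger site followed by the phased body
            start = alloc.take(chrom_idx)
            seq = revcomp(triggers[trig]) + _random_seq(rng, body)
            chroms[chrom][start : start + len(seq)] = list(seq)
            locus_start = start + site_len
            positions = [locus_start + k * cycle for k in range(config.phas_cycles)]
            phasirnas = [
                "".join(chroms[chrom][p : p + cycle]) for p in positions
            ]
            phas.append(
                PhasTruth(
                    locus_id=f"phas{pi:03d}",
                    chrom=chrom,
                    start=locus_start,
                    end=locus_start + body,
                    cycle=cycle,
                    phased_positions=positions,
                    phasirnas=phasirnas,
                    trigger=trig,
                    trigger_seq=triggers[trig],
                    trigger_site_start=start,
                    tissues=phas_panels[pi % len(phas_panels)],
                )
            )
            pi += 1

    # embedded structural RNAs (the blacklist)
    blacklist: dict[str, str] = {}
    for si in range(8):
        chrom_idx = si % config.n_chromosomes
        chrom = chrom_names[chrom_idx]
        start = alloc.take(chrom_idx)
        seq = _random_seq(rng, 80)
        chroms[chrom][start : start + 80] = list(seq)
        blacklist[f"structural{si}"] = seq

    genome = {c: "".join(s) for c, s in chroms.items()}
    truth = GroundTruth(
        mirna=mirna,
        phas=phas,
        pcg_intervals=pcg_iv,
        te_intervals=te_iv,
        synteny_blocks=blocks,
        blacklist=blacklist,
        triggers=triggers,
    )
    return SyntheticGenome(config=config, genome=genome, truth=truth)


# ---------------------------------------------------------------------------
# Read species and library sampling
# ---------------------------------------------------------------------------

def _isomir_variants(m: MirnaTruth, genome: dict[str, str]) -> dict[str, str]:
    """One planted variant read per isomiR class for a locus."""
    chrom = genome[m.chrom]
    s, e = m.mature_start, m.mature_start + len(m.mature)
    mat = m.mature
    variants = {
        "5p_trimming": mat[1:],
        "5p_addition": chrom[s - 1 : e],
        "3p_trimming": mat[:-1],
        "3p_addition": chrom[s : e + 1],  # templated: genome base (C) appended
        "3p_nt_addition": mat + "A",  # never templated (template forced to C)
        "seed_snp": _swap(mat, 4),
        "tail_snp": _swap(mat, 12),
    }
    return variants


def _swap(seq: str, pos: int) -> str:
    order = "ACGT"
    b = seq[pos]
    return seq[: pos] + order[(order.index(b) + 1) % 4] + seq[pos + 1 :]


def build_species_table(sim: SyntheticGenome) -> pd.DataFrame:
    """Enumerate every plantable read species with per-tissue weights.

    Returns a DataFrame with columns: sequence, origin (canonical / star /
    isomiR class / phasirna / structural / fragment), locus_id, and one
    weight column per tissue.  Weights are expected relative abundances; the
    library sampler normalises them per tissue.
    """
    config = sim.config
    tissues = config.tissues
    rng = np.random.default_rng([config.seed, 1])
    rows: list[dict] = []
    r = config.isomir_rate
    canon_frac = 1.0 - len(ISOMIR_CLASSES) * r

    for m in sim.truth.mirna:
        base = config.mature_weight * m.profile  # per-tissue bundle weight
        rows.append(_species(m.mature, "canonical", m.locus_id, base * canon_frac, tissues))
        rows.append(_species(m.star, "star", m.locus_id, base * config.star_fraction, tissues))
        for cls, seq in _isomir_variants(m, sim.genome).items():
            rows.append(_species(seq, cls, m.locus_id, base * r, tissues))

    for p in sim.truth.phas:
        w = np.zeros(len(tissues))
        for t in p.tissues:
            w[tissues.index(t)] = config.phasirna_weight
        for k, seq in enumerate(p.phasirnas):
            rows.append(_species(seq, "phasirna", p.locus_id, w, tissues))

    df = pd.DataFrame(rows)
    planted_total = df[tissues].to_numpy().sum(axis=0)

    # contaminants: structural fragments (genome-templated, blacklisted) and
    # random degradation fragments of 15-30 nt, split evenly
    f = config.contamination_fraction
    crow: list[dict] = []
    if f > 0:
        structural_reads = []
        for name, seq in sim.truth.blacklist.items():
            for _ in range(3):
                ln = int(rng.integers(19, 25))
                off = int(rng.integers(0, len(seq) - ln))
                structural_reads.append((seq[off : off + ln], name))
        fragments = [
            (_random_seq(rng, int(rng.integers(15, 31))), "fragment")
            for _ in range(100)
        ]
        contam_total = planted_total * f / (1.0 - f)
        n_contam = len(structural_reads) + len(fragments)
        per_species = contam_total / max(n_contam, 1)
        for seq, name in structural_reads:
            crow.append(_species(seq, "structural", name, per_species, tissues))
        for seq, name in fragments:
            crow.append(_species(seq, "fragment", name, per_species, tissues))
    if crow:
        df = pd.concat([df, pd.DataFrame(crow)], ignore_index=True)
    # collapse duplicate sequences (e.g. shared matures of duplicate loci are
    # one species; weights add)
    agg = {c: "sum" for c in tissues}
    agg["origin"] = "first"
    agg["locus_id"] = "first"
    df = df.groupby("sequence", as_index=False, sort=True).agg(agg)
    return df


def _species(seq, origin, locus, weights, tissues):
    row = {"sequence": seq, "origin": origin, "locus_id": locus}
    if np.isscalar(weights):
        weights = np.full(len(tissues), float(weights))
    for t, w in zip(tissues, weights):
        row[t] = float(w)
    return row


def generate_libraries(
    sim: SyntheticGenome, species: pd.DataFrame | None = None
) -> tuple[dict[str, pd.Series], pd.DataFrame]:
    """Draw per-library read-count tables.

    Returns ``(libraries, library_info)`` where ``libraries`` maps library id
    to a Series of counts indexed by read sequence (zero-count species are
    dropped), and ``library_info`` has columns library_id / tissue /
    replicate.  Counts in each library sum exactly to
    ``config.depth_per_library``.
    """
    config = sim.config
    if species is None:
        species = build_species_table(sim)
    tissues = config.tissues
    libraries: dict[str, pd.Series] = {}
    info_rows = []
    lib_index = 0
    for t in tissues:
        for rep in range(config.libraries_per_tissue):
            lib_id = f"{t}_rep{rep + 1}"
            info_rows.append({"library_id": lib_id, "tissue": t, "replicate": rep + 1})
            w = species[t].to_numpy(dtype=float)
            total = w.sum()
            if config.depth_per_library == 0 or total == 0:
                warnings.warn(f"library {lib_id} drawn with zero depth")
                libraries[lib_id] = pd.Series(dtype=int)
                lib_index += 1
                continue
            rng = np.random.default_rng([config.seed, 2, lib_index])
            counts = rng.multinomial(config.depth_per_library, w / total)
            s = pd.Series(counts, index=species["sequence"].to_numpy())
            libraries[lib_id] = s[s > 0]
            lib_index += 1
    return libraries, pd.DataFrame(info_rows)


# ---------------------------------------------------------------------------
# Writers (plain-text artifacts)
# ---------------------------------------------------------------------------

def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_outputs(sim: SyntheticGenome, libraries, library_info, outdir) -> None:
    """Write genome FASTA, GFF3 annotations, truth tables and library TSVs."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "genome.fa", sim.genome)
    write_fasta(out / "blacklist.fa", sim.truth.blacklist)
    write_fasta(out / "triggers.fa", sim.truth.triggers)

    with open(out / "annotations.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, s, e in sim.truth.pcg_intervals:
            fh.write(f"{chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t+\t.\tbiotype=protein_coding\n")
        for chrom, s, e, cls in sim.truth.te_intervals:
            fh.write(
                f"{chrom}\tsim\ttransposable_element\t{s + 1}\t{e}\t.\t+\t.\tte_class={cls}\n"
            )

    mt = pd.DataFrame(
        [
            {
                "locus_id": m.locus_id, "chrom": m.chrom, "start": m.start,
                "end": m.end, "strand": m.strand, "mature": m.mature,
                "mature_start": m.mature_start, "star": m.star,
                "star_start": m.star_start, "context": m.context,
                "specific": m.specific, "target_tissue": m.target_tissue or "",
                "dup_label": m.dup_label, "partner_id": m.partner_id or "",
            }
            for m in sim.truth.mirna
        ]
    )
    mt.to_csv(out / "mirna_truth.tsv", sep="\t", index=False)

    pt = pd.DataFrame(
        [
            {
                "locus_id": p.locus_id, "chrom": p.chrom, "start": p.start,
                "end": p.end, "cycle": p.cycle, "trigger": p.trigger,
                "tissues": ",".join(p.tissues),
                "phased_positions": ",".join(map(str, p.phased_positions)),
            }
            for p in sim.truth.phas
        ]
    )
    pt.to_csv(out / "phas_truth.tsv", sep="\t", index=False)

    with open(out / "synteny.tsv", "w") as fh:
        fh.write("chromA\tstartA\tendA\tchromB\tstartB\tendB\tblock_id\n")
        for ca, sa, ea, cb, sb, eb, bid in sim.truth.synteny_blocks:
            fh.write(f"{ca}\t{sa + 1}\t{ea}\t{cb}\t{sb + 1}\t{eb}\t{bid}\n")

    libdir = out / "libraries"
    libdir.mkdir(exist_ok=True)
    library_info.to_csv(out / "library_info.tsv", sep="\t", index=False)
    for lib_id, counts in libraries.items():
        counts.rename("count").rename_axis("sequence").to_csv(
            libdir / f"{lib_id}.tsv", sep="\t"
        )
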