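"""End-to-end orchestration of the small-RNA analysis stages.

Stages run in pipeline order — simulate (or load inputs), preprocess,
discover, isomiR, specificity, PHAS, duplication, report — each writing
plain-text artifacts into the run directory, with a JSON manifest recording
the configuration hash, seed, per-stage row counts and outcome.  Reruns
with an identical configuration reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import discovery, duplication, isomir, phasing, preprocess, simulate, stats

ALL_STAGES = [
    "simulate", "preprocess", "discover", "isomir",
    "specificity", "phas", "duplication", "report",
]


@dataclass
class RunConfig:
    outdir: str = "srnascape_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    sim: simulate.SimConfig | None = None
    # thresholds, mirroring each module's defaults
    min_len: int = preprocess.MIN_LEN
    max_len: int = preprocess.MAX_LEN
    max_hits: int = preprocess.MAX_HITS
    min_total_tpm: float = preprocess.MIN_TOTAL_TPM
    min_lib_tpm: float = preprocess.MIN_LIB_TPM
    min_strand_bias: float = discovery.MIN_STRAND_BIAS
    min_abundance_bias: float = discovery.MIN_ABUNDANCE_BIAS
    max_modh: float = stats.MODH_MAX
    min_zmax: float = stats.ZMAX_MIN
    phas_max_p: float = phasing.MAX_P
    phas_min_depth: int = phasing.MIN_DEPTH
    tandem_max: int = duplication.TANDEM_MAX_DISTANCE
    expressed_min_tpm: float = 1.0  # "expressed in a tissue" for the report

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    config: RunConfig
    outdir: Path
    sim: simulate.SyntheticGenome | None = None
    reads: preprocess.ReadSet | None = None
    loci: list = field(default_factory=list)
    isomir_records: list = field(default_factory=list)
    specificity: pd.DataFrame | None = None
    phas_loci: list = field(default_factory=list)
    dup_calls: dict = field(default_factory=dict)
    locus_tpm: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _locus_expression(result: RunResult) -> pd.DataFrame:
    """Per-locus, per-library TPM summed over attributed reads."""
    reads = result.reads
    rows = {}
    for locus in result.loci:
        seqs = [s for s in locus.attributed if s in reads.tpm.index]
        rows[locus.locus_id] = reads.tpm.loc[seqs].sum(axis=0)
    return pd.DataFrame(rows).T


def run_pipeline(config: RunConfig) -> RunResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.stages
    result = RunResult(config=config, outdir=outdir)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "tool": "srnascape 0.1.0",
        "stages": {},
    }
    result.manifest = manifest

    def mark(stage: str, status: str, rows: int | None = None) -> None:
        manifest["stages"][stage] = {"status": status, "rows": rows}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    for stage in ALL_STAGES:
        if stage not in stages:
            mark(stage, "skipped")
            continue
        try:
            rows = _run_stage(stage, config, result)
        except Exception:
            mark(stage, "failed")
            raise
        mark(stage, "ok", rows)
    return result


def _run_stage(stage: str, config: RunConfig, result: RunResult) -> int | None:
    outdir = result.outdir
    if stage == "simulate":
        sim_config = config.sim or simulate.SimConfig(seed=config.seed)
        sim = simulate.generate_genome(sim_config)
        libraries, info = simulate.generate_libraries(sim)
        simulate.write_outputs(sim, libraries, info, outdir / "inputs")
        result.sim = sim
        result._libraries = libraries
        result._library_info = info
        return len(sim.truth.mirna)

    if stage == "preprocess":
        sim = result.sim
        if sim is None:
            raise FileNotFoundError("preprocess needs the simulate stage (or loaded inputs)")
        params = preprocess.FilterParams(
            min_len=config.min_len, max_len=config.max_len,
            max_hits=config.max_hits, min_total_tpm=config.min_total_tpm,
            min_lib_tpm=config.min_lib_tpm,
        )
        reads = preprocess.preprocess(
            result._libraries, result._library_info, sim.genome,
            sim.truth.blacklist, params,
        )
        result.reads = reads
        reads.attrition.to_csv(outdir / "attrition.tsv", sep="\t", index=False)
        status_table = pd.DataFrame(
            {"sequence": reads.status.index, "status": reads.status.to_numpy(),
             "total_count": reads.total_counts().to_numpy()}
        )
        status_table.to_csv(outdir / "read_status.tsv", sep="\t", index=False)
        return int((reads.status == "pass").sum())

    if stage == "discover":
        loci, dstats = discovery.discover_loci(
            result.reads, result.sim.genome,
            min_strand_bias=config.min_strand_bias,
            min_abundance_bias=config.min_abundance_bias,
        )
        result.loci = loci
        result.locus_tpm = _locus_expression(result)
        table = discovery.loci_table(loci)
        table.to_csv(outdir / "mirna_loci.tsv", sep="\t", index=False)
        with open(outdir / "mirna_loci.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for l in loci:
                fh.write(
                    f"{l.chrom}\tsrnascape\tmiRNA_primary_transcript\t{l.start + 1}"
                    f"\t{l.end}\t.\t{l.strand}\t.\tID={l.locus_id}\n"
                )
        return len(loci)

    if stage == "isomir":
        records = []
        reads = result.reads
        genome = result.sim.genome
        for locus in result.loci:
            prec = genome[locus.chrom][locus.start : locus.end]
            c_off = locus.mature_start - locus.start
            for seq in locus.attributed:
                if seq == locus.mature:
                    continue
                aligns = [a for a in reads.alignments.get(seq, ())
                          if a[0] == locus.chrom and locus.start <= a[1] < locus.end]
                if not aligns:
                    continue
                rec = isomir.classify_isomir(
                    seq, locus.mature, prec, c_off,
                    locus_id=locus.locus_id,
                    offset5=aligns[0][1] - locus.mature_start,
                )
                if rec is not None and rec.classes:
                    records.append(rec)
        result.isomir_records = records
        pd.DataFrame(
            [
                {"read": r.read, "locus_id": r.locus_id,
                 "classes": ",".join(sorted(r.classes)),
                 "offset5": r.offset5, "offset3": r.offset3}
                for r in records
            ]
        ).to_csv(outdir / "isomirs.tsv", sep="\t", index=False)
        isomir.end_composition(records).to_csv(
            outdir / "end_composition.tsv", sep="\t", index=False
        )
        return len(records)

    if stage == "specificity":
        matrix = result.locus_tpm
        lib2tissue = result.reads.library_info.set_index("library_id")["tissue"]
        tissue_mean = matrix.T.groupby(matrix.columns.map(lib2tissue), sort=False).mean().T
        calls = stats.call_tissue_specific(
            tissue_mean, max_modh=config.max_modh, min_zmax=config.min_zmax
        )
        result.specificity = calls
        result._tissue_mean = tissue_mean
        calls.to_csv(outdir / "specificity.tsv", sep="\t")
        return int(calls["specific"].sum())

    if stage == "phas":
        reads = result.reads
        genome = result.sim.genome
        triggers = dict(result.sim.truth.triggers)
        all_loci = []
        for cycle in (21, 24):
            placements = []
            for seq in reads.passing():
                if len(seq) != cycle:
                    continue
                for chrom, start, strand, nm in reads.alignments[seq]:
                    placements.append((chrom, start, strand))
            loci = phasing.detect_phas_loci(
                placements, cycle,
                max_p=config.phas_max_p, min_depth=config.phas_min_depth,
            )
            for locus in loci:
                phasing.assign_trigger(locus, triggers, genome)
                phasing.apply_exclusion(locus, result.sim.truth.te_intervals)
            all_loci.extend(loci)
        result.phas_loci = all_loci
        pd.DataFrame(
            [
                {"locus_id": l.locus_id, "chrom": l.chrom, "start": l.start,
                 "end": l.end, "cycle": l.cycle,
                 "occupied": l.occupied_positions, "phased": l.phased_positions,
                 "p_value": l.p_value, "trigger": l.trigger or "",
                 "excluded": l.excluded}
                for l in all_loci
            ]
        ).to_csv(outdir / "phas_loci.tsv", sep="\t", index=False)
        with open(outdir / "phas_loci.bed", "w") as fh:
            for l in all_loci:
                fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.locus_id}\t0\t+\n")
        return len(all_loci)

    if stage == "duplication":
        table = discovery.loci_table(result.loci)
        truth = result.sim.truth
        pairs = duplication.find_conserved_pairs(table)
        calls = duplication.classify_duplication(
            table, pairs,
            [duplication.SyntenyBlock(*blk) for blk in truth.synteny_blocks],
            pcg_intervals=truth.pcg_intervals,
            te_intervals=truth.te_intervals,
            tandem_max=config.tandem_max,
        )
        result.dup_calls = calls
        for locus in result.loci:
            locus.context = calls[locus.locus_id].context
        pd.DataFrame(
            [
                {"locus_id": c.locus_id, "context": c.context, "status": c.status,
                 "mechanism": c.mechanism, "partners": ",".join(c.partners),
                 "pair_distance": c.pair_distance if c.pair_distance is not None else ""}
                for c in calls.values()
            ]
        ).to_csv(outdir / "duplication.tsv", sep="\t", index=False)
        return len(calls)

    if stage == "report":
        return _report(config, result)

    raise ValueError(f"unknown stage {stage!r}")


def summarize_contexts(calls: dict) -> pd.DataFrame:
    """Context x status counts with per-category ratio tests vs the total."""
    rows = []
    total_s = sum(1 for c in calls.values() if c.status == "singleton")
    total_d = sum(1 for c in calls.values() if c.status == "duplicate")
    rows.append({"category": "Total", "singletons": total_s, "duplicates": total_d,
                 "ratio": total_s / total_d if total_d else float("inf"),
                 "chi2": float("nan"), "p": float("nan")})
    for ctx in ("PCG", "TE", "UI"):
        s = sum(1 for c in calls.values() if c.context == ctx and c.status == "singleton")
        d = sum(1 for c in calls.values() if c.context == ctx and c.status == "duplicate")
        if total_d == 0 or (s + d) == 0 or (s == 0 and d == 0):
            rows.append({"category": ctx, "singletons": s, "duplicates": d,
                         "ratio": float("nan"), "chi2": float("nan"), "p": float("nan")})
            continue
        try:
            rt = duplication.ratio_chisq(s, d, total_s, total_d, category=ctx)
            rows.append({"category": ctx, "singletons": s, "duplicates": d,
                         "ratio": rt.ratio, "chi2": rt.chi2, "p": rt.p})
        except ValueError:
            rows.append({"category": ctx, "singletons": s, "duplicates": d,
                         "ratio": s / d if d else float("inf"),
                         "chi2": float("nan"), "p": float("nan")})
    return pd.DataFrame(rows)


def summarize_tissues(
    tissue_mean: pd.DataFrame, calls: dict, min_tpm: float = 1.0
) -> pd.DataFrame:
    """Per-tissue expressed singleton/duplicate counts with ratio tests."""
    status = {lid: c.status for lid, c in calls.items()}
    total_s = sum(1 for v in status.values() if v == "singleton")
    total_d = sum(1 for v in status.values() if v == "duplicate")
    rows = []
    for tissue in tissue_mean.columns:
        expressed = tissue_mean.index[tissue_mean[tissue] >= min_tpm]
        s = sum(1 for lid in expressed if status.get(lid) == "singleton")
        d = sum(1 for lid in expressed if status.get(lid) == "duplicate")
        try:
            rt = duplication.ratio_chisq(s, d, total_s, total_d, category=tissue)
            chi2_v, p = rt.chi2, rt.p
        except ValueError:
            chi2_v, p = float("nan"), float("nan")
        rows.append({"tissue": tissue, "singletons": s, "duplicates": d,
                     "ratio": s / d if d else float("inf"), "chi2": chi2_v, "p": p})
    return pd.DataFrame(rows)


def _report(config: RunConfig, result: RunResult) -> int:
    outdir = result.outdir
    n = 0
    if result.dup_calls:
        ctx = summarize_contexts(result.dup_calls)
        ctx.to_csv(outdir / "context_ratio_tests.tsv", sep="\t", index=False)
        n += len(ctx)
        if getattr(result, "_tissue_mean", None) is not None:
            tis = summarize_tissues(
                result._tissue_mean, result.dup_calls, config.expressed_min_tpm
            )
            tis.to_csv(outdir / "tissue_ratio_tests.tsv", sep="\t", index=False)
            n += len(tis)
    if result.phas_loci:
        summary = pd.DataFrame(
            [
                {"cycle": cycle,
                 "n_loci": sum(1 for l in result.phas_loci if l.cycle == cycle),
                 "n_excluded": sum(
                     1 for l in result.phas_loci if l.cycle == cycle and l.excluded)}
                for cycle in (21, 24)
            ]
        )
        summary.to_csv(outdir / "phas_summary.tsv", sep="\t", index=False)
        n += len(summary)
    return n
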