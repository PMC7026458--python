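"""Shared fixtures: one reference synthetic run reused across test modules."""

from __future__ import annotations

import pytest

from srnascape import pipeline, simulate


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline run under the reference study conditions (seed 1)."""
    outdir = tmp_path_factory.mktemp("run")
    config = pipeline.RunConfig(outdir=str(outdir), seed=1)
    return pipeline.run_pipeline(config)


@pytest.fixture(scope="session")
def truth(default_run):
    return default_run.sim.truth


def _overlaps(locus, planted) -> bool:
    return (
        locus.chrom == planted.chrom
        and locus.start < planted.end
        and planted.start < locus.end
    )


@pytest.fixture(scope="session")
def truth_to_discovered(default_run, truth):
    """Map planted locus id -> discovered locus id (by interval overlap)."""
    mapping = {}
    for planted in truth.mirna:
        for locus in default_run.loci:
            if _overlaps(locus, planted):
                mapping[planted.locus_id] = locus.locus_id
                break
    return mapping


@pytest.fixture(scope="session")
def small_sim():
    """Compact synthetic genome for generator-level unit tests."""
    config = simulate.SimConfig(
        seed=7, n_mirna_loci=12, n_tissue_specific=4, n_phas21=2, n_phas24=2,
        n_tandem_pairs=2, n_syntenic_pairs=2, depth_per_library=20_000,
        chrom_length=120_000,
    )
    return simulate.generate_genome(config)
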