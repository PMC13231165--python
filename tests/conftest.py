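"""Shared fixtures: synthetic sequencing runs at small and study scale."""

import pytest

from huhseq.cli import RunConfig, run_huhseq
from huhseq.synthetic_data import (
    SimulationManifest,
    default_cleavage_model,
    simulate_huhseq_run,
)

STUDY_SEED = 20260921


def study_manifest(seed: int = STUDY_SEED,
                   depth: int = 100_000) -> SimulationManifest:
    """The canonical simulated study: skewed reference pool, three
    replicates, replicate 1 of the low-Mn condition corrupted."""
    return SimulationManifest(
        seed=seed,
        depth_per_sample=depth,
        n_replicates=3,
        corrupt_replicate=("WT_lowMn", 1),
        error_rate=0.001,
        reference_profile="synthesis_bias",
    )


def study_models():
    return {
        "E2_highMn": default_cleavage_model("promiscuous"),
        "WT_lowMn": default_cleavage_model("specific"),
    }


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Full-depth (10^5 reads/sample) simulated HUH-seq run."""
    out = tmp_path_factory.mktemp("study_run")
    return simulate_huhseq_run(None, study_models(), study_manifest(), out)


@pytest.fixture(scope="session")
def study_analysis(study_run, tmp_path_factory):
    """The HUH-seq pipeline executed on the full-depth study run."""
    out = tmp_path_factory.mktemp("study_out")
    config = RunConfig(
        fastq=str(study_run.fastq_path),
        sample_sheet=str(study_run.out_dir / "sample_sheet.tsv"),
        out_dir=str(out),
    )
    return run_huhseq(config)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Fast small-depth run for plumbing tests (not for statistics)."""
    out = tmp_path_factory.mktemp("small_run")
    manifest = SimulationManifest(
        seed=7, depth_per_sample=2000, n_replicates=2,
        error_rate=0.001, reference_profile="uniform",
    )
    return simulate_huhseq_run(
        None, {"enzyme": default_cleavage_model("promiscuous")}, manifest, out
    )
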