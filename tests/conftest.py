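"""Shared fixtures: one full default-condition pipeline run per session."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from peroximir import pipeline, simulate


@dataclass
class PipelineRun:
    config: pipeline.PipelineConfig
    truth: simulate.GroundTruth
    stats: dict


@pytest.fixture(scope="session")
def default_run(tmp_path_factory) -> PipelineRun:
    """Full pipeline on the default synthetic dataset (seed 1)."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = pipeline.PipelineConfig(outdir=outdir)
    truth = pipeline.stage_simulate(cfg)
    for name, fn in pipeline.STAGES[1:]:
        fn(cfg)
    return PipelineRun(config=cfg, truth=truth, stats=pipeline._load_stats(cfg))


@pytest.fixture(scope="session")
def tiny_config() -> simulate.SimulationConfig:
    """A minimal, fast configuration for unit-level simulation tests."""
    return simulate.SimulationConfig(
        seed=7,
        n_chromosomes=1,
        chromosome_length=20_000,
        n_planted_mirnas=4,
        n_known_mirnas=2,
        n_planted_ncrnas=3,
        n_genes=8,
        n_target_genes=4,
        library_depth_cs=4_000,
        library_depth_ts=4_000,
        repeat_copy_numbers=(),
    )
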