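"""Shared fixtures: a small synthetic cohort for unit tests and one
default-conditions pipeline run shared by the slower end-to-end checks."""

from __future__ import annotations

import logging

import pytest

from cogsea.config import (
    GseaConfig,
    PipelineConfig,
    SetBuildConfig,
    SimConfig,
    ValidationConfig,
)
from cogsea.pipeline import run_full_pipeline

logging.disable(logging.INFO)


def small_sim(**overrides) -> SimConfig:
    """A fast, structurally complete simulation config for unit tests."""
    base = dict(
        n_chromosomes=2,
        n_genes=120,
        n_snps=900,
        gene_length_bp=(2000, 8000),
        intergenic_gap_bp=(12000, 30000),
        ld_block_len=3,
        within_block_r2=0.8,
        n_individuals=300,
        maf_range=(0.1, 0.5),
        n_causal_genes=8,
        shared_fraction=0.5,
        heritability=0.4,
        target_ncp=12.0,
        master_seed=42,
    )
    base.update(overrides)
    return SimConfig(**base)


def small_pipeline_config(**sim_overrides) -> PipelineConfig:
    return PipelineConfig(
        sim=small_sim(**sim_overrides),
        set_build=SetBuildConfig((5, 10, 20)),
        gsea=GseaConfig(n_permutations=200, n_runs=2, seed=0),
        validation=ValidationConfig(n_mimic=20, percentile_rule=19),
        n_traits=3,
    )


@pytest.fixture(scope="session")
def small_run():
    """One end-to-end run at the small test conditions."""
    return run_full_pipeline(small_pipeline_config())


@pytest.fixture(scope="session")
def default_run():
    """One end-to-end run at the default study conditions (shared because
    it is expensive)."""
    return run_full_pipeline(PipelineConfig(sim=SimConfig(master_seed=1)))
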