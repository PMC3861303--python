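"""Configuration dataclasses for every pipeline stage.

Each stage of the pipeline (simulation, QC, gene binning, set building,
enrichment, validation) has its own small config object with defaults that
reproduce the reference parameterization: 10 kb gene flanks, r^2 >= 0.8 LD
tagging, Sidak min-p gene scores, top-K thresholds 25..2000, weighted
(exponent 1) enrichment with 1000 permutations averaged over 3 runs,
declaration at p <= 0.05 and FDR q <= 0.25, and validation against 100
SNP-count-matched mimic sets at the 98 % rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = [
    "SimConfig",
    "QcThresholds",
    "BinningConfig",
    "SetBuildConfig",
    "ValidationConfig",
    "GseaConfig",
    "PipelineConfig",
    "load_config",
    "save_config",
]

#: default top-K thresholds for nested candidate gene sets
DEFAULT_THRESHOLDS = (25, 50, 100, 250, 500, 750, 1000, 1250, 1500, 1750, 2000)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic discovery + target cohorts.

    A quantitative-trait discovery cohort (genotypes in LD blocks, phenotype
    with age/sex covariates) and a case-control target GWAS emitted as
    summary statistics, with ``n_causal_genes`` causal genes of which a
    fraction ``shared_fraction`` also carries association signal in the
    target.  ``target_ncp`` is the non-centrality of the 1-df chi-square
    association statistic at shared causal SNPs in the target GWAS.
    """

    n_chromosomes: int = 4
    n_genes: int = 2200
    n_snps: int = 19000
    gene_length_bp: tuple[int, int] = (2000, 20000)
    intergenic_gap_bp: tuple[int, int] = (35000, 80000)
    ld_block_len: int = 3
    within_block_r2: float = 0.8
    n_individuals: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_genes: int = 25
    shared_fraction: float = 0.6
    heritability: float = 0.5
    target_ncp: float = 12.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.n_genes < 0 or self.n_snps < 1:
            raise ValueError("n_genes must be >= 0 and n_snps >= 1")
        lo, hi = self.gene_length_bp
        if not (0 < lo <= hi):
            raise ValueError("gene_length_bp must be a positive (lo, hi) range")
        lo, hi = self.intergenic_gap_bp
        if not (0 < lo <= hi):
            raise ValueError("intergenic_gap_bp must be a positive (lo, hi) range")
        if self.ld_block_len < 1:
            raise ValueError("ld_block_len must be >= 1")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ValueError("within_block_r2 must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("n_causal_genes must not exceed n_genes")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if not 0.0 <= self.heritability < 1.0:
            raise ValueError("heritability must lie in [0, 1)")
        if self.target_ncp < 0:
            raise ValueError("target_ncp must be non-negative")

    @property
    def n_shared_genes(self) -> int:
        return int(round(self.shared_fraction * self.n_causal_genes))


@dataclass(frozen=True)
class QcThresholds:
    """SNP QC exclusion thresholds; exclusion is strict (<), so a SNP whose
    value equals a threshold is kept."""

    call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 0.001

    def __post_init__(self) -> None:
        for name in ("call_rate_min", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class BinningConfig:
    """SNP-to-gene assignment: gene boundaries extended by ``flank_bp`` on
    both sides, LD tagging at pairwise r^2 >= ``r2_min``."""

    flank_bp: int = 10000
    r2_min: float = 0.8

    def __post_init__(self) -> None:
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if not 0.0 <= self.r2_min <= 1.0:
            raise ValueError("r2_min must lie in [0, 1]")


@dataclass(frozen=True)
class SetBuildConfig:
    """Top-K thresholds for the nested candidate gene sets."""

    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        ts = tuple(int(t) for t in self.thresholds)
        if not ts or any(t < 1 for t in ts):
            raise ValueError("thresholds must be >= 1")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", ts)


@dataclass(frozen=True)
class ValidationConfig:
    """Mimic-random-set validation: ``n_mimic`` matched random sets, of
    which the candidate's NES must strictly exceed ``percentile_rule``."""

    n_mimic: int = 100
    percentile_rule: int = 98
    snp_count_bins: int = 10

    def __post_init__(self) -> None:
        if self.n_mimic < 2:
            raise ValueError("n_mimic must be >= 2")
        if not 0 <= self.percentile_rule < self.n_mimic:
            raise ValueError("percentile_rule must lie in [0, n_mimic)")
        if self.snp_count_bins < 1:
            raise ValueError("snp_count_bins must be >= 1")


@dataclass(frozen=True)
class GseaConfig:
    """Weighted preranked GSEA parameters."""

    weight_exponent: float = 1.0
    n_permutations: int = 1000
    n_runs: int = 3
    p_max: float = 0.05
    q_max: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration embedding every stage config."""

    sim: SimConfig = field(default_factory=SimConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    binning: BinningConfig = field(default_factory=BinningConfig)
    set_build: SetBuildConfig = field(default_factory=SetBuildConfig)
    gsea: GseaConfig = field(default_factory=GseaConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    n_traits: int = 9
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_traits < 1:
            raise ValueError("n_traits must be >= 1")


_SECTION_TYPES = {
    "sim": SimConfig,
    "qc": QcThresholds,
    "binning": BinningConfig,
    "set_build": SetBuildConfig,
    "gsea": GseaConfig,
    "validation": ValidationConfig,
}

_TUPLE_FIELDS = {"gene_length_bp", "intergenic_gap_bp", "maf_range", "thresholds"}


def _build(cls, data: dict):
    kwargs = {}
    for k, v in data.items():
        if k in _TUPLE_FIELDS and isinstance(v, Sequence):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from a YAML file whose sections mirror
    the config field names exactly."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            kwargs[section] = _build(cls, data.pop(section))
    kwargs.update(data)
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    """Write a pipeline config as YAML (lists for tuple-valued fields)."""
    out: dict = {}
    for section in _SECTION_TYPES:
        out[section] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(getattr(config, section)).items()
        }
    out["n_traits"] = config.n_traits
    out["log_level"] = config.log_level
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
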