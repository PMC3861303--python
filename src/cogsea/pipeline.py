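"""End-to-end orchestration: simulate -> QC/GWAS -> score -> sets -> GSEA
-> mimic validation -> report.

The discovery arm runs one GWAS per trait on the simulated cohort, bins
SNPs to genes, scores and ranks genes, and builds the nested top-K
candidate sets (n_traits x 11 thresholds; 99 sets under the defaults).
The first trait carries the simulated causal genes; the remaining traits
are genetically null, so their sets act as within-suite negative controls.
The target arm converts the simulated disorder summary statistics into a
ranked gene list via the same binning and scoring, then all candidate sets
are tested together with weighted permutation GSEA; nominally enriched
sets (p <= p_max, mean q <= q_max) are validated against 100 SNP-count-
matched mimic sets at the 98 % rule.

Given an output directory the pipeline writes every intermediate file in
the standard formats plus a JSON manifest of configs, seeds and content
digests; a rerun with the same master seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from ._seeds import stage_rng
from .config import GseaConfig, PipelineConfig
from .containers import GeneSetCollection, GenotypeMatrix
from .gsea import mimic_validate, run_gsea
from .qc import GwasEngine, qc_filter
from .scoring import GeneBins, bin_snps, rank_genes, score_genes
from .sets import build_nested_sets, make_mimic_sets
from .synthetic import (
    make_cognitive_phenotype,
    make_genome,
    make_genotypes,
    make_ld_table,
    make_target_summary,
    select_causal_genes,
    select_shared_genes,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_full_pipeline", "specificity_suite", "trait_labels"]


def trait_labels(n_traits: int) -> list[str]:
    return [f"trait{i + 1}" for i in range(n_traits)]


def _derived_int(master_seed: int, stage: str) -> int:
    return int(stage_rng(master_seed, stage).integers(2**31))


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus file paths when written."""

    config: PipelineConfig
    genes: pd.DataFrame
    snp_map: pd.DataFrame
    ld_table: pd.DataFrame
    genotypes: GenotypeMatrix
    qc_report: pd.DataFrame
    kept_snps: list[str]
    causal_genes: list[str]
    shared_genes: list[str]
    gwas: dict[str, pd.DataFrame]
    discovery_bins: GeneBins
    target_bins: GeneBins
    ranked: dict[str, pd.DataFrame]
    candidate_sets: GeneSetCollection
    target_summary: pd.DataFrame
    target_ranked: pd.DataFrame
    enrichment: pd.DataFrame
    validations: dict[str, dict]
    output_dir: Path | None = None
    manifest: dict = field(default_factory=dict)


def run_full_pipeline(
    config: PipelineConfig | None = None,
    output_dir=None,
    write_genotype_matrix: bool = True,
) -> PipelineResult:
    """Run every stage and (optionally) write all artifacts + manifest."""
    config = config or PipelineConfig()
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    sim = config.sim
    labels = trait_labels(config.n_traits)

    logger.info("simulating genome: %d genes, %d SNPs", sim.n_genes, sim.n_snps)
    genes, snp_map = make_genome(sim)
    ld_table = make_ld_table(snp_map, sim)
    genotypes = make_genotypes(snp_map, ld_table, sim)

    kept, qc_report = qc_filter(genotypes, config.qc)
    logger.info("QC: %d of %d SNPs kept", len(kept), genotypes.n_snps)
    geno_kept = genotypes.subset_snps(kept)

    # eligibility on the QC-kept map: the designated causal SNP must survive QC
    causal = select_causal_genes(geno_kept.snp_map, genes, sim)
    shared = select_shared_genes(causal, sim)

    gwas: dict[str, pd.DataFrame] = {}
    engine = None
    for i, label in enumerate(labels):
        # only the first trait carries the simulated causal genes
        trait_sim = sim if i == 0 else dataclasses.replace(sim, heritability=0.0)
        phen = make_cognitive_phenotype(
            geno_kept, genes, causal if i == 0 else [], trait_sim, stage=f"phenotype-{label}"
        )
        if engine is None:  # traits share the cohort, so the engine is shared
            engine = GwasEngine(geno_kept, phen, covariates=("age", "sex"))
        gwas[label] = engine.run(phen)
    logger.info("discovery GWAS done for %d traits", len(labels))

    discovery_bins = bin_snps(geno_kept.snp_map, genes, ld_table, config.binning)
    target_bins = bin_snps(snp_map, genes, ld_table, config.binning)

    ranked: dict[str, pd.DataFrame] = {}
    candidate_sets = GeneSetCollection()
    for label in labels:
        scores = score_genes(gwas[label], discovery_bins)
        ranked[label] = rank_genes(scores)
        candidate_sets.extend(build_nested_sets(ranked[label], config.set_build, label))
    logger.info(
        "built %d candidate sets (%d traits x %d thresholds)",
        len(candidate_sets), len(labels), len(config.set_build.thresholds),
    )

    target_summary = make_target_summary(snp_map, genes, shared, sim)
    target_ranked = rank_genes(score_genes(target_summary, target_bins))

    gsea_cfg = dataclasses.replace(
        config.gsea, seed=_derived_int(sim.master_seed, f"gsea|{config.gsea.seed}")
    )
    enrichment = run_gsea(target_ranked, candidate_sets, gsea_cfg)
    n_enriched = int(enrichment["enriched"].sum())
    logger.info("GSEA: %d of %d sets nominally enriched", n_enriched, len(enrichment))

    validations: dict[str, dict] = {}
    validated_col = []
    for row in enrichment.itertuples(index=False):
        if not row.enriched:
            validated_col.append("n.a.")
            continue
        outcome = _validate_one(
            row.set_name, candidate_sets, target_bins, target_ranked, config, sim.master_seed
        )
        validations[row.set_name] = outcome
        validated_col.append(str(outcome["validated"]) if outcome["validated"] is not None else "n.c.")
    enrichment = enrichment.copy()
    enrichment["validated"] = validated_col
    logger.info(
        "validation: %d of %d enriched sets validated",
        sum(1 for v in validations.values() if v["validated"]), len(validations),
    )

    result = PipelineResult(
        config=config, genes=genes, snp_map=snp_map, ld_table=ld_table,
        genotypes=genotypes, qc_report=qc_report, kept_snps=kept,
        causal_genes=causal, shared_genes=shared, gwas=gwas,
        discovery_bins=discovery_bins, target_bins=target_bins, ranked=ranked,
        candidate_sets=candidate_sets, target_summary=target_summary,
        target_ranked=target_ranked, enrichment=enrichment, validations=validations,
    )
    if output_dir is not None:
        _write_bundle(result, Path(output_dir), write_genotype_matrix)
    return result


def _validate_one(set_name, candidate_sets, target_bins, target_ranked, config, master_seed):
    """Mimic-set validation of one nominally enriched set."""
    candidate = candidate_sets[set_name]
    try:
        mimics = make_mimic_sets(
            candidate, target_bins, config.validation,
            seed=_derived_int(master_seed, f"mimic|{set_name}"),
        )
    except ValueError as exc:
        logger.warning("mimic sets for %s not constructible: %s", set_name, exc)
        return {"validated": None, "exceeded": None, "reason": str(exc)}
    coll = GeneSetCollection()
    coll.add(candidate)
    coll.extend(mimics)
    vcfg = dataclasses.replace(
        config.gsea, n_runs=1,
        seed=_derived_int(master_seed, f"gsea-validate|{set_name}|{config.gsea.seed}"),
    )
    res = run_gsea(target_ranked, coll, vcfg).set_index("set_name")
    cand_nes = float(res.loc[set_name, "nes"])
    mimic_nes = res.drop(index=set_name)["nes"].to_numpy(dtype=float)
    validated, exceeded = mimic_validate(cand_nes, mimic_nes, config.validation)
    return {"validated": bool(validated), "exceeded": exceeded, "nes": cand_nes}


def specificity_suite(
    collection: GeneSetCollection, null_target_ranked: pd.DataFrame, config: GseaConfig
) -> tuple[pd.DataFrame, float]:
    """GSEA of a set collection against a signal-free target ranking.

    Returns the standard report and the headline statistic: the minimum
    mean FDR q over the collection.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    report = run_gsea(null_target_ranked, collection, config)
    min_q = float(np.nanmin(report["q_fdr_mean"].to_numpy()))
    return report, min_q


# ----------------------------------------------------------------- writing
def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _fixed_precision(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: f"{v:.6g}" if np.isfinite(v) else "NA")
    return out


def _write_bundle(result: PipelineResult, outdir: Path, write_genotype_matrix: bool) -> None:
    from . import __version__
    from .config import save_config

    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        written.append(path)

    emit("config.yaml", lambda p: save_config(result.config, p))
    emit("genes.bed", lambda p: io.write_bed(result.genes, p))
    emit("genes.gff3", lambda p: io.write_gff3(result.genes, p))
    emit("ld.tsv", lambda p: io.write_ld_table(result.ld_table, p))
    if write_genotype_matrix:
        emit("genotypes.tsv", lambda p: io.write_genotypes(result.genotypes, p))
    emit("qc_report.tsv", lambda p: _fixed_precision(result.qc_report).to_csv(p, sep="\t", index=False))
    for label, table in result.gwas.items():
        emit(f"gwas_{label}.assoc.tsv", lambda p, t=table: io.write_assoc(t, p))
    for label, table in result.ranked.items():
        emit(f"ranked_{label}.rnk", lambda p, t=table: io.write_rnk(t, p))
    emit("gene_bins.tsv", lambda p: result.discovery_bins.to_frame().to_csv(p, sep="\t", index=False))
    emit("candidate_sets.gmt", lambda p: io.write_gmt(result.candidate_sets, p))
    emit("target_summary.assoc.tsv", lambda p: io.write_assoc(result.target_summary, p))
    emit("target_ranked.rnk", lambda p: io.write_rnk(result.target_ranked, p))
    # full score table with gene coordinates (gene, chr, start, end, n_snps,
    # sidak_p, score, rank)
    coords = result.genes.set_index("gene_id")
    scored = result.target_ranked.join(coords, on="gene_id")
    scored = scored[
        ["gene_id", "chromosome", "start", "end", "n_snps", "p_min", "sidak_p", "score", "rank"]
    ]
    emit("target_gene_scores.tsv",
         lambda p: _fixed_precision(scored).to_csv(p, sep="\t", index=False))
    emit("enrichment_report.tsv",
         lambda p: _fixed_precision(result.enrichment).to_csv(p, sep="\t", index=False))
    emit("truth.json", lambda p: Path(p).write_text(json.dumps(
        {"causal_genes": result.causal_genes, "shared_genes": result.shared_genes}, indent=1)))

    manifest = {
        "package": "cogsea",
        "version": __version__,
        "master_seed": result.config.sim.master_seed,
        "n_candidate_sets": len(result.candidate_sets),
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    result.output_dir = outdir
    result.manifest = manifest
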