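"""Synthetic discovery and target GWAS cohorts with known shared genetics.

The generator lays non-overlapping genes along a small number of
chromosomes, scatters SNPs uniformly over the spanned intervals, imposes
block LD (consecutive SNPs within a block are noisy copies of a block
anchor), draws genotypes for a discovery cohort, builds a quantitative
phenotype (additive effects at one designated causal SNP per causal gene,
plus age and sex covariate effects and Gaussian noise), and emits a target
case-control GWAS as summary statistics in which the designated causal SNP
of every *shared* causal gene carries a non-central chi-square association
signal.

Everything is a pure function of ``SimConfig.master_seed`` (per-stage seeds
are derived from the master seed and a stage name), so identical configs
give byte-identical outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import stage_rng
from .config import SimConfig
from .containers import GenotypeMatrix

__all__ = [
    "make_genome",
    "make_ld_table",
    "make_genotypes",
    "designate_causal_snps",
    "select_causal_genes",
    "select_shared_genes",
    "make_cognitive_phenotype",
    "make_target_summary",
]

# fixed nonzero covariate effects so covariate adjustment is exercised
AGE_EFFECT = -0.02  # phenotype units per year
SEX_EFFECT = 0.25  # phenotype units (sex coded 0/1)
AGE_RANGE = (18, 79)  # inclusive, years


class SizingError(ValueError):
    """Requested counts cannot be placed in the spanned genome interval."""


def _split_counts(total: int, parts: int, weights=None) -> np.ndarray:
    """Deterministically split ``total`` into ``parts`` integers
    (proportional to ``weights`` when given, largest-remainder rounding)."""
    if weights is None:
        weights = np.ones(parts)
    weights = np.asarray(weights, dtype=float)
    raw = total * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def make_genome(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out genes and SNP positions.

    Returns ``(genes, snp_map)``: a gene annotation table (``gene_id``,
    ``chromosome``, ``start``, ``end``; 1-based inclusive, non-overlapping)
    and a SNP map (``snp_id``, ``chromosome``, ``position``; positions
    unique and strictly increasing within a chromosome).
    """
    rng = stage_rng(config.master_seed, "genome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genes_per_chrom = _split_counts(config.n_genes, config.n_chromosomes)
    snps_total = config.n_snps

    gene_rows = []
    spans = []
    gene_idx = 0
    for chrom, n_g in zip(chroms, genes_per_chrom):
        cursor = 0  # last occupied bp
        for _ in range(n_g):
            gap = int(rng.integers(config.intergenic_gap_bp[0], config.intergenic_gap_bp[1] + 1))
            length = int(rng.integers(config.gene_length_bp[0], config.gene_length_bp[1] + 1))
            start = cursor + gap + 1
            end = start + length - 1
            gene_rows.append((f"gene{gene_idx + 1:05d}", chrom, start, end))
            gene_idx += 1
            cursor = end
        tail_gap = int(rng.integers(config.intergenic_gap_bp[0], config.intergenic_gap_bp[1] + 1))
        spans.append(cursor + tail_gap)

    if config.n_genes == 0:
        # no genes anywhere: give every chromosome room for its SNP share
        per = -(-snps_total // config.n_chromosomes)
        spans = [max(s, per * 1000) for s in spans]

    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chromosome", "start", "end"])

    snps_per_chrom = _split_counts(snps_total, config.n_chromosomes, np.asarray(spans, dtype=float))
    snp_rows = []
    snp_idx = 0
    for chrom, span, n_s in zip(chroms, spans, snps_per_chrom):
        if n_s > span:
            raise SizingError(
                f"cannot place {n_s} unique SNP positions in {span} bp on {chrom}"
            )
        positions = _sample_unique_positions(rng, span, n_s)
        for pos in positions:
            snp_rows.append((f"rs{snp_idx + 1:06d}", chrom, int(pos)))
            snp_idx += 1
    snp_map = pd.DataFrame(snp_rows, columns=["snp_id", "chromosome", "position"])
    return genes, snp_map


def _sample_unique_positions(rng: np.random.Generator, span: int, n: int) -> np.ndarray:
    """Sorted unique uniform positions in [1, span]."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    chosen: np.ndarray = np.empty(0, dtype=np.int64)
    while chosen.size < n:
        draw = rng.integers(1, span + 1, size=2 * (n - chosen.size) + 16)
        chosen = np.unique(np.concatenate([chosen, draw]))
    # unique() sorts; trim deterministically by random subset to keep uniformity
    if chosen.size > n:
        keep = rng.choice(chosen.size, size=n, replace=False)
        chosen = chosen[np.sort(keep)]
    return chosen


def _block_slices(snp_map: pd.DataFrame, block_len: int):
    """Consecutive runs of ``block_len`` SNPs per chromosome (row slices)."""
    out = []
    for _, grp in snp_map.groupby("chromosome", sort=False):
        idx = grp.index.to_numpy()
        for i in range(0, len(idx), block_len):
            out.append(idx[i : i + block_len])
    return out


def make_ld_table(snp_map: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Pairwise LD table implied by the block structure.

    All within-block pairs get r^2 = ``within_block_r2``; cross-block pairs
    are absent (implicitly r^2 = 0).  Columns ``chromosome``,
    ``position_a`` < ``position_b``, ``r_squared``; one row per pair.
    """
    if snp_map.empty:
        raise ValueError("snp_map must be non-empty")
    rows = []
    for block in _block_slices(snp_map, config.ld_block_len):
        sub = snp_map.loc[block]
        pos = sub["position"].to_numpy()
        chrom = sub["chromosome"].iloc[0]
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                a, b = sorted((int(pos[i]), int(pos[j])))
                rows.append((chrom, a, b, config.within_block_r2))
    return pd.DataFrame(rows, columns=["chromosome", "position_a", "position_b", "r_squared"])


def _copy_fidelity(config: SimConfig) -> float:
    """Per-allele anchor-copy probability c.

    A non-anchor allele copies the anchor allele with probability c and is
    redrawn fresh otherwise, so corr(anchor, copy) = c at the allele level
    and genotype r^2 is c^2 for anchor-copy pairs and c^4 for copy-copy
    pairs.  c solves mean within-block pairwise r^2 = within_block_r2 for a
    full block of ``ld_block_len`` SNPs.
    """
    L = config.ld_block_len
    r2 = config.within_block_r2
    if L < 2 or r2 <= 0:
        return 0.0 if r2 <= 0 else 1.0
    a = L - 1  # anchor-copy pairs
    b = a * (a - 1) // 2  # copy-copy pairs
    target = (a + b) * r2
    if b == 0:
        u = min(1.0, target / a)
    else:
        u = (-a + np.sqrt(a * a + 4 * b * target)) / (2 * b)
    return float(np.sqrt(min(1.0, u)))


def make_genotypes(
    snp_map: pd.DataFrame, ld_table: pd.DataFrame, config: SimConfig
) -> GenotypeMatrix:
    """Genotype calls for the discovery cohort under the block LD model.

    Within each block the first SNP is the anchor, drawn Binomial(2, MAF);
    the others copy each anchor allele with probability ``c`` (see
    :func:`_copy_fidelity`) and are redrawn from Bernoulli(MAF) otherwise,
    preserving allele frequency while inducing the target pairwise r^2.
    MAFs are drawn uniformly from ``maf_range`` per block.
    """
    rng = stage_rng(config.master_seed, "genotypes")
    n = config.n_individuals
    calls = np.empty((n, len(snp_map)), dtype=np.int8)
    c = _copy_fidelity(config)
    for block in _block_slices(snp_map, config.ld_block_len):
        maf = rng.uniform(*config.maf_range)
        anchor_alleles = rng.random((n, 2)) < maf  # two alleles per individual
        calls[:, block[0]] = anchor_alleles.sum(axis=1)
        for col in block[1:]:
            keep = rng.random((n, 2)) < c
            fresh = rng.random((n, 2)) < maf
            alleles = np.where(keep, anchor_alleles, fresh)
            calls[:, col] = alleles.sum(axis=1)
    return GenotypeMatrix(calls, snp_map.reset_index(drop=True))


def designate_causal_snps(
    snp_map: pd.DataFrame, genes: pd.DataFrame, causal_genes
) -> dict[str, str]:
    """One designated causal SNP per causal gene: the SNP inside the gene
    body closest to the gene midpoint (deterministic).

    Raises ``ValueError`` if a causal gene contains no SNP.
    """
    out: dict[str, str] = {}
    gsub = genes.set_index("gene_id")
    for gid in causal_genes:
        if gid not in gsub.index:
            raise ValueError(f"causal gene {gid!r} not in annotation")
        row = gsub.loc[gid]
        inside = snp_map[
            (snp_map["chromosome"] == row["chromosome"])
            & (snp_map["position"] >= row["start"])
            & (snp_map["position"] <= row["end"])
        ]
        if inside.empty:
            raise ValueError(f"causal gene {gid!r} contains no SNP")
        mid = (row["start"] + row["end"]) / 2
        best = inside.iloc[(inside["position"] - mid).abs().argsort(kind="stable").iloc[0]]
        out[gid] = str(best["snp_id"])
    return out


def select_causal_genes(
    snp_map: pd.DataFrame, genes: pd.DataFrame, config: SimConfig
) -> list[str]:
    """Draw ``n_causal_genes`` genes uniformly among genes that contain at
    least one SNP in their body (so a causal SNP can be designated)."""
    rng = stage_rng(config.master_seed, "causal-genes")
    eligible = []
    for _, grp in genes.groupby("chromosome", sort=False):
        sub = snp_map[snp_map["chromosome"] == grp["chromosome"].iloc[0]]
        pos = np.sort(sub["position"].to_numpy())
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        has_snp = np.searchsorted(pos, ends, side="right") > np.searchsorted(pos, starts, side="left")
        eligible.extend(grp.loc[has_snp, "gene_id"].tolist())
    if len(eligible) < config.n_causal_genes:
        raise SizingError(
            f"only {len(eligible)} genes contain a SNP; cannot pick {config.n_causal_genes} causal genes"
        )
    pick = rng.choice(len(eligible), size=config.n_causal_genes, replace=False)
    return [eligible[i] for i in np.sort(pick)]


def select_shared_genes(causal_genes, config: SimConfig) -> list[str]:
    """The subset of discovery causal genes that are also causal in the
    target GWAS: round(shared_fraction * n_causal) genes, drawn
    deterministically from the master seed."""
    k = config.n_shared_genes
    rng = stage_rng(config.master_seed, "shared-genes")
    causal_genes = list(causal_genes)
    pick = rng.choice(len(causal_genes), size=k, replace=False) if k else np.empty(0, int)
    return [causal_genes[i] for i in np.sort(pick)]


def make_cognitive_phenotype(
    genotypes: GenotypeMatrix,
    genes: pd.DataFrame,
    causal_genes,
    config: SimConfig,
    stage: str = "phenotype",
) -> pd.DataFrame:
    """Quantitative phenotype with additive genetics, covariates and noise.

    phenotype = beta * sum(causal genotype) + age and sex effects + N(0, 1)
    noise, with beta scaled so the genetic variance fraction (genetic /
    (genetic + noise)) matches ``config.heritability``.  Age is uniform on
    18..79 years, sex Bernoulli(1/2).  Returns a table with columns
    ``individual``, ``phenotype``, ``age``, ``sex``.
    """
    if config.heritability >= 1.0:
        raise ValueError("heritability must be < 1 (noise-free phenotypes are not modelled)")
    rng = stage_rng(config.master_seed, stage)
    n = genotypes.n_individuals
    # age and sex belong to the cohort, not the trait: one draw per master
    # seed so every trait phenotyped on the cohort shares the covariates
    cov_rng = stage_rng(config.master_seed, "covariates")
    age = cov_rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1, size=n)
    sex = cov_rng.integers(0, 2, size=n)
    noise = rng.standard_normal(n)

    causal_genes = list(causal_genes)
    if causal_genes and config.heritability > 0:
        snp_of = designate_causal_snps(genotypes.snp_map, genes, causal_genes)
        col_of = {s: i for i, s in enumerate(genotypes.snp_ids)}
        cols = [col_of[snp_of[g]] for g in causal_genes]
        g_sum = genotypes.calls[:, cols].astype(float).sum(axis=1)
        var_g = g_sum.var()
        if var_g <= 0:
            raise ValueError("causal genotypes are constant; cannot scale heritability")
        h = config.heritability
        beta = np.sqrt(h / ((1.0 - h) * var_g))  # noise variance is 1
        genetic = beta * g_sum
    else:
        genetic = np.zeros(n)

    phenotype = genetic + AGE_EFFECT * age + SEX_EFFECT * sex + noise
    return pd.DataFrame(
        {
            "individual": [f"ind{i + 1:05d}" for i in range(n)],
            "phenotype": phenotype,
            "age": age.astype(int),
            "sex": sex.astype(int),
        }
    )


def make_target_summary(
    snp_map: pd.DataFrame,
    genes: pd.DataFrame,
    shared_causal_genes,
    config: SimConfig,
    stage: str = "target-summary",
) -> pd.DataFrame:
    """Target case-control GWAS as summary statistics.

    Non-associated SNPs get p ~ Uniform(0, 1]; the designated causal SNP of
    every shared causal gene gets the upper-tail p of a draw from a 1-df
    non-central chi-square with non-centrality ``target_ncp``.  Columns
    ``snp_id``, ``chromosome``, ``position``, ``p_value``.
    """
    rng = stage_rng(config.master_seed, stage)
    n = len(snp_map)
    p = 1.0 - rng.random(n)  # uniform on (0, 1]
    shared = list(shared_causal_genes)
    if shared and config.target_ncp > 0:
        snp_of = designate_causal_snps(snp_map, genes, shared)
        idx_of = {s: i for i, s in enumerate(snp_map["snp_id"])}
        cols = np.array([idx_of[snp_of[g]] for g in shared], dtype=int)
        z = rng.standard_normal(len(cols)) + np.sqrt(config.target_ncp)
        stat = z * z
        p[cols] = np.maximum(stats.chi2.sf(stat, df=1), 1e-300)
    out = snp_map.copy()
    out["p_value"] = p
    return out
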