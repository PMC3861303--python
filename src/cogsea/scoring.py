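"""LD-aware SNP-to-gene binning and Sidak min-p gene scoring.

A SNP is assigned to a gene when its position falls inside the gene's
extended boundaries (gene body +/- ``flank_bp``), or when a pairwise-LD
record links the SNP, at r^2 >= ``r2_min``, to any position inside those
boundaries.  A gene's score is the minimum SNP p-value in its bin, Sidak-
corrected for the bin's SNP count (1 - (1 - p)^n), -log10 transformed, and
genes are ranked from smallest to largest Sidak p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .config import BinningConfig

logger = logging.getLogger(__name__)

__all__ = [
    "extend_boundaries",
    "bin_snps",
    "GeneBins",
    "sidak_adjust",
    "score_genes",
    "rank_genes",
]


@dataclass
class GeneBins:
    """SNP membership per gene: mapping gene_id -> sorted tuple of snp_ids.

    Only genes with at least one assigned SNP appear.
    """

    bins: dict[str, tuple[str, ...]]

    def n_snps(self, gene_id: str) -> int:
        return len(self.bins[gene_id])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.bins),
                "n_snps": [len(v) for v in self.bins.values()],
                "snp_ids": [";".join(v) for v in self.bins.values()],
            }
        )

    def __len__(self) -> int:
        return len(self.bins)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.bins

    def __getitem__(self, gene_id: str) -> tuple[str, ...]:
        return self.bins[gene_id]


def extend_boundaries(genes: pd.DataFrame, config: BinningConfig | None = None) -> pd.DataFrame:
    """Extend every gene interval by ``flank_bp`` on both sides (strand
    ignored), clipping the start at 1.  1-based inclusive coordinates."""
    config = config or BinningConfig()
    out = genes.copy()
    out["start"] = np.maximum(1, genes["start"].astype(int) - config.flank_bp)
    out["end"] = genes["end"].astype(int) + config.flank_bp
    return out


def bin_snps(
    snp_map: pd.DataFrame,
    genes: pd.DataFrame,
    ld_table: pd.DataFrame | None = None,
    config: BinningConfig | None = None,
) -> GeneBins:
    """Assign SNPs to genes by extended position and LD tagging.

    The LD table is treated as symmetric and matched at the position level:
    a SNP is pulled into a gene's bin when either of an LD pair's positions
    is the SNP and the partner position lies inside the extended gene.
    Genes with zero assigned SNPs are omitted.
    """
    config = config or BinningConfig()
    extended = extend_boundaries(genes, config)

    trees: dict[str, IntervalTree] = {}
    for chrom, grp in extended.groupby("chromosome", sort=False):
        tree = IntervalTree()
        for row in grp.itertuples(index=False):
            # half-open tree interval [start, end+1) covers the inclusive range
            tree.addi(int(row.start), int(row.end) + 1, row.gene_id)
        trees[str(chrom)] = tree

    assigned: dict[str, set[str]] = {}

    def assign(snp_id: str, chrom: str, pos: int) -> None:
        tree = trees.get(chrom)
        if tree is None:
            return
        for iv in tree.at(pos):
            assigned.setdefault(iv.data, set()).add(snp_id)

    snp_at: dict[tuple[str, int], str] = {}
    for row in snp_map.itertuples(index=False):
        chrom, pos = str(row.chromosome), int(row.position)
        snp_at[(chrom, pos)] = str(row.snp_id)
        assign(str(row.snp_id), chrom, pos)

    if ld_table is not None and len(ld_table):
        known_chroms = set(snp_map["chromosome"].astype(str)) | set(
            genes["chromosome"].astype(str)
        )
        strong = ld_table[ld_table["r_squared"] >= config.r2_min]
        for row in strong.itertuples(index=False):
            chrom = str(row.chromosome)
            if chrom not in known_chroms:
                logger.warning("LD pair on unknown chromosome %s skipped", chrom)
                continue
            a, b = int(row.position_a), int(row.position_b)
            snp_a = snp_at.get((chrom, a))
            snp_b = snp_at.get((chrom, b))
            if snp_a is not None:
                assign(snp_a, chrom, b)  # partner position inside a gene tags snp_a
            if snp_b is not None:
                assign(snp_b, chrom, a)

    return GeneBins({g: tuple(sorted(s)) for g, s in sorted(assigned.items())})


def sidak_adjust(p_min, n):
    """Sidak-corrected minimum p-value: 1 - (1 - p_min)^n.

    Computed as -expm1(n * log1p(-p_min)), numerically stable down to
    p_min ~ 1e-300 and n up to ~1e5.  Accepts scalars or arrays.
    """
    p = np.asarray(p_min, dtype=float)
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ValueError("n must be >= 1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_min must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.expm1(n_arr * np.log1p(-p))
    out = np.where(p >= 1.0, 1.0, out)
    if np.ndim(p_min) == 0 and np.ndim(n) == 0:
        return float(out)
    return out


def score_genes(summary: pd.DataFrame, bins: GeneBins) -> pd.DataFrame:
    """Sidak min-p gene scores from per-SNP p-values.

    ``summary`` needs columns ``snp_id`` and ``p_value`` (a GWAS result or
    published summary statistics).  Bin SNPs absent from the summary are
    dropped (with a warning) and the bin size updated; genes whose bins
    empty out are dropped.  Returns gene_id, n_snps, p_min, sidak_p, score.
    """
    table = summary.loc[np.isfinite(summary["p_value"].to_numpy(dtype=float))]
    p_of = dict(zip(table["snp_id"].astype(str), table["p_value"].astype(float)))
    rows = []
    n_dropped = 0
    for gene_id, snp_ids in bins.bins.items():
        pvals = [p_of[s] for s in snp_ids if s in p_of]
        n_dropped += len(snp_ids) - len(pvals)
        if not pvals:
            continue
        p_min = float(min(pvals))
        n_snps = len(pvals)
        sidak_p = sidak_adjust(p_min, n_snps)
        if sidak_p > 0:
            score = -np.log10(sidak_p)
        else:  # extreme underflow; first-order Sidak ~ n * p_min
            score = -(np.log10(n_snps) + np.log10(max(p_min, 1e-320)))
        rows.append((gene_id, n_snps, p_min, sidak_p, score))
    if n_dropped:
        logger.warning("%d bin SNPs absent from the summary table were dropped", n_dropped)
    if not rows:
        raise ValueError("no bin SNP appears in the summary table")
    return pd.DataFrame(rows, columns=["gene_id", "n_snps", "p_min", "sidak_p", "score"])


def rank_genes(scores: pd.DataFrame) -> pd.DataFrame:
    """Rank genes from smallest to largest Sidak p (ties broken by gene_id).

    Returns columns ``rank`` (1-based), ``gene_id``, ``score``, ``sidak_p``,
    ``n_snps``; order is invariant to input row order.
    """
    if scores.empty:
        raise ValueError("no gene scores to rank")
    if scores["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_ids in score table")
    out = scores.sort_values(
        ["sidak_p", "gene_id"], ascending=[True, True], kind="stable"
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    cols = ["rank", "gene_id", "score", "sidak_p"]
    cols += [c for c in ("p_min", "n_snps") if c in out.columns]
    return out[cols]
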