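"""Candidate gene-set construction, mimic random sets and LD pruning.

Nested top-K sets take the K best-ranked genes per trait at each threshold
(default 25..2000, 11 thresholds).  Mimic sets replace every candidate gene
with a random non-candidate gene from the same SNP-count quantile bin,
matching the candidate on set size and per-gene SNP count; they serve as an
empirical validation null.  LD pruning greedily removes genes that share a
binned SNP with a better-ranked retained gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SetBuildConfig, ValidationConfig
from .containers import GeneSet, GeneSetCollection
from .io import read_gmt, write_gmt  # re-exported GMT round-trip
from .scoring import GeneBins

__all__ = [
    "build_nested_sets",
    "make_mimic_sets",
    "ld_prune_gene_set",
    "load_housekeeping_sets",
    "read_gmt",
    "write_gmt",
]


def load_housekeeping_sets() -> GeneSetCollection:
    """The packaged synthetic housekeeping negative-control collection.

    Evenly spaced gene ids of the default synthetic genome standing in for
    a broadly-expressed, trait-agnostic housekeeping list; an ordinary GMT
    input with no special code path.
    """
    from importlib.resources import files

    return read_gmt(files("cogsea").joinpath("data/housekeeping_synthetic.gmt"))


def build_nested_sets(
    ranked: pd.DataFrame,
    config: SetBuildConfig | None = None,
    trait_label: str = "trait",
) -> GeneSetCollection:
    """One set per threshold K holding the K top-ranked genes.

    Sets are named ``{trait_label}-{K}`` and are nested by construction.
    When K exceeds the ranked list length the set is capped at the full
    list and flagged ``capped``.
    """
    config = config or SetBuildConfig()
    if ranked.empty:
        raise ValueError("ranked gene list is empty")
    gene_ids = ranked.sort_values("rank")["gene_id"].astype(str).tolist()
    coll = GeneSetCollection()
    for k in config.thresholds:
        capped = k > len(gene_ids)
        genes = tuple(gene_ids[:k])
        coll.add(
            GeneSet(
                f"{trait_label}-{k}",
                genes,
                description=f"{trait_label} top {k}" + (" (capped)" if capped else ""),
                capped=capped,
            )
        )
    return coll


def make_mimic_sets(
    candidate: GeneSet,
    bins: GeneBins,
    config: ValidationConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> GeneSetCollection:
    """SNP-count-matched random sets mimicking a candidate set.

    Quantile bins (default deciles) of the per-gene SNP count are computed
    over all scored genes; each candidate gene is replaced by a uniform draw
    (without replacement within one mimic set) from non-candidate genes in
    the same bin.  Deterministic given ``seed``.
    """
    config = config or ValidationConfig()
    rng = np.random.default_rng(seed)
    universe = list(bins.bins)
    counts = np.array([len(bins.bins[g]) for g in universe])
    missing = [g for g in candidate.genes if g not in bins]
    if missing:
        raise ValueError(f"candidate genes absent from the bin table: {missing[:5]}")

    edges = np.quantile(counts, np.linspace(0, 1, config.snp_count_bins + 1))
    edges = np.unique(edges)
    # digitize into 1..len(edges)-1; clip so max count lands in the top bin
    which = np.clip(np.searchsorted(edges, counts, side="right") - 1, 0, len(edges) - 2)
    bin_of = dict(zip(universe, which))
    cand = set(candidate.genes)
    avail: dict[int, list[str]] = {}
    for g, b in zip(universe, which):
        if g not in cand:
            avail.setdefault(int(b), []).append(g)

    need: dict[int, int] = {}
    for g in candidate.genes:
        need[int(bin_of[g])] = need.get(int(bin_of[g]), 0) + 1
    for b, k in need.items():
        if len(avail.get(b, ())) < k:
            lo, hi = edges[b], edges[b + 1]
            raise ValueError(
                f"SNP-count bin {b} (counts in [{lo:g}, {hi:g}]) has "
                f"{len(avail.get(b, ()))} available genes but {k} are needed"
            )

    coll = GeneSetCollection()
    for i in range(config.n_mimic):
        picked: list[str] = []
        draws = {
            b: rng.choice(len(avail[b]), size=k, replace=False) for b, k in sorted(need.items())
        }
        cursor = {b: 0 for b in need}
        for g in candidate.genes:
            b = int(bin_of[g])
            j = draws[b][cursor[b]]
            cursor[b] += 1
            picked.append(avail[b][j])
        coll.add(
            GeneSet(
                f"{candidate.name}|mimic{i + 1:03d}",
                tuple(picked),
                description=f"mimic of {candidate.name}",
            )
        )
    return coll


def ld_prune_gene_set(
    gene_set: GeneSet, bins: GeneBins, ranked: pd.DataFrame
) -> tuple[GeneSet, pd.DataFrame]:
    """Greedy rank-order LD pruning of a gene set.

    Genes are visited from best to worst rank; a gene is removed when it
    shares at least one binned SNP with a better-ranked *retained* gene.
    Returns the pruned set (rank order preserved) and a report table
    (gene, kept flag, removed_because_of).
    """
    rank_of = dict(zip(ranked["gene_id"].astype(str), ranked["rank"].astype(int)))
    missing = [g for g in gene_set.genes if g not in rank_of or g not in bins]
    if missing:
        raise ValueError(f"set genes absent from bins or ranked list: {missing[:5]}")
    ordered = sorted(gene_set.genes, key=lambda g: rank_of[g])
    kept: list[str] = []
    kept_snps: dict[str, set[str]] = {}
    rows = []
    for g in ordered:
        snps = set(bins[g])
        blocker = next((k for k in kept if snps & kept_snps[k]), None)
        if blocker is None:
            kept.append(g)
            kept_snps[g] = snps
            rows.append((g, True, ""))
        else:
            rows.append((g, False, blocker))
    report = pd.DataFrame(rows, columns=["gene_id", "kept", "removed_because_of"])
    pruned = GeneSet(
        gene_set.name, tuple(kept), description=gene_set.description, capped=gene_set.capped
    )
    return pruned, report
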