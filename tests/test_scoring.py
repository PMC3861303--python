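"""Gene binning and Sidak min-p scoring: positional and LD assignment
(including a brute-force cross-check), numerical stability of the Sidak
form, and ranking semantics."""

from __future__ import annotations

from decimal import Decimal, getcontext

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogsea.config import BinningConfig
from cogsea.scoring import (
    bin_snps,
    extend_boundaries,
    rank_genes,
    score_genes,
    sidak_adjust,
)


def genes_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])


def snps_frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position"])


def ld_frame(rows):
    return pd.DataFrame(rows, columns=["chromosome", "position_a", "position_b", "r_squared"])


class TestExtendBoundaries:
    @pytest.mark.parametrize(
        "start,end,flank,expected",
        [(1000, 2000, 10000, (1, 12000)),
         (1000, 2000, 0, (1000, 2000)),
         (50000, 60000, 10000, (40000, 70000))],
    )
    def test_examples(self, start, end, flank, expected):
        genes = genes_frame([("g", "chr1", start, end)])
        out = extend_boundaries(genes, BinningConfig(flank_bp=flank))
        assert (out["start"].iloc[0], out["end"].iloc[0]) == expected


class TestBinSnps:
    def setup_method(self):
        self.genes = genes_frame([("gA", "chr1", 100000, 120000)])

    def test_positional_assignment(self):
        snps = snps_frame([("rs1", "chr1", 110000)])
        bins = bin_snps(snps, self.genes, None, BinningConfig())
        assert bins["gA"] == ("rs1",)

    def test_ld_tagging_pulls_in_distant_snp(self):
        # SNP 15 kb past the gene end, linked at r2=0.9 to a mid-gene position
        snps = snps_frame([("rs1", "chr1", 135000)])
        ld = ld_frame([("chr1", 110000, 135000, 0.9)])
        bins = bin_snps(snps, self.genes, ld, BinningConfig())
        assert "gA" in bins and bins["gA"] == ("rs1",)

    def test_ld_below_threshold_not_assigned(self):
        snps = snps_frame([("rs1", "chr1", 135000)])
        ld = ld_frame([("chr1", 110000, 135000, 0.5)])
        bins = bin_snps(snps, self.genes, ld, BinningConfig())
        assert "gA" not in bins

    def test_r2_threshold_inclusive(self):
        snps = snps_frame([("rs1", "chr1", 135000)])
        ld = ld_frame([("chr1", 110000, 135000, 0.8)])
        assert "gA" in bin_snps(snps, self.genes, ld, BinningConfig())

    def test_snp_in_overlap_lands_in_both_bins(self):
        genes = genes_frame(
            [("gA", "chr1", 100000, 120000), ("gB", "chr1", 125000, 140000)]
        )
        snps = snps_frame([("rs1", "chr1", 122000)])  # inside both extended intervals
        bins = bin_snps(snps, genes, None, BinningConfig())
        assert bins["gA"] == ("rs1",) and bins["gB"] == ("rs1",)

    def test_unknown_chromosome_ld_pair_skipped(self, caplog):
        snps = snps_frame([("rs1", "chr1", 135000)])
        ld = ld_frame([("chrX", 110000, 135000, 0.9)])
        with caplog.at_level("WARNING"):
            bins = bin_snps(snps, self.genes, ld, BinningConfig())
        assert "gA" not in bins
        assert any("unknown chromosome" in r.message for r in caplog.records)

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            genes = genes_frame(
                [(f"g{i}", f"chr{1 + i % 2}",
                  int(s := rng.integers(1, 500000)), int(s + rng.integers(1000, 40000)))
                 for i in range(20)]
            )
            snps = snps_frame(
                [(f"rs{i}", f"chr{1 + rng.integers(0, 2)}", int(rng.integers(1, 550000)))
                 for i in range(200)]
            )
            ld_rows = []
            for _ in range(100):
                chrom = f"chr{1 + rng.integers(0, 2)}"
                # half the pairs anchor at a genotyped SNP position
                same = snps[snps["chromosome"] == chrom]
                if len(same) and rng.random() < 0.5:
                    a = int(same.sample(1, random_state=int(rng.integers(1e9)))["position"].iloc[0])
                else:
                    a = int(rng.integers(1, 550000))
                b = int(rng.integers(1, 550000))
                if a == b:
                    continue
                ld_rows.append((chrom, min(a, b), max(a, b), float(rng.random())))
            ld = ld_frame(ld_rows)
            cfg = BinningConfig(flank_bp=10000, r2_min=0.8)
            bins = bin_snps(snps, genes, ld, cfg)
            expected = _brute_force_bins(snps, genes, ld, cfg)
            assert {g: set(v) for g, v in bins.bins.items()} == expected, f"trial {trial}"


def _brute_force_bins(snps, genes, ld, cfg):
    out: dict[str, set[str]] = {}
    for g in genes.itertuples(index=False):
        lo, hi = max(1, g.start - cfg.flank_bp), g.end + cfg.flank_bp
        for s in snps.itertuples(index=False):
            if s.chromosome != g.chromosome:
                continue
            inside = lo <= s.position <= hi
            tagged = False
            for r in ld.itertuples(index=False):
                if r.chromosome != s.chromosome or r.r_squared < cfg.r2_min:
                    continue
                if r.position_a == s.position and lo <= r.position_b <= hi:
                    tagged = True
                if r.position_b == s.position and lo <= r.position_a <= hi:
                    tagged = True
            if inside or tagged:
                out.setdefault(g.gene_id, set()).add(s.snp_id)
    return out


class TestSidak:
    def test_identity_at_n_one(self):
        assert sidak_adjust(0.05, 1) == pytest.approx(0.05, abs=1e-15)

    def test_zero_p(self):
        assert sidak_adjust(0.0, 1000) == 0.0

    def test_worked_example(self):
        # 1 - 0.99^10, high-precision oracle via Decimal
        getcontext().prec = 40
        expected = float(1 - Decimal("0.99") ** 10)
        assert sidak_adjust(0.01, 10) == pytest.approx(expected, abs=1e-15)
        assert f"{sidak_adjust(0.01, 10):.7f}" == "0.0956179"

    def test_extreme_stability(self):
        # tiny p with large n: 1-(1-p)^n ~ n*p
        assert sidak_adjust(1e-300, 10**5) == pytest.approx(1e-295, rel=1e-10)

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            sidak_adjust(0.5, 0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.floats(min_value=1e-12, max_value=1.0, exclude_max=False),
        st.integers(min_value=1, max_value=10**5),
    )
    def test_monotone_and_bounded(self, p, n):
        v = sidak_adjust(p, n)
        assert p - 1e-15 <= v <= 1.0
        assert v <= sidak_adjust(p, n + 1) + 1e-15  # monotone in n
        if p < 0.999:
            assert v <= sidak_adjust(min(1.0, p * 1.001), n) + 1e-12  # monotone in p


class TestScoreAndRank:
    def _summary(self, pvals: dict[str, float]):
        return pd.DataFrame(
            {"snp_id": list(pvals), "p_value": list(pvals.values())}
        )

    def test_single_snp_gene_score_is_p(self):
        from cogsea.scoring import GeneBins

        bins = GeneBins({"g": ("rs1",)})
        out = score_genes(self._summary({"rs1": 0.03}), bins)
        assert out["sidak_p"].iloc[0] == pytest.approx(0.03, abs=1e-15)

    def test_three_snp_worked_example(self):
        from cogsea.scoring import GeneBins

        bins = GeneBins({"g": ("rs1", "rs2", "rs3")})
        out = score_genes(self._summary({"rs1": 0.4, "rs2": 0.01, "rs3": 0.2}), bins)
        row = out.iloc[0]
        assert row["p_min"] == 0.01 and row["n_snps"] == 3
        assert row["sidak_p"] == pytest.approx(1 - 0.99**3, abs=1e-12)  # 0.029701

    def test_shared_minimum_snp_two_genes(self):
        from cogsea.scoring import GeneBins

        bins = GeneBins({"gA": ("rs1", "rs2"), "gB": ("rs1", "rs2", "rs3")})
        out = score_genes(
            self._summary({"rs1": 0.005, "rs2": 0.5, "rs3": 0.9}), bins
        ).set_index("gene_id")
        assert out.loc["gA", "p_min"] == out.loc["gB", "p_min"] == 0.005
        assert out.loc["gA", "sidak_p"] == pytest.approx(1 - 0.995**2, abs=1e-12)
        assert out.loc["gB", "sidak_p"] == pytest.approx(1 - 0.995**3, abs=1e-12)

    def test_missing_snp_dropped_and_n_updated(self):
        from cogsea.scoring import GeneBins

        bins = GeneBins({"g": ("rs1", "rs2", "rs_gone")})
        out = score_genes(self._summary({"rs1": 0.1, "rs2": 0.2}), bins)
        assert out["n_snps"].iloc[0] == 2

    def test_empty_intersection_errors(self):
        from cogsea.scoring import GeneBins

        bins = GeneBins({"g": ("rs_gone",)})
        with pytest.raises(ValueError):
            score_genes(self._summary({"rs1": 0.1}), bins)

    def test_rank_order_and_ties(self):
        scores = pd.DataFrame(
            {"gene_id": ["b", "a", "c"], "n_snps": [1, 1, 1],
             "p_min": [0.2, 0.2, 0.01], "sidak_p": [0.2, 0.2, 0.01],
             "score": [-np.log10(0.2)] * 2 + [-np.log10(0.01)]}
        )
        ranked = rank_genes(scores)
        assert list(ranked["gene_id"]) == ["c", "a", "b"]  # tie: lexicographic
        assert list(ranked["rank"]) == [1, 2, 3]
        # permutation invariance
        ranked2 = rank_genes(scores.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(ranked, ranked2)

    def test_duplicate_gene_ids_rejected(self):
        scores = pd.DataFrame(
            {"gene_id": ["a", "a"], "n_snps": [1, 1], "p_min": [0.1, 0.2],
             "sidak_p": [0.1, 0.2], "score": [1.0, 0.7]}
        )
        with pytest.raises(ValueError):
            rank_genes(scores)

    def test_binning_independent_of_pvalues(self):
        # permuting the p-value labels leaves (gene, n_snps) untouched
        from conftest import small_sim
        from cogsea.synthetic import make_genome, make_ld_table, make_target_summary

        cfg = small_sim()
        genes, snps = make_genome(cfg)
        ld = make_ld_table(snps, cfg)
        bins = bin_snps(snps, genes, ld, BinningConfig())
        summ = make_target_summary(snps, genes, [], cfg)
        shuffled = summ.copy()
        shuffled["p_value"] = (
            shuffled["p_value"].sample(frac=1, random_state=2).to_numpy()
        )
        a = score_genes(summ, bins)[["gene_id", "n_snps"]]
        b = score_genes(shuffled, bins)[["gene_id", "n_snps"]]
        pd.testing.assert_frame_equal(a, b)
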