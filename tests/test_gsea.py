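"""Enrichment statistics: running-sum ES against a brute-force oracle,
permutation-null enumeration, nominal p / NES / FDR q arithmetic, report
semantics and mimic validation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cogsea.config import GseaConfig, ValidationConfig
from cogsea.containers import GeneSet, GeneSetCollection
from cogsea.gsea import (
    RankedList,
    _es_from_positions,
    enrichment_score,
    fdr_q,
    mimic_validate,
    nominal_p,
    normalized_es,
    permutation_null,
    run_gsea,
)


def es_oracle(scores, member_mask, w=1.0):
    """Brute-force running sum; earliest position on |ES| ties."""
    N = len(scores)
    members = [i for i, m in enumerate(member_mask) if m]
    k = len(members)
    norm = sum(abs(scores[i]) ** w for i in members)
    run, vals = 0.0, []
    for i in range(N):
        if member_mask[i]:
            run += abs(scores[i]) ** w / norm
        else:
            run -= 1.0 / (N - k)
        vals.append(run)
    amax = max(abs(v) for v in vals)
    # earliest position whose magnitude ties the maximum (1e-9 relative)
    return next(v for v in vals if abs(v) >= amax * (1.0 - 1e-9))


def make_ranked(scores):
    return RankedList(np.array([f"g{i + 1}" for i in range(len(scores))]),
                      np.asarray(scores, dtype=float))


class TestEnrichmentScore:
    def test_lone_top_member(self):
        rl = make_ranked([4, 3, 2, 1])
        es, profile, le = enrichment_score(rl, GeneSet("s", ("g1",)))
        assert es == pytest.approx(1.0)
        assert le == ["g1"]

    def test_two_member_hand_traced(self):
        rl = make_ranked([4, 3, 2, 1])
        es, profile, le = enrichment_score(rl, GeneSet("s", ("g1", "g4")))
        np.testing.assert_allclose(profile, [0.8, 0.3, -0.2, 0.0], atol=1e-12)
        assert es == pytest.approx(0.8)
        assert le == ["g1"]

    def test_bottom_member_negative(self):
        rl = make_ranked([4, 3, 2, 1])
        es, profile, le = enrichment_score(rl, GeneSet("s", ("g4",)))
        np.testing.assert_allclose(profile, [-1 / 3, -2 / 3, -1.0, 0.0], atol=1e-12)
        assert es == pytest.approx(-1.0)
        assert le == ["g4"]

    def test_whole_list_set_rejected(self):
        rl = make_ranked([3, 2, 1])
        with pytest.raises(ValueError):
            enrichment_score(rl, GeneSet("s", ("g1", "g2", "g3")))

    def test_zero_weight_members_rejected(self):
        rl = make_ranked([3, 2, 0, 0])
        with pytest.raises(ValueError):
            enrichment_score(rl, GeneSet("s", ("g3", "g4")))

    def test_matches_oracle_random_cases(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            N = int(rng.integers(3, 40))
            scores = np.sort(rng.uniform(0, 5, N))[::-1]
            k = int(rng.integers(1, N))
            members = rng.choice(N, size=k, replace=False)
            mask = np.zeros(N, bool)
            mask[members] = True
            if np.abs(scores[mask]).sum() == 0:
                continue
            rl = make_ranked(scores)
            es, _, _ = enrichment_score(rl, tuple(rl.gene_ids[mask]))
            assert es == pytest.approx(es_oracle(scores, mask), abs=1e-12)


class TestPermutationPathEquivalence:
    def test_null_es_equals_profile_es_at_same_positions(self):
        # the event-based permutation kernel must agree with the full profile
        rng = np.random.default_rng(5)
        scores = np.sort(rng.exponential(1, 60))[::-1]
        rl = make_ranked(scores)
        cfg = GseaConfig(n_permutations=200, seed=3)
        for k in (1, 2, 7, 30, 59):
            members = np.arange(k)
            perms = np.argsort(rng.random((50, 60)), axis=1).astype(np.int32)
            null = permutation_null(rl, tuple(rl.gene_ids[members]), cfg, perms=perms)
            for row in range(50):
                pos = np.sort(perms[row, members])
                mask = np.zeros(60, bool)
                mask[pos] = True
                assert null[row] == pytest.approx(es_oracle(scores, mask), abs=1e-12)

    def test_vectorized_fallback_matches_oracle(self):
        rng = np.random.default_rng(9)
        scores = np.sort(rng.uniform(0.1, 4, 30))[::-1]
        for k in (1, 3, 10, 29):
            pos = np.sort(
                np.array([rng.choice(30, size=k, replace=False) for _ in range(40)]), axis=1
            )
            w = np.abs(scores[pos])
            out = _es_from_positions(pos, w, 30)
            for row in range(40):
                mask = np.zeros(30, bool)
                mask[pos[row]] = True
                assert out[row] == pytest.approx(es_oracle(scores, mask), abs=1e-12)

    def test_deterministic_given_seed(self):
        rl = make_ranked(np.linspace(5, 0.1, 40))
        cfg = GseaConfig(n_permutations=1, seed=11)
        a = permutation_null(rl, ("g3", "g10"), cfg)
        b = permutation_null(rl, ("g3", "g10"), cfg)
        assert a == b

    def test_singleton_null_support_enumerable(self):
        # set of size 1 on scores (2,1,1): null ES support has 3 values with
        # equal probability; check empirical frequencies over 3000 draws
        scores = [2.0, 1.0, 1.0]
        rl = make_ranked(scores)
        support = []
        for pos in range(3):
            mask = np.zeros(3, bool)
            mask[pos] = True
            support.append(round(es_oracle(scores, mask), 12))
        cfg = GseaConfig(n_permutations=3000, seed=2)
        null = np.round(permutation_null(rl, ("g1",), cfg), 12)
        freqs = {v: float((null == v).mean()) for v in set(support)}
        assert set(np.unique(null)) <= set(support)
        for v, f in freqs.items():
            assert abs(f - 1 / 3) < 0.033  # ~3.8 sigma binomial tolerance

    def test_null_mean_small(self):
        rl = make_ranked(np.linspace(4, 0.1, 200))
        cfg = GseaConfig(n_permutations=1000, seed=4)
        null = permutation_null(rl, tuple(f"g{i}" for i in range(1, 21)), cfg)
        assert abs(null.mean()) < 0.5  # small relative to the |ES| <= 1 bound


class TestNominalP:
    def test_arithmetic(self):
        null = np.linspace(0, 1, 1000)  # 50 of 1000 values >= 0.95; all >= 0
        p, flag = nominal_p(0.95, null)
        assert p == pytest.approx(50 / 1000)
        assert not flag

    def test_below_resolution_flag(self):
        null = np.linspace(0, 0.5, 1000)
        p, flag = nominal_p(0.9, null)
        assert p == 0.0 and flag

    def test_boundary_p_one(self):
        null = np.linspace(0.2, 0.8, 100)
        p, flag = nominal_p(0.0, null)
        assert p == 1.0 and not flag

    def test_negative_side(self):
        null = np.array([-0.5, -0.4, -0.1, 0.2, 0.3])
        p, _ = nominal_p(-0.45, null)
        assert p == pytest.approx(1 / 3)

    def test_no_same_sign_errors(self):
        with pytest.raises(ValueError):
            nominal_p(-0.5, np.array([0.1, 0.2]))


class TestNes:
    def test_positive(self):
        null = np.array([0.4, 0.4, -0.3])
        assert normalized_es(0.8, null) == pytest.approx(2.0)

    def test_identity(self):
        null = np.array([0.5, 0.5])
        assert normalized_es(0.5, null) == pytest.approx(1.0)

    def test_negative_sign_preserved(self):
        null = np.array([-0.3, -0.3, 0.9])
        assert normalized_es(-0.6, null) == pytest.approx(-2.0)


class TestFdrQ:
    def test_worked_example(self):
        obs = np.array([2.0, 1.0])
        pool = np.array([0.5, 1.0, 1.5, 2.5])
        q = fdr_q(obs, pool)
        assert q[0] == pytest.approx(0.5)
        assert q[1] == pytest.approx(0.75)

    def test_boundary_zero(self):
        q = fdr_q(np.array([3.0, 1.0]), np.array([0.5, 1.0, 1.5, 2.5]))
        assert q[0] == 0.0

    def test_identical_observed_identical_q(self):
        q = fdr_q(np.array([1.2, 1.2, 1.2]), np.array([0.5, 1.0, 1.5]))
        assert len(set(np.round(q, 12))) == 1


class TestRunGsea:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.exponential(1, 150))[::-1]
        rl = make_ranked(scores)
        coll = GeneSetCollection()
        for i in range(8):
            genes = rng.choice(rl.gene_ids, size=12, replace=False)
            coll.add(GeneSet(f"s{i}", tuple(genes)))
        return rl, coll

    def test_deterministic(self):
        rl, coll = self._setup()
        cfg = GseaConfig(n_permutations=100, n_runs=2, seed=9)
        a = run_gsea(rl, coll, cfg)
        b = run_gsea(rl, coll, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_enriched_requires_both_thresholds(self):
        rl, coll = self._setup()
        report = run_gsea(rl, coll, GseaConfig(n_permutations=100, n_runs=2, seed=1))
        expect = (report["p_nominal"] <= 0.05) & (report["q_fdr_mean"] <= 0.25)
        assert (report["enriched"] == expect.fillna(False)).all()

    def test_rank_R_is_permutation(self):
        rl, coll = self._setup()
        report = run_gsea(rl, coll, GseaConfig(n_permutations=100, seed=2))
        assert sorted(report["rank_R"]) == list(range(1, len(report) + 1))

    def test_absent_members_dropped(self):
        rl, coll = self._setup()
        coll.add(GeneSet("with_ghosts", ("g1", "g2", "ghostA", "ghostB")))
        report = run_gsea(rl, coll, GseaConfig(n_permutations=50, seed=3))
        row = report.set_index("set_name").loc["with_ghosts"]
        assert row["set_size"] == 4 and row["effective_size"] == 2

    def test_degenerate_set_gets_nan_not_crash(self):
        rl, coll = self._setup()
        coll.add(GeneSet("one_member", ("g1",)))
        report = run_gsea(rl, coll, GseaConfig(n_permutations=50, seed=3))
        assert np.isnan(report.set_index("set_name").loc["one_member", "es"])

    def test_all_degenerate_errors(self):
        rl, _ = self._setup()
        coll = GeneSetCollection()
        coll.add(GeneSet("solo", ("g1",)))
        with pytest.raises(ValueError):
            run_gsea(rl, coll, GseaConfig(n_permutations=10))

    def test_nominal_p_calibration_under_null(self):
        # random sets on an exchangeable list: p approximately uniform
        rng = np.random.default_rng(31)
        scores = np.sort(rng.exponential(1, 300))[::-1]
        rl = make_ranked(scores)
        pvals = []
        for rep in range(60):
            coll = GeneSetCollection()
            genes = rng.choice(rl.gene_ids, size=15, replace=False)
            coll.add(GeneSet("s", tuple(genes)))
            rep_cfg = GseaConfig(n_permutations=200, n_runs=1, seed=1000 + rep)
            pvals.append(float(run_gsea(rl, coll, rep_cfg)["p_nominal"].iloc[0]))
        frac = np.mean(np.asarray(pvals) <= 0.2)
        assert 0.05 <= frac <= 0.4  # wide band: 60 draws at 200 permutations


class TestMimicValidate:
    def test_above_all(self):
        v, c = mimic_validate(3.0, np.linspace(0, 2, 100), ValidationConfig())
        assert v and c == 100

    def test_exactly_98_validated(self):
        mimics = np.concatenate([np.linspace(0, 1, 98), [5.0, 6.0]])
        v, c = mimic_validate(2.0, mimics, ValidationConfig())
        assert v and c == 98

    def test_97_not_validated(self):
        mimics = np.concatenate([np.linspace(0, 1, 97), [5.0, 6.0, 7.0]])
        v, c = mimic_validate(2.0, mimics, ValidationConfig())
        assert not v and c == 97

    def test_nan_mimics_excluded_with_warning(self):
        mimics = np.concatenate([np.linspace(0, 1, 99), [np.nan]])
        with pytest.warns(UserWarning):
            v, c = mimic_validate(2.0, mimics, ValidationConfig())
        assert v and c == 99
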