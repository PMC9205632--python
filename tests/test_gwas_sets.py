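"""GWAS-set procedures: LD utilities, clumping, proxies, the allelic
case-control test, pruning, and the two permutation tests."""

import numpy as np
import pandas as pd
import pytest

from immunoqtl import (
    GenotypeMatrix,
    SimulationConfig,
    case_control_allelic_test,
    clump_gwas_snps,
    enrichment_test,
    find_proxies,
    ld_prune,
    ld_r2,
    simulate_genotypes,
    variance_explained,
    variance_explained_test,
)
from immunoqtl.simulate import variant_table
from tests.conftest import make_records


def _matrix(d):
    d = np.asarray(d, dtype=float)
    cfg = SimulationConfig(n_snps=d.shape[1], ld_block_size=1, seed=0)
    return GenotypeMatrix(d, [f"s{i}" for i in range(d.shape[0])], variant_table(cfg))


class TestLdR2:
    def test_identical_vectors(self, rng):
        d = rng.binomial(2, 0.4, 50).astype(float)
        assert ld_r2(d, d) == pytest.approx(1.0)

    def test_orthogonal_by_construction(self):
        a = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        b = np.array([0, 2, 0, 2, 0, 2], dtype=float)
        assert ld_r2(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula_on_haplotype_pair(self, rng):
        # haplotypes with known D': alleles drawn jointly then summed
        pA, pB, D = 0.3, 0.4, 0.1
        probs = np.array(
            [pA * pB + D, pA * (1 - pB) - D, (1 - pA) * pB - D, (1 - pA) * (1 - pB) + D]
        )
        draws = rng.choice(4, size=(5000, 2), p=probs)
        a = (draws < 2).sum(axis=1).astype(float)
        b = ((draws == 0) | (draws == 2)).sum(axis=1).astype(float)
        r = np.corrcoef(a, b)[0, 1]
        assert ld_r2(a, b) == pytest.approx(r * r, abs=1e-12)

    def test_constant_vector_warns_zero(self, rng):
        with pytest.warns(UserWarning):
            assert ld_r2(np.ones(10), rng.binomial(2, 0.4, 10).astype(float)) == 0.0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            ld_r2([1.0, np.nan], [0.0, 1.0])


class TestClump:
    def test_correlated_pair_merged(self, rng):
        n = 400
        a = rng.binomial(2, 0.4, n).astype(float)
        b = np.where(rng.random(n) < 0.7, a, rng.binomial(2, 0.4, n)).astype(float)
        c = rng.binomial(2, 0.4, n).astype(float)
        assert ld_r2(a, b) > 0.1 and ld_r2(a, c) < 0.1
        m = _matrix(np.column_stack([a, b, c]))
        tops = pd.DataFrame(
            {"snp": ["snp000000", "snp000001", "snp000002"], "p": [1e-20, 1e-8, 1e-6]}
        )
        out = clump_gwas_snps(tops, m, r2_threshold=0.1)
        assert out["snp"].tolist() == ["snp000000", "snp000002"]
        assert "snp000001" in out["clump_members"].iloc[0]

    def test_independent_set_unchanged(self, rng):
        m = _matrix(rng.binomial(2, 0.4, size=(500, 4)))
        tops = pd.DataFrame({"snp": m.variants["snp"], "p": [1e-9, 1e-8, 1e-7, 1e-6]})
        out = clump_gwas_snps(tops, m)
        assert len(out) == 4

    def test_greedy_chain_matches_exhaustive_oracle(self, rng):
        # on <=10 SNPs, compare against an oracle that greedily assigns each
        # SNP (in p order) to the first lead with r2 above threshold
        n = 300
        base = rng.binomial(2, 0.4, size=(n, 6)).astype(float)
        base[:, 1] = np.where(rng.random(n) < 0.45, base[:, 0], base[:, 1])
        base[:, 2] = np.where(rng.random(n) < 0.45, base[:, 1], base[:, 2])
        m = _matrix(base)
        pvals = np.sort(rng.uniform(1e-12, 1e-6, 6))
        tops = pd.DataFrame({"snp": m.variants["snp"], "p": pvals})

        def oracle():
            order = tops.sort_values("p")["snp"].tolist()
            leads, claimed = [], set()
            cols = {s: m.column(s) for s in order}
            for s in order:
                if s in claimed:
                    continue
                leads.append(s)
                claimed.add(s)
                for t in order:
                    if t not in claimed and ld_r2(cols[s], cols[t]) > 0.1:
                        claimed.add(t)
            return leads

        got = clump_gwas_snps(tops, m, r2_threshold=0.1)["snp"].tolist()
        assert got == oracle()

    def test_absent_snps_dropped_empty_raises(self, rng):
        m = _matrix(rng.binomial(2, 0.4, size=(100, 2)))
        with pytest.raises(ValueError):
            clump_gwas_snps(pd.DataFrame({"snp": ["nope"], "p": [1e-9]}), m)


class TestProxies:
    def test_duplicated_column_included(self, rng):
        a = rng.binomial(2, 0.4, 200).astype(float)
        m = _matrix(np.column_stack([a, a, rng.binomial(2, 0.4, 200)]))
        assert find_proxies("snp000000", m) == ["snp000000", "snp000001"]

    def test_independent_panel_lead_only(self, rng):
        m = _matrix(rng.binomial(2, 0.4, size=(500, 5)))
        assert find_proxies("snp000002", m) == ["snp000002"]

    def test_planted_block_of_four(self, rng):
        n = 500
        a = rng.binomial(2, 0.4, n).astype(float)
        block = [np.where(rng.random(n) < 0.02, rng.binomial(2, 0.4, n), a) for _ in range(3)]
        m = _matrix(np.column_stack([a] + block + [rng.binomial(2, 0.4, n)]))
        assert len(find_proxies("snp000000", m, r2_min=0.8)) == 4

    def test_absent_lead_raises(self, rng):
        m = _matrix(rng.binomial(2, 0.4, size=(100, 2)))
        with pytest.raises(KeyError):
            find_proxies("nope", m)


class TestCaseControl:
    def test_hand_computed_table(self):
        # cases: 10 alt / 90 ref alleles; controls: 30 alt / 70 ref
        d = np.concatenate([np.repeat([0.0, 1.0], [40, 10]), np.repeat([0.0, 1.0], [20, 30])])
        s = np.concatenate([np.ones(50), np.zeros(50)])
        chi2, p, orr = case_control_allelic_test(d, s)
        assert chi2 == pytest.approx(12.5, abs=1e-12)
        assert p == pytest.approx(4.07e-4, rel=0.01)
        assert orr == pytest.approx((10 * 70) / (90 * 30), abs=1e-12)

    def test_identical_frequencies_null(self):
        d = np.tile([0.0, 1.0, 2.0, 1.0], 25)
        s = np.tile([1, 0], 50)
        chi2, p, _ = case_control_allelic_test(d, s)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            case_control_allelic_test([0.0, 1.0], [1, 1])

    def test_missing_cases_rejected(self):
        d = np.array([np.nan, np.nan, 1.0, 0.0])
        s = np.array([1, 1, 0, 0])
        with pytest.raises(ValueError):
            case_control_allelic_test(d, s)


class TestPrune:
    def test_duplicated_column_one_survivor(self, rng):
        a = rng.binomial(2, 0.4, 300).astype(float)
        m = _matrix(np.column_stack([a, a]))
        assert len(ld_prune(m)) == 1

    def test_independent_all_retained(self, rng):
        m = _matrix(rng.binomial(2, 0.4, size=(800, 10)))
        assert len(ld_prune(m, r2_threshold=0.2)) == 10

    def test_survivors_pairwise_independent(self):
        cfg = SimulationConfig(
            n_samples_per_cohort=(400,), n_snps=20, ld_block_size=5, ld_rho=0.9, seed=13
        )
        g = simulate_genotypes(cfg)
        kept = ld_prune(g, r2_threshold=0.2, window_snps=20)
        sub = g.subset_snps(kept)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert ld_r2(sub.dosages[:, i], sub.dosages[:, j]) < 0.2


class TestEnrichment:
    def _setup(self, rng, k_hits=0):
        snps = [f"s{i}" for i in range(50)]
        traits = [f"t{j}" for j in range(5)]
        pvals = {(s, t): rng.uniform(0.06, 1.0) for s in snps for t in traits}
        gset = snps[:10]
        for s in gset[: k_hits // 5 + (1 if k_hits % 5 else 0)]:
            for t in traits:
                if k_hits <= 0:
                    break
                pvals[(s, t)] = 0.001
                k_hits -= 1
        return make_records(snps, traits, pvals), gset, traits, snps

    def test_observed_count_and_boundary_p(self, rng):
        recs, gset, traits, snps = self._setup(rng, k_hits=20)
        res = enrichment_test(recs, gset, traits, snps, B=50, seed=1)
        assert res.observed == 20
        assert res.p == 0.0  # literal exceedance definition
        res1 = enrichment_test(recs, gset, traits, snps, B=50, seed=1, add_one=True)
        assert res1.p == pytest.approx(1 / 51)

    def test_reproducible_given_seed(self, rng):
        recs, gset, traits, snps = self._setup(rng, k_hits=3)
        a = enrichment_test(recs, gset, traits, snps, B=100, seed=9)
        b = enrichment_test(recs, gset, traits, snps, B=100, seed=9)
        np.testing.assert_array_equal(a.null, b.null)
        assert a.p == b.p

    def test_null_mean_matches_alpha_expectation(self, rng):
        # under a global uniform null, E[count] = alpha * |set| * |traits|
        snps = [f"s{i}" for i in range(200)]
        traits = [f"t{j}" for j in range(10)]
        pvals = {(s, t): rng.uniform() for s in snps for t in traits}
        recs = make_records(snps, traits, pvals)
        res = enrichment_test(recs, snps[:20], traits, snps, B=400, seed=3)
        expect = 0.05 * 20 * 10
        assert abs(res.null.mean() - expect) < 3 * res.null.std() / np.sqrt(400) + 2

    def test_pool_too_small(self, rng):
        recs, gset, traits, snps = self._setup(rng)
        with pytest.raises(ValueError):
            enrichment_test(recs, gset, traits, snps[:5], B=10)

    def test_empty_category_rejected(self, rng):
        recs, gset, traits, snps = self._setup(rng)
        with pytest.raises(ValueError):
            enrichment_test(recs, gset, [], snps, B=10)


class TestVarianceExplained:
    def test_exact_linear_combination(self, rng):
        G = rng.binomial(2, 0.4, size=(100, 5)).astype(float)
        y = G @ rng.normal(size=5)
        assert variance_explained(G, y) == pytest.approx(1.0, abs=1e-10)

    def test_single_snp_equals_squared_pearson(self, rng):
        g = rng.binomial(2, 0.3, 200).astype(float)
        y = 0.3 * g + rng.normal(size=200)
        r2 = np.corrcoef(g, y)[0, 1] ** 2
        assert variance_explained(g[:, None], y) == pytest.approx(r2, abs=1e-12)

    def test_null_expectation(self, rng):
        # independent phenotype: E[R^2] = k/(n-1)
        k, n = 20, 150
        vals = [
            variance_explained(rng.binomial(2, 0.3, size=(n, k)).astype(float), rng.normal(size=n))
            for _ in range(100)
        ]
        assert np.mean(vals) == pytest.approx(k / (n - 1), abs=0.02)

    def test_monotone_in_set_size(self, rng):
        G = rng.binomial(2, 0.4, size=(120, 10)).astype(float)
        y = rng.normal(size=120)
        r2s = [variance_explained(G[:, : k + 1], y) for k in range(10)]
        assert (np.diff(r2s) >= -1e-12).all()

    def test_covariate_residualization(self, rng):
        n = 200
        c = rng.normal(size=n)
        G = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        y = 2.0 * c + rng.normal(size=n)
        # phenotype variance fully explained by the covariate: SNP R^2 ~ 0
        r2 = variance_explained(G, y, covariates=c)
        assert r2 < 0.05

    def test_sample_size_guard(self, rng):
        G = rng.binomial(2, 0.4, size=(10, 9)).astype(float)
        with pytest.raises(ValueError):
            variance_explained(G, rng.normal(size=10))


class TestVarianceExplainedTest:
    def test_planted_joint_effect_detected(self):
        cfg = SimulationConfig(
            n_samples_per_cohort=(300,), n_snps=200, ld_rho=0.0, seed=21
        )
        g = simulate_genotypes(cfg)
        rng = np.random.default_rng(21)
        gset = [f"snp{i:06d}" for i in range(0, 200, 20)]  # 10 set SNPs
        sub = g.subset_snps(gset)
        y = sub.dosages @ np.full(10, 0.3) + rng.normal(size=300)
        pool = list(g.variants["snp"])
        res = variance_explained_test(g, y, None, gset, pool, B=100, seed=5)
        assert res.p < 0.05

    def test_b_zero_rejected(self, rng):
        m = _matrix(rng.binomial(2, 0.4, size=(100, 10)))
        with pytest.raises(ValueError):
            variance_explained_test(m, rng.normal(size=100), None,
                                    list(m.variants["snp"][:2]),
                                    list(m.variants["snp"]), B=0)

    def test_empirical_p_conventions_close(self, rng):
        m = _matrix(rng.binomial(2, 0.4, size=(150, 30)))
        y = rng.normal(size=150)
        snps = list(m.variants["snp"])
        a = variance_explained_test(m, y, None, snps[:5], snps, B=50, seed=2)
        b = variance_explained_test(m, y, None, snps[:5], snps, B=50, seed=2, add_one=True)
        assert abs(a.p - b.p) <= 1 / 50 + 1 / 51
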