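"""Background model: distances, bagels, marginals, beta-binomial priors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synsig.background import (
    CohortMarginals,
    GcpBackground,
    GeneBackground,
    apply_synonyms,
    beta_binomial_pmf,
    build_bagel,
    compute_marginals,
    covariate_distance_matrix,
    gcp_background,
    qualify_neighbor,
    raw_background,
    site_probabilities,
)
from synsig.tensors import NONCODING, TOTAL, CountTensor, CoverageTensor


def make_cov(genes, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(len(genes), 3)),
        index=genes,
        columns=["expression", "replication_timing", "chromatin"],
    )


class TestCovariateDistance:
    def test_identical_rows_distance_zero(self):
        cov = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [0.0, 0.0, 5.0]}, index=list("xyz"))
        d = covariate_distance_matrix(cov)
        assert d.loc["x", "y"] == 0.0

    def test_symmetric_zero_diagonal(self):
        d = covariate_distance_matrix(make_cov(list("abcde")))
        np.testing.assert_allclose(d.values, d.values.T)
        assert np.diag(d.values).sum() == 0.0

    def test_one_standardized_unit(self):
        cov = pd.DataFrame({"a": [0.0, 2.0], "b": [1.0, 1.0]}, index=["g1", "g2"])
        d = covariate_distance_matrix(cov)
        # sd(ddof=0) of [0,2] is 1 -> standardized gap is 2
        assert d.loc["g1", "g2"] == pytest.approx(2.0)

    def test_all_missing_column_raises(self):
        cov = pd.DataFrame({"a": [np.nan, np.nan]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            covariate_distance_matrix(cov)

    def test_missing_values_imputed(self):
        cov = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1, 2, 3]}, index=list("xyz"))
        d = covariate_distance_matrix(cov)
        assert np.isfinite(d.values).all()

    def test_synonym_mapping(self):
        cov = make_cov(["OLD1", "g2"])
        renamed = apply_synonyms(cov, {"OLD1": "g1"})
        assert list(renamed.index) == ["g1", "g2"]


class TestRawBackground:
    def make_tensors(self, counts_by_patient):
        counts = CountTensor(["G"], [f"P{i}" for i in range(len(counts_by_patient))])
        for pi, n in enumerate(counts_by_patient):
            counts.values[0, 0, pi, NONCODING] = n
        counts.finalize()
        coverage = CoverageTensor(["G"], counts.patients)
        coverage.values[0, :6, :, NONCODING] = 10.0
        coverage.finalize()
        return counts, coverage

    def test_sum_over_patients(self):
        counts, coverage = self.make_tensors([3, 4])
        n, N = raw_background(counts, coverage, "G")
        assert n == 7 and N == 120.0

    def test_zero_mutations(self):
        counts, coverage = self.make_tensors([0, 0])
        n, N = raw_background(counts, coverage, "G")
        assert n == 0 and N > 0

    def test_missing_gene_raises(self):
        counts, coverage = self.make_tensors([1])
        with pytest.raises(KeyError):
            raw_background(counts, coverage, "NOPE")


class TestQualifyNeighbor:
    def test_identical_backgrounds_qualify(self):
        assert qualify_neighbor((5, 1000), (5, 1000))

    def test_strong_rate_mismatch_disqualified(self):
        # Monte-Carlo oracle: rate ~ Beta(1, 1001), K ~ Binomial(1000, rate)
        rng = np.random.default_rng(0)
        rates = rng.beta(1, 1001, size=200_000)
        ks = rng.binomial(1000, rates)
        mc_tail = (ks >= 100).mean()
        assert mc_tail < 0.05 / 10  # far below the qualification threshold
        assert not qualify_neighbor((0, 1000), (100, 1000))

    def test_zero_coverage_neighbor_disqualified(self):
        assert not qualify_neighbor((5, 1000), (0, 0))


class TestBuildBagel:
    def setup_method(self):
        self.genes = ["g0", "g1", "g2", "g3"]
        cov = pd.DataFrame(
            {"a": [0.0, 0.1, 0.2, 5.0], "b": 0.0, "c": 0.0}, index=self.genes
        )
        self.dist = covariate_distance_matrix(cov)

    def test_no_qualifying_neighbor_empty_bagel(self):
        backgrounds = {"g0": (0, 1000), "g1": (500, 1000), "g2": (0, 1000), "g3": (0, 1000)}
        bg = build_bagel("g0", self.dist, backgrounds)
        # nearest neighbor g1 fails -> stop immediately
        assert bg.bagel == [] and bg.x == 0 and bg.X == 1000

    def test_identical_genes_double_background(self):
        backgrounds = {g: (7, 1000) for g in self.genes}
        bg = build_bagel("g0", self.dist, backgrounds, max_neighbors=1)
        assert bg.x == 14 and bg.X == 2000

    def test_neighbor_cap(self):
        backgrounds = {g: (7, 1000) for g in self.genes}
        bg = build_bagel("g0", self.dist, backgrounds, max_neighbors=2)
        assert len(bg.bagel) == 2
        assert bg.bagel == ["g1", "g2"]  # nearest first

    def test_coverage_cap(self):
        backgrounds = {g: (7, 1000) for g in self.genes}
        bg = build_bagel("g0", self.dist, backgrounds, max_coverage=1500)
        assert len(bg.bagel) == 1

    def test_aggregation_never_lowers_coverage(self):
        rng = np.random.default_rng(4)
        backgrounds = {
            g: (int(rng.integers(0, 20)), float(rng.integers(500, 2000)))
            for g in self.genes
        }
        for g in self.genes:
            bg = build_bagel(g, self.dist, backgrounds)
            assert bg.X >= bg.N_bkgd
            assert bg.x >= bg.n_bkgd


class TestMarginals:
    def homogeneous(self, n_genes=30, n_patients=10, lam=2.0, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        patients = [f"p{i}" for i in range(n_patients)]
        counts = CountTensor(genes, patients)
        coverage = CoverageTensor(genes, patients)
        coverage.values[:, :6, :, :] = 50.0
        coverage.finalize()
        counts.values[:, :6, :, :] = rng.poisson(lam, size=(n_genes, 6, n_patients, 3))
        counts.finalize()
        return counts, coverage

    def test_homogeneous_cohort_unit_factors(self):
        counts, coverage = self.homogeneous()
        m = compute_marginals(counts, coverage)
        np.testing.assert_allclose(m.rho_c[:6], 1.0, atol=0.1)
        np.testing.assert_allclose(m.rho_p, 1.0, atol=0.1)

    def test_double_burden_patient(self):
        counts, coverage = self.homogeneous()
        counts.values[:, :6, 0, :] *= 2
        counts.finalize()
        m = compute_marginals(counts, coverage)
        ratio = m.rho_p[0] / m.rho_p[1:].mean()
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_coverage_weighted_means_are_one(self):
        counts, coverage = self.homogeneous(seed=3)
        counts.values[:, :6, :, :] += np.arange(6)[None, :, None, None]
        counts.finalize()
        m = compute_marginals(counts, coverage)
        cov_c = coverage.values[:, :6].sum(axis=(0, 2, 3))
        cov_p = coverage.values[:, :6].sum(axis=(0, 1, 3))
        assert np.average(m.rho_c[:6], weights=cov_c) == pytest.approx(1.0)
        # patient factors include category-7 mutations; with none present the
        # same normalization applies
        assert np.average(m.rho_p, weights=cov_p) == pytest.approx(1.0)

    def test_zero_total_coverage_raises(self):
        counts = CountTensor(["g"], ["p"]).finalize()
        coverage = CoverageTensor(["g"], ["p"]).finalize()
        with pytest.raises(ValueError):
            compute_marginals(counts, coverage)


class TestGcpBackground:
    def test_unity_marginals_identity(self):
        bg = GeneBackground("g", 5, 100, [], x=10, X=200)
        m = CohortMarginals(np.ones(7), np.ones(3), ["a", "b", "c"])
        gcp = gcp_background(bg, m)
        np.testing.assert_allclose(gcp.x, 10.0)
        assert gcp.X == 200

    def test_zero_category_rate_gives_zero(self):
        bg = GeneBackground("g", 5, 100, [], x=10, X=200)
        rho_c = np.ones(7)
        rho_c[2] = 0.0
        m = CohortMarginals(rho_c, np.ones(2), ["a", "b"])
        gcp = gcp_background(bg, m)
        assert (gcp.x[2] == 0).all()
        P0, _, _ = site_probabilities(GcpBackground("g", gcp.x[:6], gcp.X), np.full((6, 2), 50.0))
        # a never-observed category maximizes the probability of zero events
        assert (P0[2] >= P0.max(axis=0) - 1e-12).all()

    def test_clamped_to_coverage(self):
        bg = GeneBackground("g", 5, 100, [], x=10, X=200)
        m = CohortMarginals(np.full(7, 10.0), np.full(2, 10.0), ["a", "b"])
        gcp = gcp_background(bg, m)
        assert gcp.x.max() == 200  # 10*100*... clamped at X


class TestBetaBinomial:
    def test_pmf_normalizes(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            N = int(rng.integers(0, 30))
            X = float(rng.integers(1, 100))
            x = float(rng.uniform(0, X))
            total = beta_binomial_pmf(np.arange(N + 1), N, x, X).sum()
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_no_sites_no_mutations(self):
        assert beta_binomial_pmf(0, 0, 3, 10) == pytest.approx(1.0)

    def test_against_monte_carlo_oracle(self):
        # H(1, 2, 1, 10): rate ~ Beta(2, 10), K ~ Binomial(2, rate)
        rng = np.random.default_rng(2)
        n = 1_000_000
        rates = rng.beta(2, 10, size=n)
        ks = rng.binomial(2, rates)
        mc = (ks == 1).mean()
        se = np.sqrt(mc * (1 - mc) / n)
        assert abs(beta_binomial_pmf(1, 2, 1, 10) - mc) < 3 * se

    def test_binomial_limit(self):
        # X -> inf with x/X fixed reduces to Binomial(N, x/X)
        N, rate = 20, 0.3
        X = 1e7
        ks = np.arange(N + 1)
        bb = beta_binomial_pmf(ks, N, rate * X, X)
        bino = stats.binom.pmf(ks, N, rate)
        assert np.abs(bb - bino).max() < 1e-4

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            beta_binomial_pmf(-1, 2, 1, 10)


class TestSiteProbabilities:
    def test_zero_background_matches_summation_oracle(self):
        gcp = GcpBackground("g", np.zeros((1, 1)), 500.0)
        P0, P1, P2 = site_probabilities(gcp, np.array([[30.0]]))
        # brute-force: P0 = H(0, 30, 0, 500) via direct formula summation check
        ks = np.arange(31)
        pmf = beta_binomial_pmf(ks, 30, 0.0, 500.0)
        assert P0[0, 0] == pytest.approx(pmf[0])
        assert P1[0, 0] == pytest.approx(pmf[1])
        assert P2[0, 0] == pytest.approx(pmf[2:].sum(), abs=1e-12)

    def test_zero_coverage_triplet(self):
        gcp = GcpBackground("g", np.full((2, 2), 3.0), 100.0)
        P0, P1, P2 = site_probabilities(gcp, np.zeros((2, 2)))
        np.testing.assert_allclose(P0, 1.0)
        np.testing.assert_allclose(P1, 0.0)
        np.testing.assert_allclose(P2, 0.0)

    def test_triplets_sum_to_one_random_draws(self):
        rng = np.random.default_rng(7)
        N = rng.integers(0, 200, size=1000).astype(float)
        X = rng.uniform(1, 1e4, size=1000)
        x = rng.uniform(0, 1, size=1000) * X
        for i in range(0, 1000, 100):
            xs = np.minimum(x[i : i + 100], X[i])
            P0, P1, P2 = site_probabilities(GcpBackground("g", xs, float(X[i])), N[i : i + 100])
            np.testing.assert_allclose(P0 + P1 + P2, 1.0, atol=1e-12)
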