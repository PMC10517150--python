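"""Single-variant GLM tests, conditioning, LD statistics, genomic inflation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mphl_exwas.assoc_single import (
    conditional_single_variant_test,
    genomic_lambda,
    ld_stats,
    ld_stats_unphased,
    linear_scan,
    select_pc_count,
    single_variant_test,
    standardize_covariates,
)


class TestStandardize:
    def test_closed_form(self):
        out = standardize_covariates(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["x"], [-1.22474487, 0.0, 1.22474487], atol=1e-8)

    def test_idempotent(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=50)})
        once = standardize_covariates(X)
        twice = standardize_covariates(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_random_matrix_moments(self, rng):
        X = pd.DataFrame(rng.normal(5, 3, size=(200, 4)), columns=list("abcd"))
        out = standardize_covariates(X).to_numpy()
        assert np.abs(out.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(out.var(axis=0), 1.0, atol=1e-12)

    def test_categorical_one_hot_drops_reference(self):
        X = pd.DataFrame({"batch": ["B0", "B1", "B2", "B0"]})
        out = standardize_covariates(X)
        assert list(out.columns) == ["batch_B1", "batch_B2"]

    def test_zero_variance_named(self):
        with pytest.raises(ValueError, match="flat"):
            standardize_covariates(pd.DataFrame({"flat": [1.0, 1.0]}))


class TestSingleVariant:
    def test_perfect_fit(self, rng):
        d = rng.binomial(2, 0.3, 60).astype(float)
        res = single_variant_test(d, d, family="linear")
        assert res.effect == pytest.approx(1.0, abs=1e-10)
        assert res.p_value < 1e-100

    def test_matches_normal_equations_oracle(self, rng):
        """30-sample fixture vs hand-rolled OLS: beta/se to 1e-10."""
        n = 30
        d = rng.binomial(2, 0.4, n).astype(float)
        X = rng.normal(size=(n, 2))
        y = 0.3 * d + rng.normal(size=n)
        res = single_variant_test(d, y, X, family="linear")
        A = np.column_stack([np.ones(n), d, X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        r = y - A @ beta
        sigma2 = r @ r / (n - A.shape[1])
        cov = sigma2 * np.linalg.inv(A.T @ A)
        assert res.effect == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)

    def test_linear_scan_matches_per_variant_fits(self, rng):
        n, m = 80, 12
        G = rng.binomial(2, 0.2, size=(n, m)).astype(float)
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        scan = linear_scan(G, y, X)
        for j in range(m):
            res = single_variant_test(G[:, j], y, X, family="linear")
            assert scan["beta"].iloc[j] == pytest.approx(res.effect, abs=1e-10)
            assert scan["p"].iloc[j] == pytest.approx(res.p_value, rel=1e-8)

    def test_logistic_reports_odds_ratio(self, rng):
        n = 400
        d = rng.binomial(2, 0.3, n).astype(float)
        logit = -0.5 + 0.8 * d
        y = rng.binomial(1, 1 / (1 + np.exp(-logit))).astype(float)
        res = single_variant_test(d, y, family="logistic")
        assert res.family == "logistic"
        assert 1.0 < res.effect < 5.0  # OR scale

    def test_monomorphic_flagged(self):
        res = single_variant_test(np.zeros(20), np.random.default_rng(0).normal(size=20))
        assert not res.converged and res.p_value is None

    def test_permutation_calibration(self, rng):
        """Wald p under permuted-y null: type-I error inside the 99% interval."""
        n, m = 200, 2000
        G = rng.binomial(2, rng.uniform(0.05, 0.4, m), size=(n, m)).astype(float)
        y = rng.permutation(rng.normal(size=n))
        scan = linear_scan(G, y)
        rate = (scan["p"].dropna() < 0.05).mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / m)
        assert abs(rate - 0.05) < half


class TestConditional:
    def test_empty_lead_set_identity(self, rng):
        n = 100
        d = rng.binomial(2, 0.2, n).astype(float)
        y = rng.normal(size=n)
        a = single_variant_test(d, y, family="linear")
        b = conditional_single_variant_test(d, y, None, None, family="linear")
        assert a.p_value == b.p_value

    def test_orthogonal_lead_leaves_beta(self, rng):
        """Exactly orthogonal covariate changes beta by < 1e-8 (linear)."""
        n = 100
        d = rng.binomial(2, 0.3, n).astype(float)
        lead = rng.normal(size=n)
        lead -= lead.mean()
        d_c = d - d.mean()
        lead -= (lead @ d_c) / (d_c @ d_c) * d_c  # orthogonalize to dosage
        y = rng.normal(size=n)
        a = single_variant_test(d, y, family="linear")
        b = conditional_single_variant_test(d, y, None, lead, ("L1",), family="linear")
        assert abs(a.effect - b.effect) < 1e-8

    def test_collinear_rare_variant_loses_signal(self, rng):
        """A rare allele carried only on the lead-SNP background is explained
        away by conditioning (the sentinel-dependence pattern)."""
        n = 2000
        lead = rng.binomial(2, 0.4, n).astype(float)
        rare = np.zeros(n)
        carriers = rng.choice(np.flatnonzero(lead == 2), 30, replace=False)
        rare[carriers] = 1.0
        y = 1.0 * lead + rng.normal(size=n)
        uncond = single_variant_test(rare, y, family="linear")
        cond = conditional_single_variant_test(rare, y, None, lead, ("L1",),
                                               family="linear")
        assert uncond.p_value < 0.01
        assert cond.p_value > 0.05
        assert cond.conditioned_on == ("L1",)

    def test_duplicate_lead_column_dropped(self, rng):
        n = 100
        d = rng.binomial(2, 0.3, n).astype(float)
        lead = rng.binomial(2, 0.4, n).astype(float)
        y = rng.normal(size=n)
        with pytest.warns(UserWarning, match="collinear"):
            res = conditional_single_variant_test(
                d, y, None, np.column_stack([lead, lead]), ("L1", "L2"),
                family="linear")
        assert res.conditioned_on == ("L1",)


class TestLd:
    def test_exclusive_background_dprime_one(self):
        # rare allele only on the common risk background: D' = 1, r2 small
        hapA = np.zeros(1000)
        hapA[:5] = 1
        hapB = np.ones(1000)
        hapB[-50:] = 0
        out = ld_stats(hapA, hapB)
        assert out.d_prime == pytest.approx(1.0)
        assert out.r_squared < 0.01

    def test_independent_loci_zero(self):
        hapA = np.array([1, 1, 0, 0] * 25, float)
        hapB = np.array([1, 0, 1, 0] * 25, float)
        out = ld_stats(hapA, hapB)
        assert out.r_squared == pytest.approx(0.0, abs=1e-12)
        assert out.d_prime == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_small_tables(self):
        """All 2x2 haplotype tables with cell counts <= 4: brute-force formulas
        and the r2 <= D' inequality."""
        for n11, n10, n01, n00 in itertools.product(range(5), repeat=4):
            n = n11 + n10 + n01 + n00
            if n == 0:
                continue
            a = np.array([1] * (n11 + n10) + [0] * (n01 + n00), float)
            b = np.array([1] * n11 + [0] * n10 + [1] * n01 + [0] * n00, float)
            pA, pB = a.mean(), b.mean()
            if pA in (0, 1) or pB in (0, 1):
                with pytest.raises(ValueError):
                    ld_stats(a, b)
                continue
            out = ld_stats(a, b)
            D = n11 / n - pA * pB
            r2 = D**2 / (pA * (1 - pA) * pB * (1 - pB))
            dmax = min(pA * (1 - pB), (1 - pA) * pB) if D >= 0 \
                else min(pA * pB, (1 - pA) * (1 - pB))
            assert out.r_squared == pytest.approx(min(r2, 1.0), abs=1e-12)
            assert out.d_prime == pytest.approx(min(abs(D) / dmax, 1.0), abs=1e-12)
            assert out.r_squared <= out.d_prime + 1e-9

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            ld_stats(np.zeros(10), np.ones(10) * 0 + np.arange(10) % 2)

    def test_em_phasing_recovers_known_haplotypes(self, rng):
        # genotypes formed from known haplotypes: EM matches direct phased LD
        n = 2000
        pA, pB = 0.3, 0.4
        # build correlated haplotypes
        h1a = rng.binomial(1, pA, n)
        h1b = np.where(rng.random(n) < 0.7, h1a, rng.binomial(1, pB, n))
        h2a = rng.binomial(1, pA, n)
        h2b = np.where(rng.random(n) < 0.7, h2a, rng.binomial(1, pB, n))
        phased = ld_stats(np.concatenate([h1a, h2a]), np.concatenate([h1b, h2b]))
        em = ld_stats_unphased(h1a + h2a, h1b + h2b)
        assert em.r_squared == pytest.approx(phased.r_squared, abs=0.02)
        assert em.d_prime == pytest.approx(phased.d_prime, abs=0.05)


class TestLambda:
    def test_all_half_gives_one(self):
        assert genomic_lambda(np.full(101, 0.5)) == pytest.approx(1.0)

    def test_uniform_null(self, rng):
        p = rng.uniform(size=100_000)
        assert genomic_lambda(p) == pytest.approx(1.0, abs=0.02)

    def test_median_scaling(self, rng):
        from scipy import stats as st

        chi = st.chi2.rvs(1, size=10_001, random_state=1)
        p1 = st.chi2.sf(chi, 1)
        p2 = st.chi2.sf(2 * chi, 1)
        assert genomic_lambda(p2) == pytest.approx(2 * genomic_lambda(p1), rel=1e-9)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            genomic_lambda(np.array([0.0, 0.5]))


class TestSelectPcCount:
    def test_unstratified_flat_selects_one(self, rng):
        n, m = 800, 1500
        G = rng.binomial(2, 0.2, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        pcs = rng.normal(size=(n, 5))
        k, lambdas = select_pc_count(G, y, None, pcs, range(1, 6))
        assert k == 1
        assert max(lambdas.values()) - min(lambdas.values()) < 0.2

    def test_planted_two_population_structure(self, rng):
        """Confounded 3-subpopulation structure (2 PC dimensions): lambda is
        inflated with 1 PC and restored with >= 2."""
        n, m = 900, 600
        pop = np.repeat([0, 1, 2], n // 3)
        base = rng.uniform(0.1, 0.5, m)
        shift = rng.normal(0, 0.12, size=(3, m))
        freqs = np.clip(base + shift[pop], 0.02, 0.98)
        G = rng.binomial(2, freqs).astype(float)
        y = 0.8 * (pop == 0) - 0.8 * (pop == 2) + rng.normal(size=n)
        from sklearn.decomposition import PCA

        Gc = G - G.mean(axis=0)
        pcs = PCA(n_components=6, random_state=0).fit_transform(Gc)
        k, lambdas = select_pc_count(G, y, None, pcs, range(1, 7))
        assert lambdas[1] > lambdas[2] + 0.05
        assert k == 2

    def test_deterministic(self, rng):
        n, m = 300, 200
        G = rng.binomial(2, 0.2, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        pcs = rng.normal(size=(n, 4))
        out1 = select_pc_count(G, y, None, pcs, range(1, 5))
        out2 = select_pc_count(G, y, None, pcs, range(1, 5))
        assert out1 == out2
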