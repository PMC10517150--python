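"""Gene scores and SKAT / burden / SKAT-O collapsing tests.

Correctness is anchored to independent oracles: triple-loop brute force for
gene scores, a score-test reduction for single-variant genes, and residual
permutation for the mixture-of-chi-square p-values.
"""

import numpy as np
import pytest
from scipy import stats

from mphl_exwas.skat import (
    SkatConfig,
    beta_maf_weight,
    bonferroni_threshold,
    conditional_gene_test,
    fit_null_model,
    gene_score,
    gene_score_association,
    mixture_chisq_sf,
    skat_o,
    skat_test,
)


def _fixture(rng, n=60, m=5, maf_lo=0.05, maf_hi=0.3):
    maf = rng.uniform(maf_lo, maf_hi, m)
    G = rng.binomial(2, maf, size=(n, m)).astype(float)
    y = rng.normal(size=n)
    X = rng.normal(size=(n, 2))
    return G, y, X


def _perm_p(G, y, X, rho, n_perm, seed=5, config=None):
    """Independent permutation oracle for Q_rho (residual permutation)."""
    config = config or SkatConfig()
    null = fit_null_model(y, X, "linear")
    freq = G.mean(axis=0) / 2
    w = beta_maf_weight(np.minimum(freq, 1 - freq),
                        config.weight_a, config.weight_b)
    Z = G * w
    sig = np.sqrt(null.sigma2)
    s = Z.T @ null.resid / sig
    q_obs = (1 - rho) * (s**2).sum() + rho * s.sum() ** 2
    rng = np.random.default_rng(seed)
    P = np.column_stack([rng.permutation(null.resid) for _ in range(n_perm)])
    S = Z.T @ P / sig
    q = (1 - rho) * (S**2).sum(axis=0) + rho * S.sum(axis=0) ** 2
    return q_obs, (1 + (q >= q_obs).sum()) / (1 + n_perm)


class TestWeights:
    def test_closed_forms(self):
        assert beta_maf_weight(0.0) == pytest.approx(25.0)
        assert beta_maf_weight(0.01) == pytest.approx(25 * 0.99**24)

    def test_strictly_decreasing_on_rare_grid(self):
        grid = np.linspace(0, 0.01, 50)
        w = beta_maf_weight(grid)
        assert (np.diff(w) < 0).all()

    def test_matches_scipy_beta_pdf(self):
        grid = np.array([0.0005, 0.003, 0.01, 0.2])
        np.testing.assert_allclose(beta_maf_weight(grid),
                                   stats.beta.pdf(grid, 1, 25), rtol=1e-12)

    def test_out_of_domain(self):
        with pytest.raises(ValueError):
            beta_maf_weight(-0.1)


class TestGeneScore:
    def test_no_alt_alleles_scores_zero(self):
        G = np.zeros((5, 3))
        s = gene_score(G, np.full(3, 0.001), np.full(3, 10.0))
        assert (s == 0).all()

    def test_single_term_closed_form(self):
        s = gene_score(np.array([[1.0]]), np.array([0.001]), np.array([10.0]))
        assert s[0] == pytest.approx(25 * 0.999**24 * 10.0)

    def test_matches_triple_loop(self, rng):
        n, m = 20, 5
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        maf = rng.uniform(0.001, 0.01, m)
        cadd = rng.uniform(0, 40, m)
        s = gene_score(G, maf, cadd)
        for i in range(n):
            total = 0.0
            for v in range(m):
                w = 25.0 * (1.0 - maf[v]) ** 24
                total += w * cadd[v] * G[i, v]
            assert s[i] == pytest.approx(total, abs=1e-12)

    def test_negative_cadd_rejected(self):
        with pytest.raises(ValueError):
            gene_score(np.ones((2, 1)), np.array([0.01]), np.array([-1.0]))


class TestSkat:
    def test_single_variant_gene_reduces_to_score_test(self, rng):
        n = 200
        g = rng.binomial(2, 0.2, n).astype(float)
        y = rng.normal(size=n) + 0.2 * g
        X = rng.normal(size=(n, 2))
        null = fit_null_model(y, X, "linear")
        # score test of the variant from first principles
        gc = g - null._qr_q @ (null._qr_q.T @ g)
        u = g @ null.resid / null.sigma2
        var = gc @ gc / null.sigma2
        p_score = stats.chi2.sf(u**2 / var, 1)
        for rho in (0.0, 0.5, 1.0):
            _, p = skat_test(g[:, None], y, X, rho=rho)
            assert p == pytest.approx(p_score, rel=1e-8)
        assert skat_o(g[:, None], y, X) == pytest.approx(p_score, rel=1e-8)

    def test_rho_one_is_weighted_burden(self, rng):
        """Q at rho=1 equals the burden test on the weighted sum."""
        G, y, X = _fixture(rng)
        cfg = SkatConfig()
        q1, p1 = skat_test(G, y, X, cfg, rho=1.0)
        freq = G.mean(axis=0) / 2
        w = beta_maf_weight(np.minimum(freq, 1 - freq))
        burden = G @ w
        null = fit_null_model(y, X, "linear")
        s = burden @ null.resid / np.sqrt(null.sigma2)
        assert q1 == pytest.approx(s**2, rel=1e-10)
        bc = burden - null._qr_q @ (null._qr_q.T @ burden)
        p_burden = stats.chi2.sf(s**2 / (bc @ bc), 1)
        assert p1 == pytest.approx(p_burden, rel=1e-8)

    @pytest.mark.parametrize("rho", [0.0, 0.25, 1.0])
    def test_p_matches_permutation(self, rng, rho):
        G, y, X = _fixture(rng, n=50, m=5)
        cfg = SkatConfig(p_method="numeric_inversion")
        _, p = skat_test(G, y, X, cfg, rho=rho)
        _, p_perm = _perm_p(G, y, X, rho, 20_000)
        se = np.sqrt(p_perm * (1 - p_perm) / 20_000)
        assert abs(p - p_perm) < 4 * se + 0.01

    def test_moment_match_vs_inversion(self, rng):
        """The two mixture p-value methods agree within 10% relative."""
        for seed in range(5):
            G, y, X = _fixture(np.random.default_rng(seed))
            for rho in (0.0, 0.25):
                _, p_mm = skat_test(G, y, X, SkatConfig(), rho=rho)
                _, p_ni = skat_test(G, y, X, SkatConfig(p_method="numeric_inversion"),
                                    rho=rho)
                assert p_mm == pytest.approx(p_ni, rel=0.10)

    def test_invariant_to_column_and_sample_order(self, rng):
        G, y, X = _fixture(rng)
        p0 = skat_o(G, y, X)
        perm_cols = rng.permutation(G.shape[1])
        assert skat_o(G[:, perm_cols], y, X) == pytest.approx(p0, rel=1e-8)
        perm_rows = rng.permutation(G.shape[0])
        assert skat_o(G[perm_rows], y[perm_rows], X[perm_rows]) == \
            pytest.approx(p0, rel=1e-8)

    def test_cadd_scale_invariance_of_gene_score_test(self, rng):
        """Scaling all CADD scores scales gene scores but not p-values."""
        n, m = 100, 4
        G = rng.binomial(2, 0.2, size=(n, m)).astype(float)
        maf = rng.uniform(0.001, 0.01, m)
        cadd = rng.uniform(1, 30, m)
        y = rng.normal(size=n)
        s1 = gene_score(G, maf, cadd)
        s2 = gene_score(G, maf, cadd * 7.0)
        np.testing.assert_allclose(s2, 7.0 * s1, rtol=1e-12)
        p1 = gene_score_association(s1, y).p_value
        p2 = gene_score_association(s2, y).p_value
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_binary_small_sample_uses_permutation(self, rng):
        n = 120
        G = rng.binomial(2, 0.2, size=(n, 4)).astype(float)
        y = (rng.random(n) < 0.3).astype(float)  # ~36 cases < 200
        _, p = skat_test(G, y, None, family="logistic", rho=0.0)
        assert 0.0 < p <= 1.0

    def test_all_monomorphic_gene_rejected(self, rng):
        with pytest.raises(ValueError, match="polymorphic"):
            skat_test(np.zeros((30, 3)), rng.normal(size=30))


class TestSkatO:
    def test_p_matches_permutation_oracle(self, rng):
        """SKAT-O omnibus p vs a min-p permutation oracle."""
        G, y, X = _fixture(rng, n=60, m=6)
        cfg = SkatConfig(p_method="numeric_inversion")
        p = skat_o(G, y, X, cfg)
        # oracle: permutation distribution of the min empirical p over rhos
        null = fit_null_model(y, X, "linear")
        freq = G.mean(axis=0) / 2
        w = beta_maf_weight(np.minimum(freq, 1 - freq))
        Z = G * w
        B = 20_000
        rng2 = np.random.default_rng(9)
        sig = np.sqrt(null.sigma2)
        S = Z.T @ np.column_stack([null.resid] +
                                  [rng2.permutation(null.resid) for _ in range(B)]) / sig
        rhos = np.asarray(cfg.rho_grid)
        q = np.stack([(1 - r) * (S**2).sum(axis=0) + r * S.sum(axis=0) ** 2
                      for r in rhos])
        p_emp = np.empty_like(q)
        for i in range(q.shape[0]):
            srt = np.sort(q[i, 1:])
            p_emp[i] = (1 + B - np.searchsorted(srt, q[i], side="left")) / (1 + B)
        t = p_emp.min(axis=0)
        p_perm = (1 + (t[1:] <= t[0]).sum()) / (1 + B)
        se = np.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(p - p_perm) < 4 * se + 0.01

    def test_mixed_direction_favors_skat_same_direction_favors_burden(self):
        """SKAT-O beats burden under mixed effect directions; burden is
        competitive under same-direction effects (paired replicates)."""
        wins_mixed, wins_same = 0, 0
        R = 12
        for rep in range(R):
            rng = np.random.default_rng(100 + rep)
            n, m = 400, 6
            G = rng.binomial(2, 0.15, size=(n, m)).astype(float)
            Gz = (G - G.mean(0)) / np.maximum(G.std(0), 1e-9)
            mixed = Gz @ (np.array([1, -1, 1, -1, 1, -1]) * 0.22)
            same = Gz @ (np.full(m, 0.22))
            noise = rng.normal(size=n)
            y_mixed = mixed + noise
            y_same = same + noise
            _, pb_mixed = skat_test(G, y_mixed, None, rho=1.0)
            po_mixed = skat_o(G, y_mixed, None)
            _, pb_same = skat_test(G, y_same, None, rho=1.0)
            po_same = skat_o(G, y_same, None)
            wins_mixed += po_mixed < pb_mixed
            wins_same += pb_same < 4 * po_same  # burden within a factor
        assert wins_mixed > R / 2
        assert wins_same > R / 2

    def test_null_p_uniformity_at_moderate_alpha(self, rng):
        n = 300
        ps = []
        for _ in range(300):
            G = rng.binomial(2, rng.uniform(0.05, 0.3, 4), size=(n, 4)).astype(float)
            ps.append(skat_o(G, rng.normal(size=n), None))
        rate = np.mean(np.array(ps) < 0.1)
        assert abs(rate - 0.1) < 2.576 * np.sqrt(0.1 * 0.9 / 300)


class TestConditional:
    def test_excluding_nothing_identical(self, rng):
        G, y, X = _fixture(rng)
        vids = [f"v{j}" for j in range(G.shape[1])]
        p, p_cond = conditional_gene_test(G, vids, set(), y, X)
        assert p == p_cond

    def test_excluding_driver_nullifies_signal(self, rng):
        """Single causal variant: removing it sends the gene p near-null."""
        n, m = 1500, 5
        G = rng.binomial(2, np.array([0.01, 0.1, 0.1, 0.1, 0.1]),
                         size=(n, m)).astype(float)
        y = 1.2 * G[:, 0] + rng.normal(size=n)
        vids = [f"v{j}" for j in range(m)]
        p, p_cond = conditional_gene_test(G, vids, {"v0"}, y, None)
        assert p < 1e-4
        assert p_cond > 1e-3
        assert p_cond > p * 100

    def test_excluding_null_variant_keeps_p(self, rng):
        deltas = []
        for rep in range(6):
            r = np.random.default_rng(rep)
            n, m = 800, 5
            G = r.binomial(2, 0.1, size=(n, m)).astype(float)
            y = 0.4 * G[:, 0] + r.normal(size=n)
            vids = [f"v{j}" for j in range(m)]
            p, p_cond = conditional_gene_test(G, vids, {"v4"}, y, None)
            deltas.append(abs(np.log10(p) - np.log10(p_cond)))
        assert np.median(deltas) < 1.0

    def test_emptying_gene_flagged(self, rng):
        g = rng.binomial(2, 0.2, 100).astype(float)[:, None]
        p, p_cond = conditional_gene_test(g, ["v0"], {"v0"}, rng.normal(size=100))
        assert p_cond is None

    def test_unknown_exclusion_rejected(self, rng):
        g = rng.binomial(2, 0.2, 50).astype(float)[:, None]
        with pytest.raises(ValueError):
            conditional_gene_test(g, ["v0"], {"zz"}, rng.normal(size=50))


class TestGeneScoreAssociation:
    def test_perfect_score_p_zero(self, rng):
        s = rng.normal(size=100)
        res = gene_score_association(s, s, family="linear")
        assert res.p_value < 1e-100

    def test_l1_logistic_score_test(self, rng):
        n = 600
        s = rng.normal(size=n)
        logit = -0.8 + 1.0 * s
        y = rng.binomial(1, 1 / (1 + np.exp(-logit))).astype(float)
        res = gene_score_association(s, y, family="l1_logistic")
        assert res.p_value < 1e-6
        assert res.l1_selected is True
        null = gene_score_association(rng.normal(size=n), y, family="l1_logistic")
        assert null.p_value > 1e-4

    def test_zero_variance_flagged(self, rng):
        res = gene_score_association(np.zeros(50), rng.normal(size=50))
        assert res.p_value is None and "zero-variance" in res.note


class TestBonferroni:
    def test_published_gene_count(self):
        exact, rounded = bonferroni_threshold(18_946)
        assert rounded == pytest.approx(2.6e-6)

    def test_trivial_counts(self):
        assert bonferroni_threshold(1)[0] == 0.05
        assert bonferroni_threshold(10)[0] == pytest.approx(5e-3)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


def test_mixture_sf_two_methods_consistent(rng):
    lam = rng.uniform(0.2, 3.0, 6)
    for q in (1.0, 5.0, 12.0):
        a = mixture_chisq_sf(q, lam, "moment_matching")
        b = mixture_chisq_sf(q, lam, "numeric_inversion")
        assert a == pytest.approx(b, rel=0.1, abs=5e-4)
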