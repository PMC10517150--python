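"""Gene-collapsing association tests.

Two families of collapsing tests over the rare variants of a gene:

* **CADD-weighted gene scores** ("GenRisk-style"): per-sample burden
  score_i = sum_v Beta(1,25)(MAF_v) * CADD_v * dosage_iv, tested with
  linear regression (continuous response) or L1-logistic regression with an
  unpenalized score test for inference (binary responses).

* **SKAT / burden / SKAT-O**: variance-component score statistics
  Q_rho = (1-rho) * sum_v (w_v g_v' r)^2 + rho * (sum_v w_v g_v' r)^2 on the
  null-model residuals r, with rho = 0 the SKAT kernel test, rho = 1 the
  weighted burden test, and SKAT-O the minimum p over a rho grid with the
  standard one-dimensional numerical-integration correction for the grid
  search.  Null p-values come from the weighted mixture of 1-df chi-squares
  whose weights are the eigenvalues of the covariate-projected weighted
  kernel, evaluated either by moment matching (default) or by numerical
  inversion of the characteristic function.

Genome-wide significance for gene-based tests is declared at p < 2.6e-6
(Bonferroni for ~19k genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special, stats
import statsmodels.api as sm

from .assoc_single import impute_dosage

GENE_ALPHA = 2.6e-6

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


@dataclass
class SkatConfig:
    weight_a: float = 1.0
    weight_b: float = 25.0
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID
    p_method: str = "moment_matching"  # or "numeric_inversion"
    n_resampling: int = 2000
    small_sample_cases: int = 200  # binary permutation fallback below this

    def __post_init__(self) -> None:
        g = self.rho_grid
        if list(g) != sorted(g) or g[0] < 0 or g[-1] > 1:
            raise ValueError("rho_grid must be sorted within [0, 1]")
        if 0.0 not in g or 1.0 not in g:
            raise ValueError("rho_grid must include 0 and 1")


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """(exact, 2-significant-figure) Bonferroni threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    exact = alpha / n_tests
    if exact == 0:
        return 0.0, 0.0
    digits = -int(np.floor(np.log10(abs(exact)))) + 1
    return exact, float(np.round(exact, digits))


# ---------------------------------------------------------------------------
# Weights and gene scores
# ---------------------------------------------------------------------------

def beta_maf_weight(maf, a: float = 1.0, b: float = 25.0) -> np.ndarray | float:
    """Beta(a, b) density at the MAF; with a=1, w = 25 (1-maf)^24.

    Upweights rarer variants; MAF outside [0, 1] raises.
    """
    m = np.asarray(maf, float)
    if (m < 0).any() or (m > 1).any():
        raise ValueError("MAF must lie in [0, 1]")
    w = stats.beta.pdf(m, a, b) if a != 1.0 else b * (1.0 - m) ** (b - 1.0)
    return float(w) if np.isscalar(maf) else np.asarray(w)


def gene_score(
    G_gene: np.ndarray,
    maf: np.ndarray,
    cadd: np.ndarray,
    a: float = 1.0,
    b: float = 25.0,
) -> np.ndarray:
    """Per-sample CADD-weighted burden: sum_v w(maf_v) * cadd_v * dosage_iv.

    Missing dosages are mean-imputed (to 2 x MAF); negative deleteriousness
    scores raise.  A sample with no scored alternate allele scores exactly 0.
    """
    cadd = np.asarray(cadd, float)
    if (cadd < 0).any():
        raise ValueError("deleteriousness (CADD) scores must be nonnegative")
    G = np.asarray(G_gene, float)
    if G.ndim == 1:
        G = G[:, None]
    G = np.column_stack([impute_dosage(G[:, j]) if np.isnan(G[:, j]).any() else G[:, j]
                         for j in range(G.shape[1])])
    w = np.asarray(beta_maf_weight(maf, a, b), float)
    return G @ (w * cadd)


# ---------------------------------------------------------------------------
# Null models
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """Covariate-only null fit used by all score-type tests."""

    y: np.ndarray
    design: np.ndarray  # [1, X]
    family: str
    resid: np.ndarray
    sigma2: float | None = None  # linear only
    mu: np.ndarray | None = None  # logistic only
    v: np.ndarray | None = None  # mu(1-mu)
    _qr_q: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n(self) -> int:
        return len(self.y)


def fit_null_model(y: np.ndarray, X: np.ndarray | None = None, family: str = "linear") -> NullModel:
    y = np.asarray(y, float)
    n = len(y)
    design = np.ones((n, 1)) if X is None or not np.size(X) \
        else np.column_stack([np.ones(n), np.asarray(X, float)])
    if family == "linear":
        Q, _ = np.linalg.qr(design)
        resid = y - Q @ (Q.T @ y)
        sigma2 = float(resid @ resid / (n - design.shape[1]))
        return NullModel(y, design, "linear", resid, sigma2=sigma2, _qr_q=Q)
    if family == "logistic":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
        mu = np.asarray(fit.fittedvalues)
        v = mu * (1 - mu)
        Xv = design * np.sqrt(v)[:, None]
        Q, _ = np.linalg.qr(Xv)
        return NullModel(y, design, "logistic", y - mu, mu=mu, v=v, _qr_q=Q)
    raise ValueError(f"unknown family {family!r}")


def _score_and_half(null: NullModel, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score vector s and half-matrix Z1 with Cov(s) = Z1' Z1.

    linear:   s = Z'r / sigma,        Z1 = (I - QQ') Z
    logistic: s = Z'(y - mu),         Z1 = (I - QQ') V^{1/2} Z  (Q from the
              V-weighted design QR)
    """
    if null.family == "linear":
        sig = np.sqrt(null.sigma2)
        s = Z.T @ null.resid / sig
        Z1 = Z - null._qr_q @ (null._qr_q.T @ Z)
        return s, Z1
    s = Z.T @ null.resid
    Zv = Z * np.sqrt(null.v)[:, None]
    Z1 = Zv - null._qr_q @ (null._qr_q.T @ Zv)
    return s, Z1


# ---------------------------------------------------------------------------
# Mixture-of-chi-squares survival function
# ---------------------------------------------------------------------------

def _liu_params(lam: np.ndarray) -> tuple[float, float, float, float, float, float]:
    c1, c2 = lam.sum(), (lam**2).sum()
    c3, c4 = (lam**3).sum(), (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        d = s1 * a**3 - a**2
        df = a**2 - 2 * d
    else:
        df = 1.0 / s2
        a = np.sqrt(df)
        d = 0.0
    mu_x = df + d
    sigma_x = np.sqrt(2.0 * (df + 2 * d))
    return df, d, mu_q, sigma_q, mu_x, sigma_x


def _chi2_sf(x: float, df: float, nc: float = 0.0) -> float:
    """(Noncentral) chi-square survival function via scipy.special (fast)."""
    if x <= 0:
        return 1.0
    if nc > 0:
        return float(min(1.0, max(0.0, 1.0 - special.chndtr(x, df, nc))))
    return float(special.gammaincc(df / 2.0, x / 2.0))


def _liu_sf(q: float, lam: np.ndarray) -> float:
    df, d, mu_q, sigma_q, mu_x, sigma_x = _liu_params(lam)
    t = (q - mu_q) / sigma_q
    return _chi2_sf(t * sigma_x + mu_x, df, d)


def _liu_quantile(prob_tail: float, lam: np.ndarray) -> float:
    """q with P(mixture > q) = prob_tail, by the moment-matched chi-square."""
    df, d, mu_q, sigma_q, mu_x, sigma_x = _liu_params(lam)
    x = stats.ncx2.isf(prob_tail, df, d) if d > 0 else stats.chi2.isf(prob_tail, df)
    return float((x - mu_x) / sigma_x * sigma_q + mu_q)


def _imhof_sf(q: float, lam: np.ndarray) -> float:
    """P(sum lam_i chi2_1 > q) by numerical inversion (Imhof's formula).

    The oscillatory inversion integral sin(phi(u) - qu/2) / (u rho(u)) is
    split as sin(phi)cos(qu/2) - cos(phi)sin(qu/2); the smooth factors are
    integrated against the trigonometric weights with Fourier quadrature
    (QAWF), which stays accurate for arbitrarily many oscillations, plus an
    ordinary quadrature on the smooth initial stretch.
    """
    lam = np.asarray(lam, float)

    def phi(u: float) -> float:
        return 0.5 * np.arctan(lam * u).sum()

    def log_rho(u: float) -> float:
        return 0.25 * np.log1p((lam * u) ** 2).sum()

    def full(u: float) -> float:
        return np.sin(phi(u) - 0.5 * q * u) / (u * np.exp(log_rho(u)))

    def f_cos(u: float) -> float:
        return np.sin(phi(u)) / (u * np.exp(log_rho(u)))

    def f_sin(u: float) -> float:
        return np.cos(phi(u)) / (u * np.exp(log_rho(u)))

    a = 1.0 / max(q, lam.max(), 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        v0, _ = integrate.quad(full, 0.0, a, limit=200)
        v1, _ = integrate.quad(f_cos, a, np.inf, weight="cos", wvar=0.5 * q,
                               limit=400)
        v2, _ = integrate.quad(f_sin, a, np.inf, weight="sin", wvar=0.5 * q,
                               limit=400)
    return float(np.clip(0.5 + (v0 + v1 - v2) / np.pi, 1e-14, 1.0))


def mixture_chisq_sf(q: float, lam: np.ndarray, method: str = "moment_matching") -> float:
    """Survival function of sum_i lam_i * chi2(1 df) at q."""
    lam = np.asarray(lam, float)
    lam = lam[lam > max(lam.max(), 0) * 1e-10] if lam.size else lam
    if lam.size == 0:
        raise ValueError("no positive eigenvalues")
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], 1))
    if method == "moment_matching":
        return _liu_sf(q, lam)
    if method == "numeric_inversion":
        return _imhof_sf(q, lam)
    raise ValueError(f"unknown p-value method {method!r}")


# ---------------------------------------------------------------------------
# SKAT / burden / SKAT-O
# ---------------------------------------------------------------------------

def _rho_half(m: int, rho: float) -> np.ndarray:
    """Symmetric square root of R_rho = (1-rho) I + rho 1 1'."""
    a = np.sqrt(1.0 - rho)
    b = (np.sqrt(1.0 - rho + m * rho) - a) / m
    return a * np.eye(m) + b * np.ones((m, m))


def _prepare_gene(
    G_gene: np.ndarray,
    null: NullModel,
    config: SkatConfig,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Impute, weight and project the gene's dosage columns.

    Returns (score vector s, half matrix Z1, weights).  Monomorphic columns
    are kept (zero contribution) but an all-monomorphic gene raises.
    """
    G = np.asarray(G_gene, float)
    if G.ndim == 1:
        G = G[:, None]
    G = np.column_stack([impute_dosage(G[:, j]) if np.isnan(G[:, j]).any() else G[:, j]
                         for j in range(G.shape[1])])
    if (G.std(axis=0) == 0).all():
        raise ValueError("gene has no polymorphic variants")
    if weights is None:
        freq = G.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        weights = np.asarray(beta_maf_weight(maf, config.weight_a, config.weight_b))
    Z = G * weights
    s, Z1 = _score_and_half(null, Z)
    return s, Z1, weights


def _q_stat(s: np.ndarray, rho: float) -> float:
    return float((1.0 - rho) * (s**2).sum() + rho * s.sum() ** 2)


def skat_test(
    G_gene: np.ndarray,
    y: np.ndarray,
    X: np.ndarray | None = None,
    config: SkatConfig | None = None,
    rho: float = 0.0,
    family: str = "linear",
    null: NullModel | None = None,
    weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Score statistic Q_rho and its asymptotic p-value for one gene.

    rho = 0 is the SKAT variance-component test, rho = 1 the weighted burden
    test.  For binary traits with fewer than ``config.small_sample_cases``
    cases the p-value is estimated by residual permutation instead of the
    chi-square-mixture asymptotics.
    """
    config = config or SkatConfig()
    if null is None:
        null = fit_null_model(y, X, family)
    s, Z1, _ = _prepare_gene(G_gene, null, config, weights)
    q = _q_stat(s, rho)
    if null.family == "logistic" and null.y.sum() < config.small_sample_cases:
        return q, _permutation_p(null, Z1_to_Z(null, G_gene, config, weights), rho,
                                 config.n_resampling)
    m = len(s)
    half = _rho_half(m, rho)
    lam = np.linalg.eigvalsh(half @ (Z1.T @ Z1) @ half)
    lam = lam[lam > max(lam.max(), 0) * 1e-10]
    return q, mixture_chisq_sf(q, lam, config.p_method)


def Z1_to_Z(null: NullModel, G_gene: np.ndarray, config: SkatConfig,
            weights: np.ndarray | None) -> np.ndarray:
    """Weighted (unprojected) genotype matrix for permutation resampling."""
    G = np.asarray(G_gene, float)
    if G.ndim == 1:
        G = G[:, None]
    G = np.column_stack([impute_dosage(G[:, j]) if np.isnan(G[:, j]).any() else G[:, j]
                         for j in range(G.shape[1])])
    if weights is None:
        freq = G.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        weights = np.asarray(beta_maf_weight(maf, config.weight_a, config.weight_b))
    return G * weights


def _permutation_p(null: NullModel, Z: np.ndarray, rho: float, n_perm: int,
                   seed: int = 0) -> float:
    """Permutation p-value: permute null residuals, recompute Q_rho."""
    rng = np.random.default_rng(seed)
    r = null.resid
    scale = np.sqrt(null.sigma2) if null.family == "linear" else 1.0
    s_obs = Z.T @ r / scale
    q_obs = _q_stat(s_obs, rho)
    perms = np.array([rng.permutation(r) for _ in range(n_perm)]).T  # n x B
    S = Z.T @ perms / scale  # m x B
    q_perm = (1 - rho) * (S**2).sum(axis=0) + rho * S.sum(axis=0) ** 2
    return float((1 + (q_perm >= q_obs).sum()) / (1 + n_perm))


def skat_o(
    G_gene: np.ndarray,
    y: np.ndarray,
    X: np.ndarray | None = None,
    config: SkatConfig | None = None,
    family: str = "linear",
    null: NullModel | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """SKAT-O p-value: minimum over the rho grid with the one-dimensional
    integration correction for the grid search.

    Follows the standard construction: per-rho p-values and their minimum T,
    per-rho T-quantiles of the null mixtures, then
    p = 1 - Int P(kappa < min_rho (q_min(rho) - tau(rho) x) / (1-rho)) f_chi1(x) dx
    over the 1-df chi-square x that carries the burden direction.  Capped
    above by T * |grid|; equals the single-variant score-test p for a
    one-variant gene.
    """
    config = config or SkatConfig()
    if null is None:
        null = fit_null_model(y, X, family)
    s, Z1, _ = _prepare_gene(G_gene, null, config, weights)
    m = len(s)
    Lam = Z1.T @ Z1

    if m == 1:
        lam = Lam[0, 0]
        if lam <= 0:
            raise ValueError("gene has no polymorphic variants")
        return float(stats.chi2.sf(s[0] ** 2 / lam, 1))

    if null.family == "logistic" and null.y.sum() < config.small_sample_cases:
        return _skat_o_permutation(null, Z1_to_Z(null, G_gene, config, weights),
                                   config)

    if config.p_method == "numeric_inversion":
        # high-precision option: evaluate the rho-grid min-p statistic on the
        # exact asymptotic null s ~ N(0, Z1'Z1) by seeded Monte Carlo, which
        # avoids the approximation error of the one-dimensional grid-search
        # correction below
        return _skat_o_gaussian_mc(s, Lam, config)

    rhos = np.minimum(np.asarray(config.rho_grid, float), 0.999)
    p_rho = np.empty(len(rhos))
    lam_rho = []
    for i, rho in enumerate(rhos):
        half = _rho_half(m, rho)
        lam = np.linalg.eigvalsh(half @ Lam @ half)
        lam = lam[lam > max(lam.max(), 0) * 1e-10]
        lam_rho.append(lam)
        p_rho[i] = mixture_chisq_sf(_q_stat(s, rho), lam, config.p_method)
    T = float(p_rho.min())
    if T <= 0:
        return max(T, 1e-15)
    q_min = np.array([_liu_quantile(T, lam_rho[i]) for i in range(len(rhos))])

    # decomposition parameters from Z1 (Cov(s) = Z1'Z1)
    z_bar = Z1.mean(axis=1)
    z_bar_sq = float(z_bar @ z_bar)
    if z_bar_sq <= 0:
        return T  # degenerate: burden direction empty
    cof = (z_bar @ Z1) / z_bar_sq  # m-vector
    Z_res = Z1 - np.outer(z_bar, cof)
    lam_k = np.linalg.eigvalsh(Z_res.T @ Z_res)
    lam_k = lam_k[lam_k > max(lam_k.max(), 0) * 1e-10]
    if lam_k.size == 0:
        # rank-1 gene: all rho statistics coincide with the burden test
        return float(p_rho[-1])
    var_zeta = 4.0 * float(cof @ (Z_res.T @ Z_res) @ cof) * z_bar_sq
    mu_k = lam_k.sum()
    var_k = 2.0 * (lam_k**2).sum() + var_zeta
    tau = m**2 * rhos * z_bar_sq + (1.0 - rhos) * z_bar_sq * float(cof @ cof)

    sd_ratio = np.sqrt(max(var_k - var_zeta, 0.0)) / np.sqrt(var_k)
    liu_k = _liu_params(lam_k)

    def _surv_kappa(adj: float) -> float:
        # moment-matched survival of the non-burden component; kept smooth
        # and fast because it sits inside the outer quadrature
        if adj <= 0:
            return 1.0
        if lam_k.size == 1:
            return _chi2_sf(adj / lam_k[0], 1.0)
        df, d, mu_q, sigma_q, mu_x, sigma_x = liu_k
        return _chi2_sf((adj - mu_q) / sigma_q * sigma_x + mu_x, df, d)

    def integrand(x: float) -> float:
        thresh = ((q_min - tau * x) / (1.0 - rhos)).min()
        if thresh > lam_k.sum() * 1e4:
            surv = 0.0
        else:
            surv = _surv_kappa((thresh - mu_k) * sd_ratio + mu_k)
        # chi2(1 df) density
        return (1.0 - surv) * np.exp(-x / 2.0) / np.sqrt(2.0 * np.pi * x)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        area, _ = integrate.quad(integrand, 0.0, 40.0, limit=200)
    p = 1.0 - area
    p = min(p, T * len(rhos))  # guard against integration round-off at tiny T
    return float(np.clip(p, 1e-15, 1.0))


def _skat_o_gaussian_mc(s: np.ndarray, Sigma: np.ndarray, config: SkatConfig,
                        n_draws: int = 200_000, seed: int = 20240917) -> float:
    """SKAT-O omnibus p by Monte Carlo from the asymptotic score null.

    Draws s_b ~ N(0, Sigma), computes the per-rho empirical p of each draw
    and of the observed score, and returns the tail probability of the
    minimum.  Deterministic (fixed internal seed); MC standard error is
    about sqrt(p(1-p)/n_draws).
    """
    rng = np.random.default_rng(seed)
    m = len(s)
    vals, vecs = np.linalg.eigh(Sigma)
    vals = np.clip(vals, 0.0, None)
    A = vecs * np.sqrt(vals)
    S = np.column_stack([s, A @ rng.standard_normal((m, n_draws))])
    rhos = np.asarray(config.rho_grid, float)
    sumsq = (S**2).sum(axis=0)
    tot = S.sum(axis=0)
    q_all = np.stack([(1 - r) * sumsq + r * tot**2 for r in rhos])
    p_emp = np.empty_like(q_all)
    for i in range(q_all.shape[0]):
        srt = np.sort(q_all[i, 1:])
        p_emp[i] = (1 + n_draws - np.searchsorted(srt, q_all[i], side="left")) \
            / (1 + n_draws)
    t_stat = p_emp.min(axis=0)
    return float((1 + (t_stat[1:] <= t_stat[0]).sum()) / (1 + n_draws))


def _skat_o_permutation(null: NullModel, Z: np.ndarray, config: SkatConfig,
                        seed: int = 0) -> float:
    """Small-sample SKAT-O by residual permutation of the min-p statistic."""
    rng = np.random.default_rng(seed)
    rhos = np.asarray(config.rho_grid, float)
    B = config.n_resampling
    r = null.resid
    S = Z.T @ np.column_stack([r] + [rng.permutation(r) for _ in range(B)])
    q_all = np.stack([(1 - rho) * (S**2).sum(axis=0) + rho * S.sum(axis=0) ** 2
                      for rho in rhos])  # n_rho x (B+1)
    # per-rho empirical p (#permutations >= q) via sorted lookup, min over rho
    p_emp = np.empty_like(q_all)
    for i in range(q_all.shape[0]):
        srt = np.sort(q_all[i, 1:])
        p_emp[i] = (1 + B - np.searchsorted(srt, q_all[i], side="left")) / (1 + B)
    t_stat = p_emp.min(axis=0)
    return float((1 + (t_stat[1:] <= t_stat[0]).sum()) / (1 + B))


def conditional_gene_test(
    G_gene: np.ndarray,
    variant_ids: list[str],
    exclude: set[str] | list[str],
    y: np.ndarray,
    X: np.ndarray | None = None,
    config: SkatConfig | None = None,
    family: str = "linear",
) -> tuple[float, float | None]:
    """SKAT-O p before/after removing the named variants from the gene.

    Returns (p, p_conditioned); p_conditioned is None (flagged) when the
    exclusion empties the gene.
    """
    exclude = set(exclude)
    unknown = exclude - set(variant_ids)
    if unknown:
        raise ValueError(f"exclusions not in gene: {sorted(unknown)}")
    p_full = skat_o(G_gene, y, X, config, family)
    keep = [j for j, v in enumerate(variant_ids) if v not in exclude]
    if not keep:
        return p_full, None
    G = np.asarray(G_gene, float)
    p_cond = skat_o(G[:, keep], y, X, config, family)
    return p_full, p_cond


# ---------------------------------------------------------------------------
# Gene-score association
# ---------------------------------------------------------------------------

@dataclass
class GeneScoreResult:
    gene: str
    effect: float | None
    p_value: float | None
    n: int
    family: str
    l1_selected: bool | None = None
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < GENE_ALPHA


def gene_score_association(
    scores: np.ndarray,
    y: np.ndarray,
    X: np.ndarray | None = None,
    family: str = "linear",
    gene: str = "",
) -> GeneScoreResult:
    """Association of a per-sample gene score with the response.

    The score column is standardized before fitting.  linear: OLS Wald p.
    l1_logistic: the p-value is an unpenalized score test of the gene score
    against the covariate-only logistic null; an L1-penalized fit of
    [score, covariates] is kept as a stability/selection diagnostic
    (``l1_selected``).
    """
    s = np.asarray(scores, float)
    y = np.asarray(y, float)
    n = len(y)
    sd = s.std()
    if sd == 0:
        return GeneScoreResult(gene, None, None, n, family, note="zero-variance score")
    s_std = (s - s.mean()) / sd
    if family == "linear":
        design = np.column_stack([np.ones(n), s_std] if X is None or not np.size(X)
                                 else [np.ones(n), s_std, np.asarray(X, float)])
        fit = sm.OLS(y, design).fit()
        return GeneScoreResult(gene, float(fit.params[1]), float(fit.pvalues[1]), n, "linear")
    if family == "l1_logistic":
        null = fit_null_model(y, X, "logistic")
        u = float(s_std @ null.resid)
        sv = s_std * np.sqrt(null.v)
        proj = null._qr_q.T @ sv
        var = float(sv @ sv - proj @ proj)
        if var <= 0:
            return GeneScoreResult(gene, None, None, n, "l1_logistic",
                                   note="degenerate score variance")
        p = float(stats.chi2.sf(u * u / var, 1))
        selected = None
        try:
            from sklearn.linear_model import LogisticRegression

            feats = s_std[:, None] if X is None or not np.size(X) \
                else np.column_stack([s_std, np.asarray(X, float)])
            l1 = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0,
                                    max_iter=500).fit(feats, y.astype(int))
            selected = bool(abs(l1.coef_[0][0]) > 1e-8)
            effect = float(l1.coef_[0][0])
        except Exception:
            effect = u / var  # score-based effect approximation
        return GeneScoreResult(gene, effect, p, n, "l1_logistic", l1_selected=selected)
    raise ValueError(f"unknown family {family!r}; want linear|l1_logistic")
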