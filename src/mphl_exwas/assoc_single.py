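"""Single-variant association, conditioning, LD and genomic inflation.

Single-variant tests are GWAS-style GLMs: ordinary least squares for the
continuous pattern response, logistic regression for the binary models,
with Wald two-sided p-values on the dosage coefficient.  Continuous
covariates are normalized to mean 0, variance 1 before fitting; missing
dosages are mean-imputed to 2 x MAF.  Conditioning appends lead-SNP
dosages (same chromosome) as covariates.  Genome-wide significance for
single variants is declared at p < 8e-9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

SINGLE_VARIANT_ALPHA = 8e-9

_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549364...


@dataclass
class AssocResult:
    """Per-unit (variant or gene) association result.

    ``effect`` is beta on the linear scale, or an odds ratio for logistic
    fits.  ``conditioned_on`` lists the lead SNPs included as covariates.
    """

    unit_id: str
    effect: float | None
    se: float | None
    p_value: float | None
    n: int
    model: str = ""
    family: str = "linear"
    conditioned_on: tuple[str, ...] = ()
    converged: bool = True
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < SINGLE_VARIANT_ALPHA


@dataclass
class LdStats:
    r_squared: float
    d_prime: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12 and 0.0 <= self.d_prime <= 1.0 + 1e-12):
            raise ValueError("LD statistics out of [0, 1]")


def standardize_covariates(X: pd.DataFrame) -> pd.DataFrame:
    """Normalize continuous columns to mean 0, variance 1 (population
    variance, ddof=0); one-hot encode categoricals with the reference level
    dropped.  Zero-variance continuous columns raise, naming the column."""
    out: dict[str, np.ndarray] = {}
    for col in X.columns:
        s = X[col]
        if pd.api.types.is_numeric_dtype(s):
            v = s.to_numpy(float)
            sd = v.std()  # ddof=0
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"covariate column {col!r} has zero variance")
            out[col] = (v - v.mean()) / sd
        else:
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:  # drop reference level
                out[f"{col}_{lev}"] = (s.astype(str) == lev).to_numpy(float)
    return pd.DataFrame(out, index=X.index)


def impute_dosage(dosage: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages (mean of non-missing = 2 x sample MAF)."""
    d = np.asarray(dosage, float).copy()
    miss = np.isnan(d)
    if miss.all():
        raise ValueError("all dosages missing")
    if miss.any():
        d[miss] = d[~miss].mean()
    return d


def _design(dosage: np.ndarray, X: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(dosage), dosage]
    if X is not None and X.size:
        cols.append(np.asarray(X, float))
    return np.column_stack(cols)


def single_variant_test(
    dosage: np.ndarray,
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame | None = None,
    family: str = "linear",
    unit_id: str = "",
    model: str = "",
    conditioned_on: tuple[str, ...] = (),
) -> AssocResult:
    """GLM association of one variant: OLS (linear) or ML logistic Wald test.

    Monomorphic dosages and non-converged logistic fits are returned flagged
    with ``p_value=None`` rather than raising.
    """
    if X is not None and isinstance(X, pd.DataFrame):
        X = X.to_numpy(float)
    d = impute_dosage(dosage)
    y = np.asarray(y, float)
    n = len(y)
    if d.std() == 0:
        return AssocResult(unit_id, None, None, None, n, model, family,
                           conditioned_on, converged=False, note="monomorphic")
    design = _design(d, X)
    if family == "linear":
        fit = sm.OLS(y, design).fit()
        return AssocResult(unit_id, float(fit.params[1]), float(fit.bse[1]),
                           float(fit.pvalues[1]), n, model, "linear", conditioned_on)
    if family == "logistic":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception as exc:  # perfect separation, singularities
            return AssocResult(unit_id, None, None, None, n, model, "logistic",
                               conditioned_on, converged=False, note=str(exc))
        if not converged:
            return AssocResult(unit_id, None, None, None, n, model, "logistic",
                               conditioned_on, converged=False, note="non-convergence")
        return AssocResult(unit_id, float(np.exp(fit.params[1])), float(fit.bse[1]),
                           float(fit.pvalues[1]), n, model, "logistic", conditioned_on)
    raise ValueError(f"unknown family {family!r}")


def conditional_single_variant_test(
    dosage: np.ndarray,
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame | None,
    lead_genotypes: np.ndarray | None,
    lead_ids: tuple[str, ...] = (),
    family: str = "linear",
    unit_id: str = "",
    model: str = "",
) -> AssocResult:
    """Single-variant test conditioned on same-chromosome lead-SNP dosages.

    Lead dosages are mean-imputed and appended to the covariates; collinear
    lead columns are dropped with a warning.  An empty lead set reduces to
    the unconditional test.
    """
    if lead_genotypes is None or np.size(lead_genotypes) == 0:
        return single_variant_test(dosage, y, X, family, unit_id, model)
    L = np.asarray(lead_genotypes, float)
    if L.ndim == 1:
        L = L[:, None]
    L = np.column_stack([impute_dosage(L[:, j]) for j in range(L.shape[1])])
    if X is not None and isinstance(X, pd.DataFrame):
        X = X.to_numpy(float)
    base = np.column_stack([np.ones(len(L))] + ([X] if X is not None and np.size(X) else []))
    kept: list[int] = []
    used = list(lead_ids) if lead_ids else [f"lead{j}" for j in range(L.shape[1])]
    kept_ids: list[str] = []
    for j in range(L.shape[1]):
        trial = np.column_stack([base] + [L[:, k] for k in kept] + [L[:, j]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept.append(j)
            kept_ids.append(used[j])
        else:
            warnings.warn(f"dropping collinear lead-SNP covariate {used[j]}")
    Xc = np.column_stack([X] + [L[:, k] for k in kept]) if X is not None and np.size(X) \
        else L[:, kept]
    return single_variant_test(dosage, y, Xc, family, unit_id, model,
                               conditioned_on=tuple(kept_ids))


def linear_scan(G: np.ndarray, y: np.ndarray, X: np.ndarray | None = None) -> pd.DataFrame:
    """Vectorized per-column OLS Wald tests of y on each dosage column.

    Covariates (plus intercept) are projected out of both response and
    dosages (Frisch-Waugh); the returned frame has beta, se, t, p per
    column.  Missing dosages must be imputed beforehand; monomorphic
    columns get NaN results.
    """
    y = np.asarray(y, float)
    n = len(y)
    base = np.ones((n, 1)) if X is None or not np.size(X) \
        else np.column_stack([np.ones(n), np.asarray(X, float)])
    Q, _ = np.linalg.qr(base)
    ry = y - Q @ (Q.T @ y)
    RG = G - Q @ (Q.T @ G)
    gg = np.einsum("ij,ij->j", RG, RG)
    gy = RG.T @ ry
    df = n - base.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = ry @ ry - beta * gy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    bad = gg <= 1e-12
    for arr in (beta, se, t):
        arr[bad] = np.nan
    p[bad] = np.nan
    return pd.DataFrame({"beta": beta, "se": se, "t": t, "p": p})


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_stats(hapA: np.ndarray, hapB: np.ndarray) -> LdStats:
    """D' and r-squared from two binary haplotype vectors of equal length.

    Male X genotypes are haplotypes directly; autosomal genotypes must be
    phased first (or use :func:`ld_stats_unphased`).  Monomorphic loci are
    undefined and raise.
    """
    a = np.asarray(hapA, float)
    b = np.asarray(hapB, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("haplotype vectors must be 1-D and of equal length")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("haplotypes must be binary")
    pA, pB = a.mean(), b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic locus: LD undefined")
    pAB = (a * b).mean()
    D = pAB - pA * pB
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    if D >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if d_max == 0 else abs(D) / d_max
    return LdStats(r_squared=float(min(r2, 1.0)), d_prime=float(min(d_prime, 1.0)))


def ld_stats_unphased(g1: np.ndarray, g2: np.ndarray,
                      max_iter: int = 100, tol: float = 1e-10) -> LdStats:
    """EM haplotype-frequency estimation for two unphased diploid loci,
    followed by the standard D'/r-squared formulas."""
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    keep = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[keep], g2[keep]
    n = len(g1)
    p1, p2 = g1.mean() / 2, g2.mean() / 2
    if p1 in (0, 1) or p2 in (0, 1):
        raise ValueError("monomorphic locus: LD undefined")
    dh = (g1 == 1) & (g2 == 1)  # double heterozygotes: phase ambiguous
    n_dh = int(dh.sum())
    # for every other genotype pair the 1-1 haplotype count is g1*g2/2
    fixed = float((g1[~dh] * g2[~dh]).sum() / 2.0)
    f11 = p1 * p2  # start at linkage equilibrium
    for _ in range(max_iter):
        f10 = p1 - f11
        f01 = p2 - f11
        f00 = 1 - p1 - p2 + f11
        denom = f11 * f00 + f10 * f01
        frac = 0.5 if denom <= 0 else f11 * f00 / denom
        f_new = (fixed + n_dh * frac) / (2 * n)
        if abs(f_new - f11) < tol:
            f11 = f_new
            break
        f11 = f_new
    D = f11 - p1 * p2
    r2 = D * D / (p1 * (1 - p1) * p2 * (1 - p2))
    d_max = min(p1 * (1 - p2), (1 - p1) * p2) if D >= 0 else min(p1 * p2, (1 - p1) * (1 - p2))
    return LdStats(r_squared=float(min(r2, 1.0)),
                   d_prime=float(0.0 if d_max == 0 else min(abs(D) / d_max, 1.0)))


# ---------------------------------------------------------------------------
# Genomic inflation and PC-count selection
# ---------------------------------------------------------------------------

def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median association chi-square (1 df,
    from two-sided p) divided by the null chi-square median 0.4549."""
    p = np.asarray(p_values, float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


def select_pc_count(
    genotypes: np.ndarray,
    y: np.ndarray,
    X_base: np.ndarray | None,
    pc_matrix: np.ndarray,
    k_range: range = range(1, 21),
    lambda_tol: float = 0.05,
) -> tuple[int, dict[int, float]]:
    """Pick how many top PCs to include by minimizing genomic inflation.

    For each k in ``k_range`` the common-variant panel is scanned (linear
    Wald tests) with ``X_base`` plus the top-k PC columns, and the genomic
    inflation factor of the resulting p-values is computed.  Returns the
    smallest k whose lambda is within ``lambda_tol`` of the minimum (lambda
    is a noisy median statistic; an exact argmin would be unstable between
    equivalent k), together with the full lambda-by-k profile.
    """
    pc_matrix = np.asarray(pc_matrix, float)
    if pc_matrix.shape[1] < max(k_range):
        raise ValueError("pc_matrix has fewer columns than max(k_range)")
    G = np.asarray(genotypes, float)
    if np.isnan(G).any():
        G = np.column_stack([impute_dosage(G[:, j]) for j in range(G.shape[1])])
    lambdas: dict[int, float] = {}
    for k in k_range:
        covs = pc_matrix[:, :k] if X_base is None or not np.size(X_base) \
            else np.column_stack([X_base, pc_matrix[:, :k]])
        res = linear_scan(G, y, covs)
        lambdas[k] = genomic_lambda(res["p"].dropna().to_numpy())
    best = min(lambdas.values())
    k_star = min(k for k in k_range if lambdas[k] <= best + lambda_tol)
    return k_star, lambdas
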