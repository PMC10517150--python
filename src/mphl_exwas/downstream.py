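"""Downstream analyses: enrichment, common-variant dependence, risk models.

* Locus-window enrichment: one-tailed (greater) Fisher's exact test of the
  associated-gene set against genes lying within +/-1 Mb of GWAS lead SNPs,
  over the tested-gene background (closed 1-based intervals; a gene is
  "near" a locus when any base of its span falls in the window).
* Gene-set enrichment: the same test with membership defined by a target
  gene list (e.g. monogenic trichosis genes).
* GWAS / gene-score dependence: per locus (lead +/- 500 kb), each common
  variant is tested with and without the local gene score as an extra
  covariate; variants with |delta(-log10 p)| < 1 are "minimally impacted".
* PRS: clumping + thresholding of summary statistics, best-fit threshold by
  incremental variance explained on a tuning split.
* Risk models: a 25-50-25 split; the first 25% estimates per-gene weights
  to collapse the gene-score matrix into one scalar risk score, the middle
  50% trains L2-logistic models with 10-fold cross-validation, the last 25%
  yields AUC / average precision for three case contrasts (pattern 4 vs 1,
  3-4 vs 1, 2-4 vs 1) and three feature sets (PRS, gene score, combined).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_single import impute_dosage, linear_scan


# ---------------------------------------------------------------------------
# Enrichment (one-tailed Fisher)
# ---------------------------------------------------------------------------

def _fisher_greater(table: np.ndarray) -> tuple[float, float]:
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def locus_window_enrichment(
    assoc_genes: set[str],
    all_tested_genes: set[str],
    lead_snps: pd.DataFrame,
    gene_positions: pd.DataFrame,
    window: int = 1_000_000,
) -> tuple[float, float]:
    """Enrichment of associated genes within +/-window of lead SNPs.

    ``gene_positions`` needs columns gene, chrom, start, end.  The 2x2 table
    is (associated x near-locus) over the background ``all_tested_genes``;
    returns (sample odds ratio, one-tailed greater Fisher p).
    """
    if not all_tested_genes:
        raise ValueError("empty background gene set")
    if not assoc_genes <= all_tested_genes:
        raise ValueError("assoc_genes must be a subset of the background")
    gp = gene_positions[gene_positions["gene"].isin(all_tested_genes)]
    near: set[str] = set()
    leads_by_chrom = {c: grp["pos"].to_numpy() for c, grp in lead_snps.groupby("chrom")}
    for _, row in gp.iterrows():
        pos = leads_by_chrom.get(row["chrom"])
        if pos is None:
            continue
        # closed-interval overlap of [start,end] with [lead-window, lead+window]
        if ((row["start"] <= pos + window) & (row["end"] >= pos - window)).any():
            near.add(row["gene"])
    a = len(assoc_genes & near)
    b = len(assoc_genes) - a
    c = len(near) - a
    d = len(all_tested_genes) - len(assoc_genes) - c
    return _fisher_greater(np.array([[a, b], [c, d]]))


def gene_set_enrichment(
    assoc_genes: set[str],
    background: set[str],
    target_set: set[str],
) -> tuple[float, float]:
    """One-tailed Fisher enrichment of associated genes in a target list.

    Membership is intersection with the background; a target set disjoint
    from the background leaves the table undefined and raises.
    """
    if not background:
        raise ValueError("empty background gene set")
    if not assoc_genes <= background:
        raise ValueError("assoc_genes must be a subset of the background")
    members = target_set & background
    if not members:
        raise ValueError("target set is disjoint from the background; table undefined")
    a = len(assoc_genes & members)
    b = len(assoc_genes) - a
    c = len(members) - a
    d = len(background) - len(assoc_genes) - c
    return _fisher_greater(np.array([[a, b], [c, d]]))


# ---------------------------------------------------------------------------
# GWAS / gene-score dependence
# ---------------------------------------------------------------------------

def gwas_genescore_dependence(
    common_dosages: np.ndarray,
    variant_meta: pd.DataFrame,
    y: np.ndarray,
    X: np.ndarray | None,
    gene_scores: pd.DataFrame,
    leads: pd.DataFrame,
    gene_positions: pd.DataFrame,
    flank: int = 500_000,
) -> tuple[pd.DataFrame, float]:
    """Per-locus dependence of common-variant signals on local gene scores.

    For every lead SNP, common variants within ``flank`` are paired with the
    genes whose span overlaps the locus window.  Each (variant, gene) pair
    gets p_base (covariates only) and p_corrected (covariates + that gene's
    standardized score); delta = -log10(p_base) + log10(p_corrected), and a
    pair is "minimally impacted" when |delta| < 1.  A zero-variance gene
    score contributes delta = 0 exactly.  Returns the pair table and the
    fraction of pairs minimally impacted; loci with no overlapping gene are
    skipped with a note row.
    """
    G = np.asarray(common_dosages, float)
    rows = []
    for _, lead in leads.iterrows():
        lo, hi = lead["pos"] - flank, lead["pos"] + flank
        vmask = ((variant_meta["chrom"] == lead["chrom"])
                 & (variant_meta["pos"] >= lo) & (variant_meta["pos"] <= hi)).to_numpy()
        genes = gene_positions[(gene_positions["chrom"] == lead["chrom"])
                               & (gene_positions["start"] <= hi)
                               & (gene_positions["end"] >= lo)]["gene"]
        genes = [g for g in genes if g in gene_scores.columns]
        if not vmask.any():
            continue
        if not genes:
            rows.append({"lead": lead["snp_id"], "variant_id": None, "gene": None,
                         "p_base": np.nan, "p_corrected": np.nan, "delta": np.nan,
                         "note": "no genes at locus"})
            continue
        sub = G[:, vmask]
        sub = np.column_stack([impute_dosage(sub[:, j]) for j in range(sub.shape[1])])
        vids = variant_meta.loc[vmask, "variant_id"].tolist()
        base = linear_scan(sub, y, X)
        for gene in genes:
            score = gene_scores[gene].to_numpy(float)
            if score.std() == 0:
                for vid, pb in zip(vids, base["p"]):
                    rows.append({"lead": lead["snp_id"], "variant_id": vid, "gene": gene,
                                 "p_base": pb, "p_corrected": pb, "delta": 0.0, "note": ""})
                continue
            score_std = (score - score.mean()) / score.std()
            Xg = score_std[:, None] if X is None or not np.size(X) \
                else np.column_stack([X, score_std])
            corr = linear_scan(sub, y, Xg)
            delta = -np.log10(base["p"].to_numpy()) + np.log10(corr["p"].to_numpy())
            for vid, pb, pc, dl in zip(vids, base["p"], corr["p"], delta):
                rows.append({"lead": lead["snp_id"], "variant_id": vid, "gene": gene,
                             "p_base": pb, "p_corrected": pc, "delta": dl, "note": ""})
    table = pd.DataFrame(rows)
    tested = table.dropna(subset=["delta"])
    frac = float((tested["delta"].abs() < 1.0).mean()) if len(tested) else np.nan
    return table, frac


# ---------------------------------------------------------------------------
# Polygenic risk score (clumping + thresholding)
# ---------------------------------------------------------------------------

@dataclass
class PrsResult:
    scores: np.ndarray  # best-fit per-sample PRS
    best_threshold: float
    kept_snps: list[str]
    profile: dict[float, np.ndarray] = field(default_factory=dict)
    r2_by_threshold: dict[float, float] = field(default_factory=dict)


def _ld_clump(meta: pd.DataFrame, dosages: np.ndarray,
              clump_r2: float, clump_kb: float) -> list[int]:
    """Greedy clumping: keep best-p SNPs, drop neighbors in LD.

    Works on column indices of ``dosages``; deterministic given the input
    (ties in p broken by snp id so SNP input order cannot matter).
    """
    order = meta.sort_values(["p", "snp_id"]).index.tolist()
    kept: list[int] = []
    removed: set[int] = set()
    window = clump_kb * 1000.0
    for i in order:
        if i in removed:
            continue
        kept.append(i)
        gi = dosages[:, meta.index.get_loc(i)]
        for j in order:
            if j == i or j in removed or j in kept:
                continue
            if meta.loc[j, "chrom"] != meta.loc[i, "chrom"]:
                continue
            if abs(meta.loc[j, "pos"] - meta.loc[i, "pos"]) > window:
                continue
            gj = dosages[:, meta.index.get_loc(j)]
            if gi.std() == 0 or gj.std() == 0:
                continue
            r = np.corrcoef(gi, gj)[0, 1]
            if r * r > clump_r2:
                removed.add(j)
    return kept


def compute_prs(
    dosages: np.ndarray,
    summary_stats: pd.DataFrame,
    y_tune: np.ndarray | None = None,
    tune_idx: np.ndarray | None = None,
    X_tune: np.ndarray | None = None,
    clump_r2: float = 0.1,
    clump_kb: float = 250.0,
    p_grid: tuple[float, ...] = (5e-8, 1e-5, 1e-3, 7.85e-3, 0.05, 0.5, 1.0),
) -> PrsResult:
    """Clumping + thresholding PRS over a common-variant panel.

    ``summary_stats`` (snp_id, chrom, pos, beta, p) come from a GWAS with no
    sample overlap with the target cohort.  After greedy LD clumping (best p
    first, removing neighbors with r^2 > clump_r2 within clump_kb), each
    threshold in ``p_grid`` scores samples as sum(beta x dosage) over
    surviving SNPs with p < threshold.  The best-fit threshold maximizes
    incremental R^2 over covariates on the tuning split (``tune_idx`` rows);
    without a tuning response the largest threshold is returned.
    """
    meta = summary_stats.reset_index(drop=True)
    if len(meta) != dosages.shape[1]:
        raise ValueError("summary_stats rows must match dosage columns")
    D = np.column_stack([impute_dosage(dosages[:, j]) for j in range(dosages.shape[1])])
    kept = _ld_clump(meta, D, clump_r2, clump_kb)
    if not any((meta.loc[kept, "p"] < max(p_grid)).tolist()):
        raise ValueError("no SNP survives any threshold")
    profile: dict[float, np.ndarray] = {}
    r2s: dict[float, float] = {}
    for thr in p_grid:
        use = [i for i in kept if meta.loc[i, "p"] < thr]
        if not use:
            continue
        cols = [meta.index.get_loc(i) for i in use]
        score = D[:, cols] @ meta.loc[use, "beta"].to_numpy(float)
        profile[thr] = score
        if y_tune is not None:
            idx = np.arange(len(score)) if tune_idx is None else np.asarray(tune_idx)
            s = score[idx]
            if s.std() == 0:
                r2s[thr] = 0.0
                continue
            res = linear_scan(s[:, None], np.asarray(y_tune, float), X_tune)
            t = res["t"].iloc[0]
            df = len(idx) - 2 - (0 if X_tune is None or not np.size(X_tune)
                                 else np.asarray(X_tune).shape[1])
            r2s[thr] = float(t**2 / (t**2 + df))  # partial R^2 of the score
    if not profile:
        raise ValueError("no SNP survives any threshold")
    if r2s:
        best = max(r2s, key=lambda k: (r2s[k], -k))
    else:
        best = max(profile)
    best_ids = [meta.loc[i, "snp_id"] for i in kept if meta.loc[i, "p"] < best]
    return PrsResult(scores=profile[best], best_threshold=float(best),
                     kept_snps=best_ids, profile=profile, r2_by_threshold=r2s)


# ---------------------------------------------------------------------------
# Risk models
# ---------------------------------------------------------------------------

def auc_rank(y_true: np.ndarray, score: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties share ranks)."""
    y = np.asarray(y_true, float)
    s = np.asarray(score, float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


CONTRASTS = {"severe": (4,), "moderate": (3, 4), "slight": (2, 3, 4)}


@dataclass
class RiskModelReport:
    auc: pd.DataFrame  # contrasts x feature sets
    average_precision: pd.DataFrame
    split_sizes: tuple[int, int, int]
    gene_weights: pd.Series
    notes: list[str] = field(default_factory=list)


def collapse_gene_scores(gene_scores: pd.DataFrame, y_weighting: np.ndarray,
                         rows: np.ndarray) -> tuple[pd.Series, np.ndarray]:
    """Estimate per-gene weights on the weighting split and collapse.

    Weights are univariate OLS effects (sign and magnitude) of the
    continuous response on each standardized gene score, estimated on the
    ``rows`` subset; the collapsed scalar is the weight-sum over genes.
    """
    S = gene_scores.to_numpy(float)
    mu = S.mean(axis=0)
    sd = S.std(axis=0)
    sd[sd == 0] = 1.0
    Sz = (S - mu) / sd
    sub = Sz[rows]
    yc = np.asarray(y_weighting, float)
    yc = yc - yc.mean()
    weights = sub.T @ yc / np.maximum((sub**2).sum(axis=0), 1e-12)
    w = pd.Series(weights, index=gene_scores.columns)
    return w, Sz @ weights


def fit_risk_models(
    pattern: np.ndarray,
    prs: np.ndarray,
    gene_scores: pd.DataFrame,
    covariates: np.ndarray | None = None,
    split: tuple[float, float, float] = (0.25, 0.50, 0.25),
    cv_folds: int = 10,
    seed: int = 0,
) -> RiskModelReport:
    """Train and evaluate PRS-only / gene-score-only / combined risk models.

    The cohort is split 25-50-25 (seeded): per-gene weights and the scalar
    gene risk score come from the first block, L2-logistic models with
    ``cv_folds``-fold cross-validated regularization train on the second,
    and AUC / average precision are reported on the held-out third for the
    severe (4 vs 1), moderate (3-4 vs 1) and slight (2-4 vs 1) contrasts.
    Pattern 1 is always the control class; a contrast missing a class in
    the test split is omitted with a note.
    """
    from sklearn.linear_model import LogisticRegressionCV
    from sklearn.metrics import average_precision_score

    pattern = np.asarray(pattern, int)
    n = len(pattern)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_w = int(round(split[0] * n))
    n_t = int(round(split[1] * n))
    idx_w, idx_train, idx_test = perm[:n_w], perm[n_w:n_w + n_t], perm[n_w + n_t:]

    weights, gene_risk = collapse_gene_scores(gene_scores, pattern[idx_w], idx_w)
    prs = np.asarray(prs, float)
    feature_sets = {
        "prs_only": prs[:, None],
        "gene_scores_only": gene_risk[:, None],
        "combined": np.column_stack([prs, gene_risk]),
    }
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, float)
        feature_sets = {k: np.column_stack([v, C]) for k, v in feature_sets.items()}

    auc = pd.DataFrame(index=list(CONTRASTS), columns=list(feature_sets), dtype=float)
    ap = pd.DataFrame(index=list(CONTRASTS), columns=list(feature_sets), dtype=float)
    notes: list[str] = []
    for contrast, case_patterns in CONTRASTS.items():
        is_case = np.isin(pattern, case_patterns)
        is_ctrl = pattern == 1
        keep_train = idx_train[(is_case | is_ctrl)[idx_train]]
        keep_test = idx_test[(is_case | is_ctrl)[idx_test]]
        y_train = is_case[keep_train].astype(int)
        y_test = is_case[keep_test].astype(int)
        if len(np.unique(y_train)) < 2 or len(np.unique(y_test)) < 2:
            notes.append(f"contrast {contrast}: fewer than 2 classes; omitted")
            continue
        for name, F in feature_sets.items():
            scaler_mu = F[keep_train].mean(axis=0)
            scaler_sd = F[keep_train].std(axis=0)
            scaler_sd[scaler_sd == 0] = 1.0
            Ftr = (F[keep_train] - scaler_mu) / scaler_sd
            Fte = (F[keep_test] - scaler_mu) / scaler_sd
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                clf = LogisticRegressionCV(cv=cv_folds, Cs=5, max_iter=1000,
                                           scoring="neg_log_loss").fit(Ftr, y_train)
            prob = clf.predict_proba(Fte)[:, 1]
            auc.loc[contrast, name] = auc_rank(y_test, prob)
            ap.loc[contrast, name] = float(average_precision_score(y_test, prob))
    return RiskModelReport(auc=auc, average_precision=ap,
                           split_sizes=(len(idx_w), len(idx_train), len(idx_test)),
                           gene_weights=weights, notes=notes)
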