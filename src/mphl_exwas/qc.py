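"""Variant- and sample-level quality control and consequence masks.

Filter order used by the pipeline: sample missingness -> variant
missingness -> exact Hardy-Weinberg -> subset MAF -> consequence mask.
Thresholds follow the strict-inequality conventions of the source analysis:
samples/variants are kept when their missing rate is < 5%, variants are kept
when the HWE exact p-value is > 1e-6 and when 0 < MAF < 1% within the
phenotype-model sample subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

# Consequence vocabulary.  The nonsynonymous (moderate + high impact) set is
# the coding/splice/ablation categories used for the collapsing and
# single-variant tests; the high-impact tier is the stricter subset.
HIGH_IMPACT = frozenset({
    "frameshift",
    "splice_acceptor",
    "splice_donor",
    "start_lost",
    "stop_gained",
    "stop_lost",
    "transcript_ablation",
    "transcript_amplification",
})

MODERATE_IMPACT = frozenset({
    "missense",
    "inframe_insertion",
    "inframe_deletion",
    "regulatory_region_ablation",
})

NO_IMPACT = frozenset({"synonymous", "intron", "utr", "intergenic"})

KNOWN_CONSEQUENCES = HIGH_IMPACT | MODERATE_IMPACT | NO_IMPACT

NONSYNONYMOUS = HIGH_IMPACT | MODERATE_IMPACT


def impact_of(consequence: str) -> str:
    """Map a consequence category to its impact tier {high, moderate, none}."""
    if consequence in HIGH_IMPACT:
        return "high"
    if consequence in MODERATE_IMPACT:
        return "moderate"
    if consequence in NO_IMPACT:
        return "none"
    raise ValueError(f"unknown consequence category {consequence!r}")


@dataclass
class QcReport:
    """Counts of samples/variants removed per filter, in application order."""

    n_samples_in: int = 0
    n_variants_in: int = 0
    samples_removed_missingness: int = 0
    variants_removed_missingness: int = 0
    variants_removed_hwe: int = 0
    variants_removed_maf: int = 0
    variants_removed_consequence: int = 0
    steps: list[tuple[str, int]] = field(default_factory=list)

    def record(self, step: str, removed: int) -> None:
        self.steps.append((step, removed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "n_removed"])


def missingness_filter(
    G: GenotypeMatrix,
    sample_thresh: float = 0.05,
    variant_thresh: float = 0.05,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples then variants whose missing fraction is >= threshold.

    Sample filtering runs first; variant missing rates are recomputed on the
    surviving samples.  Strict "<" keeps, as in the source thresholds.
    """
    report = report or QcReport(n_samples_in=G.n_samples, n_variants_in=G.n_variants)
    miss = G.missing_mask
    keep_s = miss.mean(axis=1) < sample_thresh
    report.samples_removed_missingness = int((~keep_s).sum())
    report.record("sample_missingness", report.samples_removed_missingness)
    G = G.subset(samples=keep_s)
    if G.n_samples:
        keep_v = G.missing_mask.mean(axis=0) < variant_thresh
    else:
        keep_v = np.ones(G.n_variants, dtype=bool)
    report.variants_removed_missingness = int((~keep_v).sum())
    report.record("variant_missingness", report.variants_removed_missingness)
    return G.subset(variants=keep_v), report


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (same parity) that are no more likely than the
    observed one, under the exact distribution

        P(n_Aa | n, n_A) proportional to  n! / (n_AA! n_Aa! n_aa!) * 2^n_Aa.

    Probabilities are built by the stable two-sided recurrence over the
    heterozygote count.  Monomorphic input gives p = 1; all-zero counts are
    undefined and return 1.
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        import warnings

        warnings.warn("HWE test undefined for zero genotypes; returning p=1")
        return 1.0
    n_A = 2 * n_AA + n_Aa  # rare-vs-common symmetric: use minor allele count
    n_minor = min(n_A, 2 * n - n_A)
    if n_minor == 0:
        return 1.0
    # possible heterozygote counts share the parity of the minor-allele count
    het_max = n_minor if (n_minor % 2 == n_Aa % 2) else n_minor - 1
    hets = np.arange(n_Aa % 2, het_max + 1, 2)
    probs = np.zeros(len(hets))
    # start from the largest het count and recurse downward:
    # P(h-2)/P(h) = h*(h-1) / (4 * (n_rr+1) * (n_cc+1)) with r=minor, c=common
    probs[-1] = 1.0
    for k in range(len(hets) - 1, 0, -1):
        h = hets[k]
        n_rr = (n_minor - h) // 2
        n_cc = n - n_rr - h
        probs[k - 1] = probs[k] * h * (h - 1) / (4.0 * (n_rr + 1) * (n_cc + 1))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_filter(
    G: GenotypeMatrix,
    p_thresh: float = 1e-6,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove diploid variants with HWE exact p <= p_thresh (strict ">" keeps).

    Hemizygous male-X columns bypass the test: the exact test assumes diploid
    genotypes and an all-male X has no heterozygotes.
    """
    report = report or QcReport(n_samples_in=G.n_samples, n_variants_in=G.n_variants)
    keep = np.ones(G.n_variants, dtype=bool)
    for j in range(G.n_variants):
        if G.is_hemizygous[j]:
            continue
        col = G.dosage[:, j]
        col = col[~np.isnan(col)]
        counts = [(col == 0).sum(), (col == 1).sum(), (col == 2).sum()]
        keep[j] = hwe_exact(*counts) > p_thresh
    report.variants_removed_hwe = int((~keep).sum())
    report.record("hwe", report.variants_removed_hwe)
    return G.subset(variants=keep), report


def maf_filter(
    G: GenotypeMatrix,
    subset_sample_ids: list[str] | None = None,
    maf_max: float = 0.01,
) -> np.ndarray:
    """Boolean keep-mask for variants with 0 < MAF < maf_max within a subset.

    MAF is computed on non-missing dosages of the subset samples; hemizygous
    {0,2} columns land on the allele scale through the same sum/(2n) formula.
    """
    if subset_sample_ids is not None:
        idx = {s: i for i, s in enumerate(G.sample_ids)}
        missing = [s for s in subset_sample_ids if s not in idx]
        if missing:
            raise ValueError(f"subset samples not in genotype matrix: {missing[:3]}")
        G = G.subset(samples=np.array([idx[s] for s in subset_sample_ids]))
    maf = G.minor_allele_frequency()
    with np.errstate(invalid="ignore"):
        return np.asarray((maf > 0) & (maf < maf_max) & ~np.isnan(maf))


def consequence_mask(variants: pd.DataFrame, tier: str) -> set[str]:
    """Variant ids passing a consequence tier.

    tier = "nonsynonymous": moderate + high impact coding/splice/ablation
    categories; "high_impact": the strict subset (frameshift, splice
    acceptor/donor, start/stop-altering, transcript ablation/amplification);
    "all": no consequence filtering (rare-variant gene-score input).
    """
    unknown = set(variants["consequence"]) - KNOWN_CONSEQUENCES
    if unknown:
        raise ValueError(f"unknown consequence categories: {sorted(unknown)}")
    if tier == "all":
        sel = np.ones(len(variants), dtype=bool)
    elif tier == "nonsynonymous":
        sel = variants["consequence"].isin(NONSYNONYMOUS).to_numpy()
    elif tier == "high_impact":
        sel = variants["consequence"].isin(HIGH_IMPACT).to_numpy()
    else:
        raise ValueError(f"unknown tier {tier!r}; want nonsynonymous|high_impact|all")
    return set(variants.loc[sel, "variant_id"])
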