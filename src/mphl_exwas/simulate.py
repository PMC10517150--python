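"""Synthetic cohort generator.

Generates all-male cohorts with the statistical structure the association
pipeline assumes: rare variants (MAF < 1%) with impact-tier-ordered
deleteriousness scores, genotypes in Hardy-Weinberg proportions (with an
optional violation flag for QC testing), a liability-threshold phenotype
with polygenic and rare-burden components that progresses with age on a
4-level pattern scale, noisy multi-visit self-reports, kinship pairs, and
batch / PC-like covariates.

Randomness is fully determined by ``SimulationConfig.seed``; each operation
draws from its own child stream so outputs are bit-identical across runs
and insensitive to call order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig
from .io import GenotypeMatrix, write_vcf
from .qc import KNOWN_CONSEQUENCES, impact_of

# category sampling weights for simulated variant consequences
_CONSEQ_PROBS = {
    "missense": 0.35,
    "synonymous": 0.25,
    "intron": 0.05,
    "frameshift": 0.06,
    "inframe_insertion": 0.04,
    "inframe_deletion": 0.04,
    "splice_acceptor": 0.03,
    "splice_donor": 0.03,
    "start_lost": 0.02,
    "stop_gained": 0.05,
    "stop_lost": 0.02,
    "transcript_ablation": 0.02,
    "regulatory_region_ablation": 0.02,
    "transcript_amplification": 0.02,
}
assert set(_CONSEQ_PROBS) <= KNOWN_CONSEQUENCES

# deleteriousness-score gamma parameters (shape, scale) per impact tier;
# chosen so scores are stochastically increasing none < moderate < high,
# with tier means ~3 / ~12 / ~30 on a CADD-like scale
_SCORE_GAMMA = {"none": (2.0, 1.5), "moderate": (3.0, 4.0), "high": (5.0, 6.0)}

_BASES = np.array(list("ACGT"))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def sample_ids(config: SimulationConfig) -> list[str]:
    return [f"S{i:06d}" for i in range(config.n_samples)]


def simulate_variants(config: SimulationConfig) -> pd.DataFrame:
    """Draw the variant annotation table.

    Genes are named G0000..; the last gene is always placed on chromosome
    "23" (X), the rest cycle through the autosomes.  MAFs are log-uniform on
    ``maf_spectrum``; consequence categories are drawn from a fixed mixture
    of the nonsynonymous set plus synonymous/other classes, and the
    deleteriousness score is an impact-tier-dependent gamma draw.
    """
    rng = _rng(config, 1)
    n_genes = config.n_genes
    if isinstance(config.variants_per_gene, (int, np.integer)):
        counts = np.full(n_genes, int(config.variants_per_gene))
    else:
        counts = 1 + rng.poisson(config.variants_per_gene - 1.0, size=n_genes)
    genes = [f"G{g:04d}" for g in range(n_genes)]
    chroms = [str(g % 22 + 1) for g in range(n_genes)]
    chroms[-1] = "23"

    rows = []
    cats = list(_CONSEQ_PROBS)
    cat_p = np.array(list(_CONSEQ_PROBS.values()))
    lo, hi = config.maf_spectrum
    for g in range(n_genes):
        m = counts[g]
        base = 1_000_000 * (g + 1)
        offsets = np.sort(rng.choice(200_000, size=m, replace=False))
        if lo == hi:
            maf = np.full(m, lo)
        else:
            maf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=m))
        conseq = rng.choice(cats, size=m, p=cat_p)
        refs = _BASES[rng.integers(0, 4, size=m)]
        alts = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in refs])
        for v in range(m):
            impact = impact_of(conseq[v])
            shape, scale = _SCORE_GAMMA[impact]
            pos = int(base + offsets[v])
            rows.append({
                "variant_id": f"{chroms[g]}:{pos}:{refs[v]}:{alts[v]}",
                "chrom": chroms[g],
                "pos": pos,
                "maf": float(maf[v]),
                "consequence": conseq[v],
                "impact": impact,
                "score": float(rng.gamma(shape, scale)),
                "gene": genes[g],
            })
    variants = pd.DataFrame(rows)
    hwe_flag = np.zeros(len(variants), dtype=bool)
    if config.hwe_violation_rate > 0:
        auto = (variants["chrom"] != "23").to_numpy()
        hwe_flag[auto] = rng.random(auto.sum()) < config.hwe_violation_rate
    variants["hwe_flag"] = hwe_flag
    return variants


def simulate_genotypes(variants: pd.DataFrame, config: SimulationConfig) -> GenotypeMatrix:
    """Draw dosages: two allele draws per autosomal variant (HWE by
    construction), one draw coded {0, 2} on the X; per-entry missingness at
    ``genotype_missing_rate``; flagged variants get a heterozygote deficit
    (inbreeding-style, F = 0.6) for HWE-filter testing."""
    if len(variants) == 0:
        raise ValueError("variant table is empty")
    rng = _rng(config, 2)
    n = config.n_samples
    m = len(variants)
    maf = variants["maf"].to_numpy(float)
    hemi = (variants["chrom"] == "23").to_numpy()
    flagged = variants.get("hwe_flag", pd.Series(False, index=variants.index)).to_numpy(bool)

    dosage = rng.binomial(2, np.broadcast_to(maf, (n, m))).astype(float)
    if hemi.any():
        dosage[:, hemi] = 2.0 * rng.binomial(1, np.broadcast_to(maf[hemi], (n, hemi.sum())))
    F = 0.6
    for j in np.flatnonzero(flagged & ~hemi):
        p = maf[j]
        q = 1 - p
        probs = [q * q + F * p * q, 2 * p * q * (1 - F), p * p + F * p * q]
        dosage[:, j] = rng.choice([0.0, 1.0, 2.0], size=n, p=probs)
    if config.genotype_missing_rate > 0:
        dosage[rng.random((n, m)) < config.genotype_missing_rate] = np.nan
    return GenotypeMatrix(sample_ids(config), variants["variant_id"].tolist(), dosage, hemi)


@dataclass
class LiabilityPhenotype:
    """Latent liability plus the deterministic pattern-at-age map.

    pattern(age) = 1 + #{thresholds below liability + age_slope*(age - age_min)};
    nondecreasing in age because age_slope >= 0.
    """

    sample_ids: list[str]
    liability: np.ndarray
    polygenic: np.ndarray
    thresholds: tuple[float, float, float]
    age_slope: float
    age_min: float

    def pattern(self, ages: np.ndarray) -> np.ndarray:
        """Pattern 1-4 for each sample at its own age (vector of ages)."""
        drift = self.liability + self.age_slope * (np.asarray(ages, float) - self.age_min)
        return 1 + (drift[:, None] > np.asarray(self.thresholds)[None, :]).sum(axis=1)

    def pattern_at(self, index: int, age: float) -> int:
        drift = self.liability[index] + self.age_slope * (age - self.age_min)
        return int(1 + (drift > np.asarray(self.thresholds)).sum())


def simulate_liability_phenotype(
    G: GenotypeMatrix,
    variants: pd.DataFrame,
    config: SimulationConfig,
    covariates: pd.DataFrame | None = None,
) -> LiabilityPhenotype:
    """Liability = polygenic (variance polygenic_h2) + per-causal-gene effect
    x standardized deleterious-allele burden + Gaussian noise (variance
    1 - polygenic_h2), optionally confounded with the first PC covariate."""
    if config.age_slope < 0:
        raise ConfigurationError("age_slope must be nonnegative (progressive phenotype)")
    rng = _rng(config, 3)
    n = G.n_samples
    known_genes = set(variants["gene"])
    polygenic = rng.normal(0.0, np.sqrt(config.polygenic_h2), size=n)
    liability = polygenic + rng.normal(0.0, np.sqrt(1.0 - config.polygenic_h2), size=n)
    vid_col = {v: j for j, v in enumerate(G.variant_ids)}
    for gene, effect in config.causal_genes.items():
        if gene not in known_genes:
            raise ConfigurationError(f"causal gene {gene!r} absent from variant table")
        sel = variants[(variants["gene"] == gene) & variants["impact"].isin(["moderate", "high"])]
        cols = [vid_col[v] for v in sel["variant_id"] if v in vid_col]
        if not cols:
            continue
        burden = np.nan_to_num(G.dosage[:, cols]).sum(axis=1)
        sd = burden.std()
        if sd > 0:
            liability += effect * (burden - burden.mean()) / sd
    if config.confounding_strength != 0.0 and covariates is not None and "pc1" in covariates:
        liability += config.confounding_strength * covariates["pc1"].to_numpy(float)
    return LiabilityPhenotype(
        sample_ids=list(G.sample_ids),
        liability=liability,
        polygenic=polygenic,
        thresholds=tuple(config.liability_thresholds),
        age_slope=config.age_slope,
        age_min=config.age_range[0],
    )


def simulate_visits(phen: LiabilityPhenotype, config: SimulationConfig) -> pd.DataFrame:
    """Multi-visit self-reports: 1-4 visits at sorted uniform ages; each
    visit reports the true pattern(age) with probability 1 - misreport_rate,
    otherwise a uniformly drawn different pattern."""
    rng = _rng(config, 4)
    lo, hi = config.age_range
    rows = []
    n_visits = rng.choice([1, 2, 3, 4], size=len(phen.sample_ids),
                          p=np.asarray(config.n_visits_distribution))
    for i, sid in enumerate(phen.sample_ids):
        ages = np.sort(rng.uniform(lo, hi, size=n_visits[i]))
        for k, age in enumerate(ages, start=1):
            true = phen.pattern_at(i, age)
            if rng.random() < config.misreport_rate:
                reported = int(rng.choice([p for p in (1, 2, 3, 4) if p != true]))
            else:
                reported = true
            rows.append({"sample_id": sid, "visit_index": k,
                         "age": float(age), "pattern": reported})
    return pd.DataFrame(rows, columns=["sample_id", "visit_index", "age", "pattern"])


def simulate_kinship(config: SimulationConfig) -> list[tuple[str, str, float]]:
    """Random related pairs (coefficients near 0.25 / 0.125 / 0.0625,
    first- to third-degree) plus sub-threshold noise pairs."""
    rng = _rng(config, 5)
    ids = sample_ids(config)
    n = config.n_samples
    pairs: list[tuple[str, str, float]] = []
    seen: set[tuple[int, int]] = set()

    def draw_pair() -> tuple[int, int] | None:
        for _ in range(20):
            i, j = rng.choice(n, size=2, replace=False)
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen.add(key)
                return key
        return None

    n_related = rng.poisson(config.kinship_rate * n)
    n_noise = rng.poisson(config.kinship_rate * n / 2.0)
    for _ in range(n_related):
        key = draw_pair()
        if key is None:
            break
        base = rng.choice([0.25, 0.125, 0.0625])
        coef = float(np.clip(base * (1.0 + rng.normal(0.0, 0.05)), 0.045, 0.5))
        pairs.append((ids[key[0]], ids[key[1]], coef))
    for _ in range(n_noise):
        key = draw_pair()
        if key is None:
            break
        pairs.append((ids[key[0]], ids[key[1]], float(rng.uniform(0.005, 0.04))))
    return pairs


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Sequencing batch (categorical) and PC-like standard-normal columns."""
    rng = _rng(config, 6)
    n = config.n_samples
    df = pd.DataFrame({"sample_id": sample_ids(config)})
    df["batch"] = [f"B{b}" for b in rng.integers(0, config.batch_count, size=n)]
    for k in range(1, config.n_covariate_pcs + 1):
        df[f"pc{k}"] = rng.normal(size=n)
    return df


def simulate_cohort(config: SimulationConfig) -> dict:
    """Run the full generator; returns genotypes, variants, phenotype,
    visits, kinship and covariates in one bundle."""
    variants = simulate_variants(config)
    G = simulate_genotypes(variants, config)
    covariates = simulate_covariates(config)
    phen = simulate_liability_phenotype(G, variants, config, covariates=covariates)
    visits = simulate_visits(phen, config)
    kinship = simulate_kinship(config)
    return {"genotypes": G, "variants": variants, "phenotype": phen,
            "visits": visits, "kinship": kinship, "covariates": covariates}


def write_cohort(cohort: dict, outdir: str | os.PathLike) -> None:
    """Write a cohort bundle: one VCF per chromosome plus annotation,
    visit, kinship and covariate TSVs (schemas in the README)."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    G: GenotypeMatrix = cohort["genotypes"]
    variants: pd.DataFrame = cohort["variants"]
    for chrom in dict.fromkeys(variants["chrom"]):
        cols = variants.index[variants["chrom"] == chrom].to_numpy()
        write_vcf(G.subset(variants=cols), os.path.join(outdir, f"genotypes.chr{chrom}.vcf"))
    variants[["variant_id", "chrom", "pos", "maf", "consequence", "impact", "score", "gene"]].to_csv(
        os.path.join(outdir, "annotations.tsv"), sep="\t", index=False)
    cohort["visits"].to_csv(os.path.join(outdir, "visits.tsv"), sep="\t", index=False)
    pd.DataFrame(cohort["kinship"], columns=["sample_a", "sample_b", "kinship"]).to_csv(
        os.path.join(outdir, "kinship.tsv"), sep="\t", index=False)
    cohort["covariates"].to_csv(os.path.join(outdir, "covariates.tsv"), sep="\t", index=False)
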