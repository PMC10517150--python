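"""Configuration for the synthetic cohort generator.

The generator emulates the statistical structure of an all-male exome
cohort with a self-reported, age-progressive 4-level balding phenotype:
a rare-variant MAF spectrum (<1%), impact-tier-ordered deleteriousness
scores, a liability-threshold phenotype with a common-variant polygenic
component and rare-variant gene burdens, multi-visit self-report noise
(including implausible "improvements"), sequencing-batch and PC-like
stratification covariates, and third-degree kinship pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    n_samples : int
        Cohort size (all male).
    n_genes : int
        Number of genes; roughly one in twenty is placed on chromosome 23
        (X), at least one always.
    variants_per_gene : int | float
        If an ``int``, every gene gets exactly that many variants; if a
        ``float`` m, counts are drawn as 1 + Poisson(m - 1).
    maf_spectrum : tuple[float, float]
        (low, high) bounds of a log-uniform MAF distribution, support
        within (0, 0.01).  low == high gives a point mass.
    causal_genes : dict[str, float]
        Gene id -> burden effect size in liability SD units per SD of the
        standardized deleterious-allele burden.
    polygenic_h2 : float
        Variance of the common-variant polygenic liability component, in
        [0, 1).  Environmental noise variance is 1 - polygenic_h2 so the
        baseline (burden-free) liability has unit variance.
    age_range : tuple[float, float]
        [min, max] visit ages in years.
    liability_thresholds : tuple[float, float, float]
        Strictly increasing cutpoints mapping liability + age drift to
        patterns 1-4.
    age_slope : float
        Liability units per year of age.
    misreport_rate : float
        Per-visit probability of reporting a uniformly drawn wrong pattern.
    n_visits_distribution : tuple[float, ...]
        Probabilities over {1, 2, 3, 4} visits.
    kinship_rate : float
        Expected related (>= third-degree) pairs per sample.
    batch_count : int
        Number of sequencing batches.
    genotype_missing_rate : float
        Per-entry genotype missingness probability.
    hwe_violation_rate : float
        Fraction of autosomal variants flagged to violate HWE (heterozygote
        deficit), for QC testing.
    n_covariate_pcs : int
        Number of PC-like standard-normal covariate columns.
    confounding_strength : float
        Loading of the first PC-like covariate on liability (0 = none), to
        exercise covariate correction.
    seed : int
        Seed for all randomness; identical configs give bit-identical
        output.
    """

    n_samples: int = 2000
    n_genes: int = 100
    variants_per_gene: int | float = 5.0
    maf_spectrum: tuple[float, float] = (1e-4, 9.9e-3)
    causal_genes: dict[str, float] = field(default_factory=dict)
    polygenic_h2: float = 0.30
    age_range: tuple[float, float] = (39.0, 82.0)
    liability_thresholds: tuple[float, float, float] = (0.30, 0.95, 1.70)
    age_slope: float = 0.04
    misreport_rate: float = 0.05
    n_visits_distribution: tuple[float, ...] = (0.60, 0.25, 0.10, 0.05)
    kinship_rate: float = 0.01
    batch_count: int = 2
    genotype_missing_rate: float = 0.002
    hwe_violation_rate: float = 0.0
    n_covariate_pcs: int = 5
    confounding_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ConfigurationError("n_samples and n_genes must be positive")
        lo, hi = self.maf_spectrum
        if not (0.0 < lo <= hi < 0.01 + 1e-12):
            raise ConfigurationError(
                f"maf_spectrum support must lie within (0, 0.01), got {self.maf_spectrum}"
            )
        t = self.liability_thresholds
        if not (len(t) == 3 and t[0] < t[1] < t[2]):
            raise ConfigurationError("liability_thresholds must be 3 strictly increasing values")
        for name in ("misreport_rate", "genotype_missing_rate", "hwe_violation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.polygenic_h2 < 1.0:
            raise ConfigurationError("polygenic_h2 must be in [0, 1)")
        p = self.n_visits_distribution
        if len(p) != 4 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ConfigurationError("n_visits_distribution must be 4 probabilities summing to 1")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range must satisfy min < max")
        if isinstance(self.variants_per_gene, int):
            if self.variants_per_gene < 1:
                raise ConfigurationError("variants_per_gene must be >= 1")
        elif self.variants_per_gene < 1.0:
            raise ConfigurationError("mean variants_per_gene must be >= 1")
        if self.kinship_rate < 0:
            raise ConfigurationError("kinship_rate must be nonnegative")
        if self.batch_count < 1:
            raise ConfigurationError("batch_count must be >= 1")
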