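"""Shared study configuration for the analysis scripts.

One synthetic cohort is used across all numbered analyses; every script
regenerates it deterministically from this config (cheap), so scripts can
be run independently and in any order.  Three causal genes are planted:
two autosomal and the X-chromosome gene (G0099 lands on chromosome 23 with
100 genes), echoing an X-linked-heavy genetic architecture.
"""

from mphl_exwas.config import SimulationConfig

STUDY_SEED = 20240601

COHORT = SimulationConfig(
    n_samples=4000,
    n_genes=100,
    variants_per_gene=6.0,
    maf_spectrum=(2e-4, 9.9e-3),
    causal_genes={"G0010": 0.35, "G0042": 0.30, "G0099": 0.40},
    polygenic_h2=0.30,
    misreport_rate=0.05,
    kinship_rate=0.01,
    genotype_missing_rate=0.005,
    hwe_violation_rate=0.02,
    n_covariate_pcs=5,
    confounding_strength=0.15,
    seed=STUDY_SEED,
)

RESULTS_DIR = "results"
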