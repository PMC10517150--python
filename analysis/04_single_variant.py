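"""Single-variant association, lead-SNP conditioning, LD, PC selection.

Runs the continuous-model linear scan over rare nonsynonymous variants,
repeats it conditioned on a synthetic panel of common GWAS lead SNPs
(constructed to tag part of the polygenic signal), reports sentinel LD for
the top X-chromosome variant, and selects the PC count by genomic
inflation on a stratified common-variant panel.  Tables go to
results/single_variant/.
"""

import importlib
import os
import sys

sys.path.insert(0, os.path.dirname(__file__))

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from cohort_config import COHORT, RESULTS_DIR, STUDY_SEED  # noqa: E402

from mphl_exwas.assoc_single import (  # noqa: E402
    SINGLE_VARIANT_ALPHA,
    genomic_lambda,
    impute_dosage,
    ld_stats,
    linear_scan,
    select_pc_count,
    standardize_covariates,
)
from mphl_exwas.simulate import simulate_cohort  # noqa: E402

build_designs = importlib.import_module("02_phenotypes").build_designs
run_qc = importlib.import_module("03_variant_qc").run_qc


def make_lead_snps(cohort, n_leads=20, seed=STUDY_SEED + 5):
    """Synthetic common lead SNPs tagging the polygenic liability component.

    Allele frequency per sample is tilted by the (latent) polygenic score,
    so leads are phenotype-associated the way GWAS hits are; one lead per
    gene-rich region, positions set inside existing gene spans.
    """
    rng = np.random.default_rng(seed)
    phen = cohort["phenotype"]
    poly = (phen.polygenic - phen.polygenic.mean()) / max(phen.polygenic.std(), 1e-9)
    variants = cohort["variants"]
    spans = variants.groupby("gene").agg(chrom=("chrom", "first"),
                                         lo=("pos", "min"), hi=("pos", "max"))
    anchor_genes = [g for g in spans.index[:: max(1, len(spans) // n_leads)]][:n_leads]
    if "G0099" not in anchor_genes:  # keep the X-linked locus in the panel
        anchor_genes[-1] = "G0099"
    dosages, rows = [], []
    for j, gene in enumerate(anchor_genes):
        base = rng.uniform(0.2, 0.4)
        p = np.clip(base + 0.06 * poly, 0.02, 0.98)
        chrom = spans.loc[gene, "chrom"]
        if chrom == "23":
            d = 2.0 * rng.binomial(1, p)
        else:
            d = rng.binomial(2, p).astype(float)
        dosages.append(d)
        rows.append({"snp_id": f"lead{j:02d}", "chrom": chrom,
                     "pos": int(spans.loc[gene, "lo"]) + 500,
                     "effect_allele": "A", "beta": 0.1, "p": 1e-12,
                     "gene": gene})
    return pd.DataFrame(rows), np.column_stack(dosages)


def main() -> None:
    cohort = simulate_cohort(COHORT)
    _, designs, _ = build_designs(cohort)
    G2, kept, _, per_model = run_qc(cohort, designs)

    model = "continuous"
    frame = designs[model]
    roster = {s: i for i, s in enumerate(G2.sample_ids)}
    rows = np.array([roster[s] for s in frame["sample_id"]])
    y = frame["response"].to_numpy(float)

    cov = cohort["covariates"].set_index("sample_id").loc[frame["sample_id"]]
    cov = cov.assign(age=frame["age"].to_numpy())
    X = standardize_covariates(cov).to_numpy()

    vids = [v for v in G2.variant_ids if v in per_model[model]["nonsynonymous"]]
    cols = [G2.variant_ids.index(v) for v in vids]
    G = np.column_stack([impute_dosage(G2.dosage[rows, c]) for c in cols])

    scan = linear_scan(G, y, X).assign(variant_id=vids)
    ann = kept.set_index("variant_id")
    scan["gene"] = [ann.loc[v, "gene"] for v in vids]
    scan = scan.sort_values("p")

    leads, lead_dosages = make_lead_snps(cohort)
    lead_dosages = lead_dosages[[cohort["genotypes"].sample_ids.index(s)
                                 for s in frame["sample_id"]]]
    # conditioning: same-chromosome leads appended to the covariates
    cond_p = np.empty(len(vids))
    chroms = np.array([ann.loc[v, "chrom"] for v in vids])
    for chrom in np.unique(chroms):
        lsel = (leads["chrom"] == chrom).to_numpy()
        vsel = chroms == chrom
        Xc = X if not lsel.any() else np.column_stack([X, lead_dosages[:, lsel]])
        cond_p[vsel] = linear_scan(G[:, vsel], y, Xc)["p"].to_numpy()
    scan["p_conditioned"] = [cond_p[vids.index(v)] for v in scan["variant_id"]]

    outdir = os.path.join(RESULTS_DIR, "single_variant")
    os.makedirs(outdir, exist_ok=True)
    scan.to_csv(os.path.join(outdir, "continuous_scan.tsv"), sep="\t", index=False)

    n_sig = int((scan["p"] < SINGLE_VARIANT_ALPHA).sum())
    print(f"continuous model: {len(scan)} rare nonsynonymous variants tested, "
          f"{n_sig} genome-wide significant (p < {SINGLE_VARIANT_ALPHA:g})")
    print("top 5 variants (unconditioned / conditioned p):")
    print(scan.head(5)[["variant_id", "gene", "beta", "p", "p_conditioned"]]
          .to_string(index=False))

    # sentinel LD for the strongest X-chromosome variant (hemizygous
    # dosage/2 values are haplotypes)
    top_x = scan[scan["variant_id"].str.startswith("23:")].iloc[0]
    x_lead = leads[leads["chrom"] == "23"].index[0]
    hap_rare = G[:, vids.index(top_x["variant_id"])] / 2.0
    hap_lead = lead_dosages[:, x_lead] / 2.0
    ld = ld_stats(np.round(hap_rare), np.round(hap_lead))
    print(f"sentinel LD for {top_x['variant_id']}: r^2 = {ld.r_squared:.2e}, "
          f"D' = {ld.d_prime:.2f}")

    # PC-count selection on a stratified common panel (structure along pc1)
    rng = np.random.default_rng(STUDY_SEED + 9)
    pc1 = cov["pc1"].to_numpy()
    base = rng.uniform(0.1, 0.5, 800)
    freqs = np.clip(base[None, :] + 0.05 * pc1[:, None], 0.02, 0.98)
    panel = rng.binomial(2, freqs).astype(float)
    pcs = cov[[c for c in cov.columns if c.startswith("pc")]].to_numpy()
    k_star, lambdas = select_pc_count(panel, y, None, pcs,
                                      range(1, pcs.shape[1] + 1))
    print("genomic inflation by PC count:",
          {k: round(v, 3) for k, v in lambdas.items()})
    print(f"selected k* = {k_star} top PCs "
          f"(lambda {lambdas[k_star]:.3f}; exome-scan lambda "
          f"{genomic_lambda(scan['p'].dropna().to_numpy()):.3f})")
    leads.to_csv(os.path.join(outdir, "lead_snps.tsv"), sep="\t", index=False)


if __name__ == "__main__":
    main()
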