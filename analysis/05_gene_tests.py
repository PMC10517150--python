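"""Gene-collapsing tests: SKAT-O and CADD-weighted gene scores.

Per gene and phenotype model (continuous: linear; two-as-control:
logistic / L1-logistic), runs SKAT-O over rare nonsynonymous variants and
the gene-score association over all rare variants, flags genes at the
Bonferroni threshold, and reruns SKAT-O for the top gene after removing
its single most associated variant (conditional analysis).  Tables go to
results/gene_tests/.
"""

import importlib
import os
import sys

sys.path.insert(0, os.path.dirname(__file__))

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from cohort_config import COHORT, RESULTS_DIR  # noqa: E402

from mphl_exwas.assoc_single import impute_dosage, linear_scan, standardize_covariates  # noqa: E402
from mphl_exwas.simulate import simulate_cohort  # noqa: E402
from mphl_exwas.skat import (  # noqa: E402
    SkatConfig,
    bonferroni_threshold,
    conditional_gene_test,
    fit_null_model,
    gene_score,
    gene_score_association,
    skat_o,
)

build_designs = importlib.import_module("02_phenotypes").build_designs
run_qc = importlib.import_module("03_variant_qc").run_qc


def main() -> None:
    cohort = simulate_cohort(COHORT)
    _, designs, _ = build_designs(cohort)
    G2, kept, _, per_model = run_qc(cohort, designs)
    ann = kept.set_index("variant_id")
    cfg = SkatConfig()

    results = []
    cond_rows = []
    for model, family, score_family in (("continuous", "linear", "linear"),
                                        ("two_as_control", "logistic", "l1_logistic")):
        frame = designs[model]
        roster = {s: i for i, s in enumerate(G2.sample_ids)}
        rows = np.array([roster[s] for s in frame["sample_id"]])
        y = frame["response"].to_numpy(float)
        cov = cohort["covariates"].set_index("sample_id").loc[frame["sample_id"]]
        cov = cov.assign(age=frame["age"].to_numpy())
        X = standardize_covariates(cov).to_numpy()
        null = fit_null_model(y, X, family)

        skat_ids = per_model[model]["nonsynonymous"]
        score_ids = per_model[model]["rare"]
        for gene, sub in ann.groupby("gene"):
            vids = [v for v in sub.index if v in skat_ids]
            if vids:
                cols = [G2.variant_ids.index(v) for v in vids]
                G = G2.dosage[np.ix_(rows, cols)]
                G = np.column_stack([impute_dosage(G[:, j]) for j in range(len(cols))])
                if (G.std(axis=0) > 0).any():
                    p_skato = skat_o(G, y, X, cfg, family=family, null=null)
                    results.append({"gene": gene, "model": model, "method": "skat_o",
                                    "tier": "nonsynonymous", "n_variants": len(vids),
                                    "p": p_skato})
            svids = [v for v in sub.index if v in score_ids]
            if svids:
                cols = [G2.variant_ids.index(v) for v in svids]
                Gs = G2.dosage[np.ix_(rows, cols)]
                s = gene_score(Gs, sub.loc[svids, "maf"].to_numpy(),
                               sub.loc[svids, "score"].to_numpy())
                res = gene_score_association(s, y, X, family=score_family, gene=gene)
                if res.p_value is not None:
                    results.append({"gene": gene, "model": model, "method": "gene_score",
                                    "tier": "all", "n_variants": len(svids),
                                    "p": res.p_value})

        # conditional rerun for the top SKAT-O gene of this model
        model_hits = [r for r in results
                      if r["model"] == model and r["method"] == "skat_o"]
        top = min(model_hits, key=lambda r: r["p"])
        vids = [v for v in ann[ann["gene"] == top["gene"]].index if v in skat_ids]
        cols = [G2.variant_ids.index(v) for v in vids]
        G = np.column_stack([impute_dosage(G2.dosage[rows, c]) for c in cols])
        per_var = linear_scan(G, y, X)
        driver = vids[int(np.nanargmin(per_var["p"].to_numpy()))]
        p_full, p_cond = conditional_gene_test(G, vids, {driver}, y, X, cfg, family)
        cond_rows.append({"model": model, "gene": top["gene"], "excluded": driver,
                          "p": p_full, "p_conditioned": p_cond})

    table = pd.DataFrame(results)
    n_genes = table.loc[table["method"] == "skat_o", "gene"].nunique()
    _, threshold = bonferroni_threshold(n_genes)
    table["significant"] = table["p"] < threshold

    outdir = os.path.join(RESULTS_DIR, "gene_tests")
    os.makedirs(outdir, exist_ok=True)
    table.sort_values("p").to_csv(os.path.join(outdir, "gene_results.tsv"),
                                  sep="\t", index=False)
    cond = pd.DataFrame(cond_rows)
    cond.to_csv(os.path.join(outdir, "conditional.tsv"), sep="\t", index=False)

    print(f"Bonferroni threshold for {n_genes} genes: {threshold:g}")
    for (model, method), grp in table.groupby(["model", "method"]):
        hits = grp[grp["significant"]]
        print(f"{model} / {method}: {len(grp)} genes tested, "
              f"{len(hits)} significant ({', '.join(sorted(hits['gene']))})")
    print("\ntop 8 gene associations:")
    print(table.sort_values("p").head(8)[["gene", "model", "method", "p"]]
          .to_string(index=False))
    print("\nconditional SKAT-O (driver variant removed):")
    print(cond.to_string(index=False))


if __name__ == "__main__":
    main()
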