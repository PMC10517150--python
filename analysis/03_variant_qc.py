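"""Variant and sample QC for the exome-style analyses.

Pipeline: sample missingness (<5%) -> variant missingness (<5%) -> exact
HWE (p > 1e-6; hemizygous X bypassed) -> per-model-subset MAF (<1%) ->
consequence masks.  Writes the QC report and per-model filtered variant
lists to results/qc/.
"""

import importlib
import os
import sys

sys.path.insert(0, os.path.dirname(__file__))

import pandas as pd  # noqa: E402
from cohort_config import COHORT, RESULTS_DIR  # noqa: E402

from mphl_exwas.qc import consequence_mask, hwe_filter, maf_filter, missingness_filter  # noqa: E402
from mphl_exwas.simulate import simulate_cohort  # noqa: E402

build_designs = importlib.import_module("02_phenotypes").build_designs


def run_qc(cohort, designs):
    G = cohort["genotypes"]
    variants = cohort["variants"]
    G1, report = missingness_filter(G)
    G2, report = hwe_filter(G1, report=report)
    kept_variants = variants[variants["variant_id"].isin(G2.variant_ids)]
    per_model = {}
    for model, frame in designs.items():
        mask = maf_filter(G2, frame["sample_id"].tolist())
        ids = {v for v, keep in zip(G2.variant_ids, mask) if keep}
        nonsyn = consequence_mask(kept_variants, "nonsynonymous") & ids
        high = consequence_mask(kept_variants, "high_impact") & ids
        per_model[model] = {"rare": ids, "nonsynonymous": nonsyn, "high_impact": high}
    return G2, kept_variants, report, per_model


def main() -> None:
    cohort = simulate_cohort(COHORT)
    _, designs, _ = build_designs(cohort)
    G2, kept, report, per_model = run_qc(cohort, designs)

    outdir = os.path.join(RESULTS_DIR, "qc")
    os.makedirs(outdir, exist_ok=True)
    report.to_frame().to_csv(os.path.join(outdir, "qc_report.tsv"), sep="\t", index=False)
    print("QC removals, in order:")
    print(report.to_frame().to_string(index=False))
    # flagged HWE-violating variants should be the ones caught
    flagged = set(cohort["variants"].loc[cohort["variants"]["hwe_flag"], "variant_id"])
    removed_hwe = set(cohort["genotypes"].variant_ids) - set(G2.variant_ids)
    print(f"planted HWE violations: {len(flagged)}; removed by the HWE filter "
          f"(incl. missingness overlaps): {len(removed_hwe & flagged)}")
    rows = []
    for model, tiers in per_model.items():
        rows.append({"model": model, **{k: len(v) for k, v in tiers.items()}})
        for tier, ids in tiers.items():
            path = os.path.join(outdir, f"variants_{model}_{tier}.txt")
            with open(path, "w") as fh:
                fh.write("\n".join(sorted(ids)) + "\n")
    counts = pd.DataFrame(rows)
    counts.to_csv(os.path.join(outdir, "variant_counts.tsv"), sep="\t", index=False)
    print(counts.to_string(index=False))


if __name__ == "__main__":
    main()
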