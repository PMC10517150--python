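"""Reconcile multi-visit self-reports and build the four phenotype models.

Applies the sanity rules for implausible "improvements", prunes relatives
(kinship >= 0.0442; separately per model roster), and writes one design
table per model plus a case/control count summary to results/phenotypes/.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))

import pandas as pd  # noqa: E402
from cohort_config import COHORT, RESULTS_DIR  # noqa: E402

from mphl_exwas.phenotypes import MODELS, assign_model, prune_kinship, reconcile_all  # noqa: E402
from mphl_exwas.simulate import simulate_cohort  # noqa: E402


def build_designs(cohort):
    """Reconciled phenotypes and per-model kinship-pruned designs."""
    recon = reconcile_all(cohort["visits"])
    n_excluded = int(recon["pattern"].isna().sum())
    designs = {}
    for model in MODELS:
        design = assign_model(recon, model)
        roster = set(design.sample_ids)
        pairs = [p for p in cohort["kinship"] if p[0] in roster and p[1] in roster]
        kept = prune_kinship(design.sample_ids, pairs)
        frame = design.to_frame()
        designs[model] = frame[frame["sample_id"].isin(kept)].reset_index(drop=True)
    return recon, designs, n_excluded


def main() -> None:
    cohort = simulate_cohort(COHORT)
    recon, designs, n_excluded = build_designs(cohort)

    outdir = os.path.join(RESULTS_DIR, "phenotypes")
    os.makedirs(outdir, exist_ok=True)
    recon.to_csv(os.path.join(outdir, "reconciled.tsv"), sep="\t", index=False)

    print(f"reconciliation: {len(recon)} participants, {n_excluded} excluded "
          "(no plausible pattern)")
    rows = []
    for model, frame in designs.items():
        frame.to_csv(os.path.join(outdir, f"design_{model}.tsv"), sep="\t", index=False)
        if model == "continuous":
            rows.append({"model": model, "n": len(frame), "cases": "-", "controls": "-"})
            continue
        cases = int(frame["response"].sum())
        rows.append({"model": model, "n": len(frame), "cases": cases,
                     "controls": len(frame) - cases})
    summary = pd.DataFrame(rows)
    summary.to_csv(os.path.join(outdir, "model_counts.tsv"), sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
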