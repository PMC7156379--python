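#!/usr/bin/env python
"""Generate every synthetic input used by the downstream analysis scripts.

Writes to results/data/: the frozen 27-trial panel (trials.tsv), a
confounded observational cohort with immune-feature matrix
(clinical.tsv, features.tsv, cohort_truth.json), an ICB-treated cohort
with a sex effect on survival (icb_clinical.tsv), and an expression
matrix with embedded gene-set signal (expression.tsv, sets.gmt,
expression_truth.json).
"""

import json
from pathlib import Path

from icbsex import dataio, synth

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2020


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    panel = synth.synthetic_trial_panel()
    dataio.write_trials(panel, OUT / "trials.tsv")
    print(f"trial panel: {len(panel)} trials -> {OUT / 'trials.tsv'}")

    spec = synth.default_cohort_spec(seed=SEED)
    cohort, features, truth = synth.simulate_cohort(spec)
    cohort.to_csv(OUT / "clinical.tsv", sep="\t", index=False)
    dataio.write_matrix(features.values, OUT / "features.tsv")
    (OUT / "cohort_truth.json").write_text(json.dumps(truth, indent=2, default=str))
    n_f = (cohort["sex"] == "female").sum()
    print(
        f"observational cohort: n={len(cohort)} ({n_f} female), "
        f"{features.values.shape[1]} features (5 with a true +0.5 SD female shift)"
    )

    icb_spec = synth.CohortSimSpec(
        n=300, survival=(0.05, 0.35), confounder_effects={"age": 0.3}, seed=SEED + 1
    )
    icb_cohort, _, _ = synth.simulate_cohort(icb_spec)
    icb_cohort.to_csv(OUT / "icb_clinical.tsv", sep="\t", index=False)
    print("ICB cohort: n=300, true female log-HR = 0.35 (worse OS in females)")

    genes = [f"G{i + 1:04d}" for i in range(2000)]
    sets = synth.make_gene_sets(6, 30, genes, seed=SEED)
    expr, expr_truth = synth.simulate_expression(2000, 100, sets, shift=1.0, seed=SEED)
    dataio.write_matrix(expr, OUT / "expression.tsv")
    dataio.write_gmt(sets, OUT / "sets.gmt")
    (OUT / "expression_truth.json").write_text(json.dumps(expr_truth, indent=2))
    print(
        f"expression: {expr.shape[0]} genes x {expr.shape[1]} samples, "
        f"6 sets up-shifted (+1.0 log units) in {len(expr_truth['target_samples'])} samples"
    )


if __name__ == "__main__":
    main()
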