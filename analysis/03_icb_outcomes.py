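#!/usr/bin/env python
"""Survival and response comparisons in an ICB-treated cohort.

Univariate Cox (female vs male) with log-rank on the synthetic ICB cohort
— whose generator put a true female log-HR of 0.35 on overall survival —
and the benefit-rate arithmetic on the reported lung-cancer response
counts (16/32 female vs 6/24 male responders) with Fisher's exact test.
Outputs: results/icb_cox.tsv, results/icb_response.tsv.
"""

from pathlib import Path

import pandas as pd

from icbsex import dataio, survstats

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = dataio.read_cohort(ROOT / "data" / "icb_clinical.tsv")
    z = (cohort["sex"] == "female").to_numpy(dtype=float)
    t = cohort["os_time"].to_numpy(dtype=float)
    e = cohort["os_event"].to_numpy(dtype=float)

    fit = survstats.cox_univariate(t, e, z)
    logrank = survstats.logrank_test(t[z == 0], e[z == 0], t[z == 1], e[z == 1])
    pd.DataFrame(
        [{**vars(fit), "logrank_p": logrank.p_value}]
    ).to_csv(ROOT / "icb_cox.tsv", sep="\t", index=False, float_format="%.6g")
    print(
        f"female-vs-male OS: HR {fit.hr:.2f} (95% CI {fit.ci_lo:.2f}-{fit.ci_hi:.2f}), "
        f"Cox p={fit.p_value:.4f}, log-rank p={logrank.p_value:.4f} "
        f"[generator truth: log-HR 0.35, HR {2.718281828**0.35:.2f}]"
    )

    benefit_f, n_f, benefit_m, n_m = 16, 32, 6, 24
    fisher = survstats.fisher_exact_2x2(
        [[benefit_f, n_f - benefit_f], [benefit_m, n_m - benefit_m]]
    )
    pd.DataFrame(
        [
            {
                "benefit_female": benefit_f, "n_female": n_f,
                "rate_female_pct": 100.0 * benefit_f / n_f,
                "benefit_male": benefit_m, "n_male": n_m,
                "rate_male_pct": 100.0 * benefit_m / n_m,
                "odds_ratio": fisher.effect, "fisher_p": fisher.p_value,
            }
        ]
    ).to_csv(ROOT / "icb_response.tsv", sep="\t", index=False, float_format="%.6g")
    print(
        f"response benefit: female {100 * benefit_f / n_f:.0f}% vs male "
        f"{100 * benefit_m / n_m:.0f}%, Fisher p={fisher.p_value:.3f} "
        "- a trend short of significance at these sample sizes"
    )


if __name__ == "__main__":
    main()
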