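#!/usr/bin/env python
"""Simulate the study-shaped questionnaire cohort and check its calibration.

Generates 95 subjects (45 non-SCD / 50 SCD) with the planted measurement
and structural model, assigns groups by the 12-item memory-complaint
cutoff (>= 20) and reports how the calibrated CCI-S memory scores and the
descriptive group comparisons come out.  Writes the indicator table and
construct map consumed by the later scripts.
"""

from pathlib import Path

import pandas as pd

from scdnet.pipeline import assign_scd_group, compare_groups
from scdnet.synthetic_data import generate_questionnaire_cohort, study_cohort_spec

SEED = 1
OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = generate_questionnaire_cohort(study_cohort_spec(seed=SEED))
    table = cohort.indicators.copy()
    table["group"] = [assign_scd_group(s) for s in table["CCIS_memory"]]

    table.to_csv(OUT / "indicators.csv", index=False)
    cohort.construct_map.to_csv(OUT / "construct_map.csv", index=False)
    cohort.latents.to_csv(OUT / "latents_ground_truth.csv", index=False)

    stats = table.groupby("group")["CCIS_memory"].agg(["size", "mean", "std"])
    print("CCI-S memory by cutoff-assigned group (targets 16.31/32.34):")
    print(stats.round(2).to_string())

    rows = []
    for col in cohort.spec.indicator_map:
        res = compare_groups(table[col].rename(col), table["group"])
        rows.append(
            {"variable": col, "test": res.test,
             "statistic": round(res.statistic, 3), "p": round(res.p_value, 5)}
        )
    comp = pd.DataFrame(rows)
    comp.to_csv(OUT / "group_comparisons.csv", index=False)
    sig = comp[comp.p < 0.05]
    print(f"\n{len(sig)}/{len(comp)} indicators differ between groups at p<0.05 "
          "(memory-complaint indicators separate; exogenous batteries mostly do not).")


if __name__ == "__main__":
    main()
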