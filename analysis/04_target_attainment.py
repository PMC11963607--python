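#!/usr/bin/env python
"""PK/PD target attainment per dosing category and overall, for both regimens.

MAP-assesses every simulated subject's first-interval Cmax, Cmin and
AUC0-tau, evaluates all targets (Cmax >= 15/24/35 mg/L, Cmin <= 3/5 mg/L,
AUC/MIC >= 21.4 and >= 62.5 at MIC 2/4/8 mg/L), tabulates attainment per
dosing category with the >= 90% adequacy rule, and draws the stacked bar
chart.  Requires 01_simulate_cohorts.py to have run.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from neopta import (SITE_A, SITE_B, TargetSet, assess_subject, default_parameters,
                    map_estimate, read_dataset, summarize_cohort)
from neopta.cohorts import assign_for_site

OUT = Path("results")


def main() -> None:
    pop = default_parameters()
    tables = []
    for profile, regimen in ((SITE_A, "simplified"), (SITE_B, "complex")):
        dataset = read_dataset(OUT / f"cohort_site_{profile.name}.csv")
        assessments, categories = [], []
        for s in dataset:
            if s.assignment is None:
                s.assignment = assign_for_site(profile, s.covariates)
            res = map_estimate(s, pop)
            assessments.append(assess_subject(s, pop, res))
            categories.append(str(s.assignment.category_id))
        summary = summarize_cohort(assessments, categories, TargetSet(), regimen=regimen)
        tables.append(summary.table)
        overall = summary.table[summary.table["category"] == "all"]
        print(f"\n{regimen} regimen (n={len(dataset)}), overall attainment:")
        for _, row in overall.iterrows():
            flag = "adequate" if row["adequate"] else "below 90%"
            print(f"  {row['target']:22s} {row['percent']:5.1f}%  ({flag})")
    combined = pd.concat(tables, ignore_index=True)
    combined.to_csv(OUT / "target_attainment.csv", index=False)

    # stacked-bar figure: attainment per category for the clinical targets
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
    for ax, regimen in zip(axes, ("simplified", "complex")):
        sub = combined[(combined["regimen"] == regimen) & (combined["category"] != "all")]
        cats = sorted(sub["category"].unique(), key=lambda c: (len(c), c))
        targets = ("cmax_ge_15", "cmax_ge_24", "cmin_le_3", "cmin_le_5")
        width = 0.2
        for i, t in enumerate(targets):
            vals = [sub[(sub["category"] == c) & (sub["target"] == t)]["percent"].iloc[0] for c in cats]
            ax.bar([x + i * width for x in range(len(cats))], vals, width=width, label=t)
        ax.axhline(90, color="k", ls="--", lw=1)
        ax.set_xticks([x + 1.5 * width for x in range(len(cats))])
        ax.set_xticklabels(cats, rotation=45, ha="right")
        ax.set_title(f"{regimen} regimen")
        ax.set_ylabel("% attaining target")
    axes[1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "target_attainment.png", dpi=120)
    print(f"\ntable -> {OUT / 'target_attainment.csv'}; figure -> {OUT / 'target_attainment.png'}")


if __name__ == "__main__":
    main()
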