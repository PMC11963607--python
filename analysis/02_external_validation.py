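#!/usr/bin/env python
"""External-validation battery on the site A (simplified regimen) dataset.

Runs MAP estimation on the simulated site A TDM data, then computes
bias/imprecision (MPE and RMSE with CIs, stratified by peak/trough),
NPDE with mean/variance tests, VPC bin summaries, and the eta-versus-
covariate rank correlations.  Writes tables and diagnostic plots under
results/validation/.  Requires 01_simulate_cohorts.py to have run.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from neopta import default_parameters, map_estimate, npde, read_dataset, vpc
from neopta.attainment import classify_sample
from neopta.validation import bias_imprecision, iiv_covariate_diagnostics

SEED = 20250926
OUT = Path("results/validation")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pop = default_parameters()
    dataset = read_dataset("results/cohort_site_A.csv")
    print(f"{len(dataset)} subjects, {dataset.n_observations} samples")

    map_results = [map_estimate(s, pop) for s in dataset]

    # goodness-of-fit table: obs vs population and individual predictions
    rows = []
    for s, r in zip(dataset, map_results):
        usable = [o for o in s.observations if not o.blq]
        for o, ipred, pred in zip(usable, r.ipred, r.pred):
            tad = o.time_h - max(d.start_time_h for d in s.doses if d.start_time_h <= o.time_h)
            rows.append({"ID": s.subject_id, "time": o.time_h, "class": classify_sample(tad),
                         "obs": o.value_mg_L, "ipred": float(ipred), "pred": float(pred)})
    gof = pd.DataFrame(rows)
    gof.to_csv(OUT / "gof.csv", index=False)

    bias_rows = []
    for klass in ("all", "peak", "trough"):
        sel = gof if klass == "all" else gof[gof["class"] == klass]
        for pred_type in ("ipred", "pred"):
            bi = bias_imprecision(sel[pred_type], sel["obs"], seed=SEED)
            bias_rows.append({"class": klass, "prediction": pred_type, "n": bi.n,
                              "mpe": bi.mpe, "mpe_lo": bi.mpe_ci[0], "mpe_hi": bi.mpe_ci[1],
                              "rmse": bi.rmse, "rmse_lo": bi.rmse_ci[0], "rmse_hi": bi.rmse_ci[1]})
            print(f"{klass:7s} {pred_type}: MPE {bi.mpe:+.2f} "
                  f"({bi.mpe_ci[0]:+.2f} to {bi.mpe_ci[1]:+.2f}) mg/L, "
                  f"RMSE {bi.rmse:.2f} ({bi.rmse_ci[0]:.2f}-{bi.rmse_ci[1]:.2f}) mg/L")
    pd.DataFrame(bias_rows).to_csv(OUT / "bias_imprecision.csv", index=False)

    res = npde(dataset, pop, K=1000, seed=SEED + 1)
    print(f"NPDE: mean {res.mean:+.3f} (t-test p={res.t_pvalue:.3f}), "
          f"variance {res.variance:.3f} (p={res.var_pvalue:.3f})")
    pd.DataFrame({"npde": res.values}).to_csv(OUT / "npde.csv", index=False)

    vpc_table = vpc(dataset, pop, n_sim=300, seed=SEED + 2)
    vpc_table.to_csv(OUT / "vpc.csv", index=False)

    eta_df, rho = iiv_covariate_diagnostics(map_results, [s.covariates for s in dataset])
    eta_df.to_csv(OUT / "eta_covariates.csv", index=False)
    for cov_name, entry in rho.items():
        print(f"Spearman rho(eta_CL, {cov_name}) = {entry['rho']:+.3f} (p={entry['pvalue']:.3f})")

    # diagnostic plots
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, col, label in zip(axes, ("pred", "ipred"), ("population", "individual")):
        ax.scatter(gof[col], gof["obs"], s=8, alpha=0.4)
        lim = max(gof["obs"].max(), gof[col].max()) * 1.05
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel(f"{label} prediction (mg/L)")
        ax.set_ylabel("observed (mg/L)")
    fig.tight_layout()
    fig.savefig(OUT / "gof.png", dpi=120)

    fig, ax = plt.subplots(figsize=(6, 4))
    for p, style in (("p5", ":"), ("p50", "-"), ("p95", ":")):
        ax.plot(vpc_table["tald_mid"], vpc_table[f"obs_{p}"], "o" + style, color="C0", ms=4)
        ax.fill_between(vpc_table["tald_mid"], vpc_table[f"sim_{p}_lo"], vpc_table[f"sim_{p}_hi"],
                        color="C1", alpha=0.25)
    ax.set_xlabel("time after last dose (h)")
    ax.set_ylabel("concentration (mg/L)")
    ax.set_title("visual predictive check")
    fig.tight_layout()
    fig.savefig(OUT / "vpc.png", dpi=120)
    print(f"tables and plots -> {OUT}/")


if __name__ == "__main__":
    main()
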