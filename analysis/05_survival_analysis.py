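"""Survival analysis of the simulated cohort from step 04: append the
MTV / chromogranin-A composite, fit univariable and multivariable Cox
models with Schoenfeld diagnostics, estimate the overall Kaplan-Meier
curve, run the 5-year fixed-horizon ROC for MTV and CgA with Youden
cutoffs, and compare markers between deceased and surviving patients.

At n=62 the estimates are noisy by design (that is the study scale); a
companion fit on n=2000 shows the per-SD composite hazard ratio
converging to its generating value of e^0.98 ~ 2.66.

Writes results/survival_report.json and results/cox_multivariable.csv.
"""

import json
from pathlib import Path

import pandas as pd

from netmtv import RunConfig, fit_cox, generate_cohort, paper_like_cohort_config, run_pipeline
from netmtv.pipeline import add_composite

SEED = 7
res = Path("results")

cfg = RunConfig(cohort_csv=res / "cohort.csv", roc_horizon_months=60.0, seed=SEED)
report = run_pipeline(cfg)
(res / "survival_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

surv = report["survival"]
multi = surv["multivariable_cox"]
rows = []
print(f"multivariable Cox (n={multi['n']}, events={multi['n_events']}):")
for cov, row in multi["covariates"].items():
    print(f"  {cov:18s} HR {row['hazard_ratio']:6.2f} "
          f"({row['ci95_low']:.2f}-{row['ci95_high']:.2f})  p={row['p_value']:.3g}  "
          f"PH p={row['p_schoenfeld']:.2f}")
    rows.append({"covariate": cov, **row})
pd.DataFrame(rows).to_csv(res / "cox_multivariable.csv", index=False)

print(f"KM 5-year OS: {surv['km_overall']['survival_at_horizon']:.1%}")
for marker in ("mtv_ml", "cga"):
    roc = surv[f"roc_{marker}"]
    print(f"ROC {marker}: AUC {roc['auc']:.2f} "
          f"({roc['auc_ci95'][0]:.2f}-{roc['auc_ci95'][1]:.2f}), "
          f"cutoff {roc['cutoff']:.1f}, sens {roc['sensitivity']:.0%}, "
          f"spec {roc['specificity']:.0%} [{roc['n_cases']} cases/{roc['n_controls']} controls]")
    lr = surv.get(f"logrank_{marker}_cutoff")
    if lr:
        print(f"  log-rank at cutoff: chi2 {lr['chi2']:.2f}, p={lr['p_value']:.3g}")

# convergence check at large n: the per-SD composite HR approaches e^0.98
big, _ = generate_cohort(paper_like_cohort_config(seed=SEED + 1, n=2000))
big = add_composite(big)
comp = big["mtv_cga_composite"]
big["composite_std"] = comp / comp.std(ddof=1)
fit = fit_cox(big, ["composite_std"])
row = fit.summary.loc["composite_std"]
print(f"large-n (2000) composite HR per SD: {row['hazard_ratio']:.2f} "
      f"({row['ci95_low']:.2f}-{row['ci95_high']:.2f}); generating value 2.66")
print(f"wrote {res}/survival_report.json and {res}/cox_multivariable.csv")
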