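#!/usr/bin/env python
"""Crude survival description of the synthetic cohort.

Fits the overall Kaplan-Meier curve (exported as a table and a step plot),
then screens each stratification variable with the k-sample log-rank test
and reports per-stratum restricted-mean survival — the screening step that
decides which prognostic factors enter the multivariable quantile model.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import cqrsurv as cs

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cohort = cs.read_cohort(OUT / "synthetic_cohort.csv")
frame = cohort.frame
curve = cs.km_fit(frame.time.to_numpy(), frame.event.to_numpy())
curve.to_frame().to_csv(OUT / "km_overall.csv", index=False)

fig, ax = plt.subplots(figsize=(6, 4))
ax.step([0, *curve.times], [1, *curve.surv], where="post")
ax.set_xlabel("months since surgery")
ax.set_ylabel("overall survival")
ax.set_ylim(0, 1.02)
fig.tight_layout()
fig.savefig(OUT / "km_overall.png", dpi=120)

horizon = frame.time.max()
rows = []
print(f"median survival: {cs.median_survival(curve):.1f} months "
      f"(NaN = not reached)")
for var in ("age", "tumor_size", "n_nodes", "marital", "surgery", "stage",
            "metastasis"):
    strata = {k: c for k, c in cs.stratify(cohort, var).items() if c is not None}
    groups = [(c.frame.time.to_numpy(), c.frame.event.to_numpy())
              for c in strata.values()]
    lr = cs.logrank_test(groups)
    print(f"{var}: log-rank chi2={lr.statistic:.2f} (df={lr.df}), "
          f"p={lr.p_value:.4f}")
    for label, sub in strata.items():
        sub_curve = cs.km_fit(sub.frame.time.to_numpy(), sub.frame.event.to_numpy())
        rmst, se = cs.restricted_mean(sub_curve, min(horizon, sub_curve.max_followup))
        rows.append({"variable": var, "stratum": label, "n": len(sub),
                     "deaths": int(sub.frame.event.sum()),
                     "rmst_months": round(rmst, 1), "rmst_se": round(se, 2),
                     "logrank_p": round(lr.p_value, 4)})
tab = pd.DataFrame(rows)
tab.to_csv(OUT / "survival_by_stratum.csv", index=False)
print(f"\nwrote {OUT / 'survival_by_stratum.csv'} and km_overall.{{csv,png}}")
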