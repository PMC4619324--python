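"""Test whether a marker's survival effect is treatment-specific.

Simulates a two-arm cohort in which marker-positive patients have hazard
ratio 3.5 under carboplatin but 1.0 under cisplatin, fits per-arm Cox
models, and runs the marker x treatment likelihood-ratio interaction test.
"""

import pandas as pd

from dnamesig import SimulationConfig, cox_fit, interaction_lrt, km_estimate, simulate_cohort

cfg = SimulationConfig(
    n_pos=150, n_neg=150, n_probes=1, n_informative=0, delta=0.0, seed=5,
    treatment_probs={"carboplatin": 0.5, "cisplatin": 0.5, "none": 0.0},
    hr_marker_by_treatment={"carboplatin": 3.5, "cisplatin": 1.0, "none": 1.0},
)
cohort, _ = simulate_cohort(cfg)
clin = cohort.clinical_frame()
marker = (clin["marker_status"] == "positive").astype(int)

for arm in ("carboplatin", "cisplatin"):
    sub = clin[clin["treatment"] == arm]
    fit = cox_fit(sub["time"], sub["event"],
                  pd.DataFrame({"marker": marker[sub.index]}))
    row = fit.table.loc["marker"]
    print(f"{arm:12s} HR {row['hazard_ratio']:.2f} "
          f"(95% CI {row['ci_lower']:.2f}-{row['ci_upper']:.2f}), "
          f"LRT p {fit.lrt_p:.4f}, {fit.n_events}/{fit.n} events")

res = interaction_lrt(clin["time"], clin["event"], marker, clin["treatment"])
print(f"interaction LRT: chi2 {res.lrt_statistic:.2f} on {res.df} df, p {res.p:.2e}")
# a small p says the marker's hazard ratio genuinely differs between arms —
# the pattern expected if the marker tags carboplatin-resistant tumours

km = km_estimate(clin.loc[marker == 1, "time"], clin.loc[marker == 1, "event"])
print(f"marker-positive 3-year survival: {km.survival_at(3.0):.0%}")
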