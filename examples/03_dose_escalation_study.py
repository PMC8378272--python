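"""A complete dose-escalation cardiotoxicity study on synthetic tissues.

Simulates seven tissues through an HCQ-like acute escalation (doses 0 to
1000 µM around a 1 µM Cmax), analyzes every recording, and prints the
study outputs: inclusion, per-dose normalized APD80 with Dunnett-adjusted
p-values against dose 0, and the arrhythmia incidence table.
"""

import pandas as pd

from cardiomps import AnalysisConfig, run_study
from cardiomps.design import DoseEscalationDesign, DrugArm
from cardiomps.synth import SimConfig, hcq_like_model, simulate_cohort

pd.set_option("display.width", 160)

design = DoseEscalationDesign(
    drugs=(DrugArm.single("HCQ", 1.0, (0, 0.1, 1, 10, 100, 1000)),),
    n_tissues=7,
)
sim = simulate_cohort(design, {"HCQ": hcq_like_model()}, SimConfig(seed=11))
report = run_study(design, sim.traces, config=AnalysisConfig(seed=11))

n_in = int(report.inclusion["included"].sum())
print(f"inclusion (baseline APD80 < 500 ms): {n_in}/{len(report.inclusion)} tissues\n")

summary = (
    report.metrics.groupby("dose_uM")["apd80_corrected_ms_norm"]
    .agg(["count", "mean"])
    .rename(columns={"count": "n", "mean": "mean cAPD80 / baseline"})
)
print(summary.round(3).to_string(), "\n")

apd_stats = report.anova[report.anova["metric"] == "apd80_corrected_ms_norm"]
print("Dunnett vs dose 0 (normalized cAPD80):")
print(apd_stats[["dose_uM", "n", "mean", "p_adjusted", "stars"]].round(4).to_string(index=False))

print("\narrhythmia incidence (% of MPS):")
cols = ["dose", "n", "arrhythmic_pct", "weak_or_silent_pct", "normal_pct"]
print(report.incidence[cols].round(1).to_string(index=False))

print(
    "\nReading: cAPD80 rises with dose (QT-prolongation signature), EAD-driven\n"
    "arrhythmic calls appear at intermediate doses, and the top dose silences\n"
    "most tissues (weak_or_silent), which excludes it from APD statistics."
)
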