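# cardiomps

Optical electrophysiology analysis for cardiac microphysiological systems
(MPS, "heart-on-a-chip"): a Python library for turning fluorescence
recordings of beating hiPSC-CM micro-tissues — voltage dye or genetically
encoded calcium indicator, nominally 100 frames/s — into the quantities
used in in vitro safety pharmacology:

- **per-beat metrics**: APD30/50/80/90 (action-potential / calcium-transient
  duration at a repolarization fraction), beat rate, maximum upstroke
  velocity (max dF/dt), and **triangulation** `(APD80 − APD30)/APD80`;
- **QT-interval proxy**: APD80 with **Fridericia rate correction**
  `cAPD = APD / RR^(1/3)` (RR in seconds; pacing period when the tissue
  captures the stimulus);
- **arrhythmia analysis**: early/delayed afterdepolarization (EAD/DAD)
  detection, TdP-like waveform irregularity, and Poincaré beat-to-beat
  instability (RMS distance of successive mean-normalized APD80 pairs from
  the identity line; `ε·√2` for perfect alternans `a(1±ε)`);
- **tissue calls**: each tissue × dose is classified
  `normal | arrhythmic | weak_or_silent`, with weakness (amplitude < 60% of
  the tissue's drug-free control, or no beating) taking precedence;
- **dose-escalation studies**: inclusion screening (baseline APD80 < 500 ms),
  per-tissue baseline normalization, one-way ANOVA with exact **Dunnett**
  many-to-one comparisons against dose 0, pairwise chi-squared tests on
  arrhythmia incidence;
- **effluent biomarker filtering**: limit of detection = mean + 3 SD of
  negative controls, markers retained when detected in > 65% of samples;
- a **synthetic-trace generator** with analytic ground truth (beat
  templates whose APD30/APD80 equal their targets exactly, injected
  EADs/DADs/alternans, photobleaching, pacing vs spontaneous rhythm, and
  Hill-type drug-effect models) for calibrating and testing every step.

The intended users are groups running MPS/organoid cardiotoxicity screens
who need a transparent, scriptable alternative to in-house one-off trace
analysis.

## Worked example

```python
from cardiomps import AnalysisConfig, run_study
from cardiomps.design import DoseEscalationDesign, DrugArm
from cardiomps.synth import SimConfig, hcq_like_model, simulate_cohort

design = DoseEscalationDesign(
    drugs=(DrugArm.single("HCQ", 1.0, (0, 0.1, 1, 10, 100, 1000)),),  # ×Cmax
    n_tissues=7,
)
sim = simulate_cohort(design, {"HCQ": hcq_like_model()}, SimConfig(seed=11))
report = run_study(design, sim.traces, config=AnalysisConfig(seed=11))
print(report.incidence[["dose", "arrhythmic_pct", "weak_or_silent_pct", "normal_pct"]])
```

which prints (seed 11):

```
  dose  arrhythmic_pct  weak_or_silent_pct  normal_pct
   0.0             0.0                 0.0       100.0
   0.1             0.0                 0.0       100.0
   1.0             0.0                 0.0       100.0
  10.0            71.4                 0.0        28.6
 100.0           100.0                 0.0         0.0
1000.0             0.0               100.0         0.0
```

Reading: the simulated compound prolongs APD with an EC50 at its 1 µM
Cmax (the accompanying Dunnett table shows normalized cAPD80 rising to
~1.4× with adjusted p ≪ 0.001), EAD-driven arrhythmic calls appear at
10–100 µM, and the top dose silences beating entirely — so it is reported
as weak/silent and excluded from APD statistics rather than imputed.

The `examples/` directory holds one short script per capability
(single-trace metrics, arrhythmia detection and Poincaré instability, the
full dose-escalation study, biomarker LOD filtering); each prints its
numbers with a line on what they mean. A thin CLI mirrors the stages:
`cardiomps simulate | analyze | stats | biomarkers | report`.

## Layout

```
src/cardiomps/
  traces.py      trace + metadata types, CSV dialect, TIFF reduction
  beats.py       detrending, segmentation, APD/upstroke/Fridericia/triangulation
  arrhythmia.py  EAD/DAD detection, Poincaré instability, tissue classification
  design.py      dose-escalation designs (ladders in µM or ×Cmax)
  study.py       orchestration: inclusion, routing, normalization, statistics
  stats.py       exact Dunnett (multivariate-t quadrature), chi-squared pairs
  biomarkers.py  marker×sample panels and the LOD retention filter
  synth.py       synthetic traces, cohorts and panels with ground truth
  evaluation.py  benchmark harnesses used by tests and scripts/acceptance.py
  cli.py         thin command-line front end
docs/methods.md  model, assumptions, tunables, numerical choices, limits
```

See `docs/methods.md` for the full description of the signal model, every
threshold and its default, and what the synthetic benchmarks do and do not
demonstrate about real recordings.
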