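"""Afterdepolarization detection and Poincaré instability.

Injects two EADs (phase-3 reversals) and one DAD (diastolic hump) into a
synthetic calcium recording, detects them, and contrasts the Poincaré
instability index of a stable recording with one showing APD alternans —
the beat-to-beat pattern that precedes torsades-like arrhythmia.
"""

import numpy as np

from cardiomps import (
    classify_tissue,
    detect_dads,
    detect_eads,
    detrend,
    instability_index,
    normalize,
    poincare_pairs,
    segment_beats,
)
from cardiomps.synth import BeatTemplateParams, SimConfig, simulate_trace

config = SimConfig(seed=7, noise_sd=0.02, spontaneous_rate_hz=0.75)
events = [
    dict(kind="EAD", beat_index=4, amplitude_fraction=0.15),
    dict(kind="EAD", beat_index=12, amplitude_fraction=0.22),
    dict(kind="DAD", beat_index=8, amplitude_fraction=0.25),
]
trace, truth = simulate_trace(
    BeatTemplateParams(), config, "spontaneous", events, length_s=30.0
)
nz = normalize(detrend(trace, "exponential"))
series = segment_beats(nz)

eads = detect_eads(nz, series)
dads = detect_dads(nz, series)
print(f"injected: 2 EADs + 1 DAD   detected: {len(eads)} EADs + {len(dads)} DADs")
for e in eads + dads:
    print(f"  {e.kind.value} at {e.time_s:6.2f} s, {100 * e.relative_amplitude:.0f}% of beat amplitude")

call = classify_tissue(nz, series, control_amplitude=1.0)
print(f"tissue call: {call.category.value} (any afterdepolarization marks the recording arrhythmic)")

# instability: stable rhythm vs alternans
stable, _ = simulate_trace(BeatTemplateParams(), config, "spontaneous", [], 30.0)
alternans, _ = simulate_trace(
    BeatTemplateParams(), config, "spontaneous", [], 30.0, alternans_eps=0.1
)
for name, tr in (("stable", stable), ("alternans eps=0.1", alternans)):
    s = segment_beats(normalize(detrend(tr, "exponential")))
    idx, unstable = instability_index(poincare_pairs(s.apd80_sequence()))
    print(f"instability index ({name}): {idx:.3f} -> {'UNSTABLE' if unstable else 'stable'}")
print("\nAlternans of +/-10% puts successive APD80 pairs off the Poincaré")
print("identity line; the index approaches 0.1 * sqrt(2) = 0.141, well above")
print("the 0.05 instability threshold, while a stable rhythm stays near its")
print("noise floor (~0.01-0.02).")
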