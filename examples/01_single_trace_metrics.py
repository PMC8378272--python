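"""Per-beat metrics from one optical recording.

Simulates a 30-s spontaneous calcium recording (100 frames/s) with known
beat parameters, runs the detrend -> normalize -> segment pipeline, and
prints the per-beat table: APD30/50/80/90, amplitude, and maximum upstroke
velocity.  APD80 is the QT-interval proxy; the Fridericia-corrected value
divides it by the cube root of the RR interval.
"""

import numpy as np

from cardiomps import beat_table, detrend, fridericia_correct, normalize, segment_beats
from cardiomps.synth import BeatTemplateParams, SimConfig, simulate_trace

params = BeatTemplateParams(channel="calcium", apd30_ms=230.0, apd80_ms=350.0)
config = SimConfig(seed=42, noise_sd=0.02, spontaneous_rate_hz=0.75)
trace, truth = simulate_trace(params, config, rhythm="spontaneous", length_s=30.0)

series = segment_beats(normalize(detrend(trace, method="exponential")))
table = beat_table(series)

print(table.round(2).to_string(index=False))
apd80 = table["apd80_ms"].median()
rr = float(np.mean(series.rr_intervals_s))
print(f"\nbeats detected: {len(series)} (generated: {len(truth.beats)})")
print(f"median APD80:   {apd80:.1f} ms (target 350 ms)")
print(f"mean RR:        {rr:.3f} s  ->  Fridericia cAPD80 = {fridericia_correct(apd80, rr):.1f} ms")
print("\nThe corrected APD80 removes the rate dependence so that slow- and")
print("fast-beating tissues are comparable, exactly as QTc does clinically.")
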