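"""Synthetic optical AP / calcium-transient generator with known ground truth.

No raw recordings accompany the screening protocol this package implements,
so every analysis step is exercised against a parameterized generator whose
waveforms have *analytic* beat metrics:

* the upstroke is a scaled logistic over ``upstroke_ms`` (voltage-dye beats
  rise in ~20 ms, calcium-indicator beats in ~80 ms), with the maximum slope
  — the activation reference — at its midpoint;
* repolarization is piecewise linear through the control points
  ``(APD30, 0.7 A)`` and ``(APD80, 0.2 A)`` and reaches zero at
  ``APD80 + 0.5 (APD80 - APD30)``, so the template's APD30/APD80 (measured
  from activation, per the analysis definition) equal their targets exactly
  before noise, and APD90 stays defined.

Traces add, in order: injected afterdepolarizations (an EAD reverses
repolarization by a known fraction of the beat amplitude; a DAD is a smooth
diastolic hump), APD/amplitude alternans, a multiplicative exponential
photobleaching drift, a baseline fluorescence offset, and additive Gaussian
noise.  Every beat time, per-beat APD, and injected event is returned as
ground truth.

Dose-escalation cohorts draw per-tissue baselines (APD80 truncated-normal
350 +/- 60 ms on [200, 600] so a realistic minority violates the 500-ms
inclusion screen) and apply a phenomenological drug-effect model: Hill
dose-response curves for APD multiplication, triangulation shift, amplitude
suppression, alternans, and the probabilities of EADs, DADs and beating
cessation.  All randomness derives from one seed through per-recording
substreams, so identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .biomarkers import BiomarkerPanel
from .design import DoseEscalationDesign, DrugArm
from .traces import Channel, FluorescenceTrace, RecordingMeta, Rhythm, TraceSet, write_trace_csv
from .design import save_design

__all__ = [
    "BeatTemplateParams",
    "BeatTemplate",
    "SimConfig",
    "DrugEffectModel",
    "EventSpec",
    "TraceGroundTruth",
    "CohortSim",
    "make_beat_template",
    "simulate_trace",
    "simulate_cohort",
    "simulate_biomarker_panel",
    "hcq_like_model",
    "azm_like_model",
    "polytherapy_like_model",
    "default_effect_models",
]

_DEFAULT_UPSTROKE_MS = {Channel.VOLTAGE: 20.0, Channel.CALCIUM: 80.0}


@dataclass(frozen=True)
class BeatTemplateParams:
    """Target metrics of a single noise-free beat."""

    channel: Channel = Channel.CALCIUM
    apd30_ms: float = 230.0
    apd80_ms: float = 350.0
    amplitude: float = 1.0
    upstroke_ms: Optional[float] = None  # default by channel

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", Channel(self.channel))
        if self.upstroke_ms is None:
            object.__setattr__(
                self, "upstroke_ms", _DEFAULT_UPSTROKE_MS[self.channel]
            )
        if not 0 < self.apd30_ms < self.apd80_ms:
            raise ValueError("need 0 < apd30_ms < apd80_ms")
        if not self.upstroke_ms < self.apd30_ms:
            raise ValueError("upstroke must complete before the APD30 point")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")

    @property
    def plateau(self) -> bool:
        """Plateau-shaped beats keep APD30/APD80 near 1 (low triangulation)."""
        return self.apd30_ms / self.apd80_ms >= 0.75

    @property
    def triangulation(self) -> float:
        return (self.apd80_ms - self.apd30_ms) / self.apd80_ms


class BeatTemplate:
    """Analytic beat waveform; ``value(tau_ms)`` with tau = t - activation."""

    def __init__(self, params: BeatTemplateParams):
        self.params = params
        p = params
        self.u = p.upstroke_ms
        self.A = p.amplitude
        self.apd30 = p.apd30_ms
        self.apd80 = p.apd80_ms
        self.t_end = p.apd80_ms + 0.5 * (p.apd80_ms - p.apd30_ms)
        # logistic with 5-95% rise spanning upstroke_ms, max slope at tau=0
        self.k = 2.0 * math.log(19.0) / self.u
        s_hi = 1.0 / (1.0 + math.exp(-self.k * self.u / 2.0))
        self._s_lo = 1.0 - s_hi
        self._s_span = s_hi - self._s_lo

    def value(self, tau_ms: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau_ms, dtype=float)
        out = np.zeros_like(tau)
        A, u = self.A, self.u
        half = u / 2.0
        rise = (tau >= -half) & (tau <= half)
        sig = 1.0 / (1.0 + np.exp(-self.k * tau[rise]))
        out[rise] = A * (sig - self._s_lo) / self._s_span
        seg1 = (tau > half) & (tau <= self.apd30)
        out[seg1] = A - 0.3 * A * (tau[seg1] - half) / (self.apd30 - half)
        seg2 = (tau > self.apd30) & (tau <= self.apd80)
        out[seg2] = 0.7 * A - 0.5 * A * (tau[seg2] - self.apd30) / (
            self.apd80 - self.apd30
        )
        seg3 = (tau > self.apd80) & (tau <= self.t_end)
        out[seg3] = 0.2 * A * (1.0 - (tau[seg3] - self.apd80) / (self.t_end - self.apd80))
        return out

    def apd(self, fraction: float) -> float:
        """Analytic APD at repolarization fraction ``fraction``, in ms."""
        if not 0 < fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        half = self.u / 2.0
        if fraction <= 0.3:
            return half + (self.apd30 - half) * fraction / 0.3
        if fraction <= 0.8:
            return self.apd30 + (self.apd80 - self.apd30) * (fraction - 0.3) / 0.5
        return self.apd80 + (self.t_end - self.apd80) * (fraction - 0.8) / 0.2

    @property
    def max_upstroke_per_s(self) -> float:
        """Analytic maximum upstroke slope, amplitude units per second."""
        return 1000.0 * self.A * self.k / 4.0 / self._s_span

    @property
    def peak_tau_ms(self) -> float:
        return self.u / 2.0

    def sample(self, fps: float) -> np.ndarray:
        """The waveform sampled at ``fps`` from -upstroke/2 to the terminal zero."""
        taus = np.arange(-self.u / 2.0, self.t_end + 1000.0 / fps, 1000.0 / fps)
        return self.value(taus)


def make_beat_template(params: BeatTemplateParams, fps: float = 100.0) -> BeatTemplate:
    """Build the analytic beat template (errors if APD30 >= APD80)."""
    return BeatTemplate(params)


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and nuisance parameters of a simulated recording."""

    seed: int = 0
    fps: float = 100.0
    noise_sd: float = 0.02           # additive Gaussian, units of beat amplitude
    bleach_per_s: float = 0.005      # multiplicative exponential drift rate
    spontaneous_rate_hz: float = 0.75
    pacing_frequency_hz: float = 1.0
    recording_lengths_s: Tuple[float, float] = (6.0, 30.0)
    rr_jitter: float = 0.02          # relative SD of spontaneous RR intervals
    baseline_fluorescence: float = 100.0  # offset in camera units
    beat_scale: float = 50.0         # camera units per unit of amplitude
    start_s: float = 0.3             # first activation time

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class EventSpec:
    """One afterdepolarization to inject.

    ``timing`` places the event within its window: for EADs the fraction of
    the APD30->APD80 span at which the reversal starts; for DADs the
    fraction of the diastolic interval at which the hump is centered.
    """

    kind: str  # "EAD" | "DAD"
    beat_index: int
    amplitude_fraction: float
    timing: float = 0.4

    def __post_init__(self) -> None:
        if self.kind not in ("EAD", "DAD"):
            raise ValueError("kind must be 'EAD' or 'DAD'")
        if not 0 < self.amplitude_fraction < 1:
            raise ValueError("amplitude_fraction must be in (0, 1)")
        if not 0 <= self.timing <= 1:
            raise ValueError("timing must be in [0, 1]")


@dataclass
class TraceGroundTruth:
    beats: List[dict]          # activation/peak times, analytic APDs, amplitude
    events: List[dict]         # kind, time_s, relative_amplitude, beat_index
    silent: bool
    alternans_eps: float
    params: BeatTemplateParams


_EAD_RISE_MS = 30.0
_EAD_PLATEAU_MS = 20.0
_EAD_FALL_MS = 40.0
_DAD_WIDTH_MS = 100.0


def _ead_bump(
    tpl: BeatTemplate, h: float, timing: float, taus: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Additive deflection reversing repolarization by ``h * A``.

    Starts at APD30 + timing * (APD80 - APD30); the trace rises from the
    local repolarization level by exactly ``h * A`` over a half-cosine,
    holds a short plateau (so the peak survives frame-rate smoothing), and
    rejoins the template, making the ground-truth rise equal ``h`` by
    construction.  Returns (bump values on ``taus``, peak-center tau in ms).
    """
    total = _EAD_RISE_MS + _EAD_PLATEAU_MS + _EAD_FALL_MS
    t0 = tpl.apd30 + timing * (tpl.apd80 - tpl.apd30)
    if t0 + total >= tpl.apd(0.9):
        # keep the event inside the phase-3 (pre-APD90) window
        t0 = tpl.apd(0.9) - total - 5.0
        if t0 <= tpl.peak_tau_ms:
            raise ValueError("beat too short to host an EAD")
    t_top = t0 + _EAD_RISE_MS
    t_fall = t_top + _EAD_PLATEAU_MS
    t_rejoin = t_fall + _EAD_FALL_MS
    base = tpl.value(taus)
    bump = np.zeros_like(taus)
    v0 = float(tpl.value(np.array([t0]))[0])
    v_rejoin = float(tpl.value(np.array([t_rejoin]))[0])
    peak_v = v0 + h * tpl.A
    rise = (taus >= t0) & (taus <= t_top)
    frac = (taus[rise] - t0) / _EAD_RISE_MS
    bump[rise] = v0 + h * tpl.A * 0.5 * (1 - np.cos(np.pi * frac)) - base[rise]
    top = (taus > t_top) & (taus <= t_fall)
    bump[top] = peak_v - base[top]
    fall = (taus > t_fall) & (taus <= t_rejoin)
    frac = (taus[fall] - t_fall) / _EAD_FALL_MS
    bump[fall] = (
        v_rejoin + (peak_v - v_rejoin) * 0.5 * (1 + np.cos(np.pi * frac)) - base[fall]
    )
    return bump, t_top + _EAD_PLATEAU_MS / 2.0


def simulate_trace(
    params: BeatTemplateParams,
    config: SimConfig,
    rhythm: Rhythm | str = Rhythm.SPONTANEOUS,
    events: Sequence[EventSpec | dict] = (),
    length_s: float = 30.0,
    alternans_eps: float = 0.0,
    amplitude_factor: float = 1.0,
    silent: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[FluorescenceTrace, TraceGroundTruth]:
    """Simulate one recording and return it with its ground truth.

    The beat train runs at the pacing frequency (paced) or at the
    spontaneous rate with relative RR jitter ``config.rr_jitter``
    (spontaneous).  Raises if the template does not fit inside the beat
    period ("beats overlap").  ``silent`` produces a noise-plus-drift-only
    trace with zero beats.
    """
    rhythm = Rhythm(rhythm)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    events = [EventSpec(**e) if isinstance(e, dict) else e for e in events]
    if not 0 <= alternans_eps < 0.5:
        raise ValueError("alternans_eps must be in [0, 0.5)")

    fps = config.fps
    n = int(round(length_s * fps))
    t = np.arange(n) / fps
    signal = np.zeros(n)
    gt_beats: List[dict] = []
    gt_events: List[dict] = []

    if not silent:
        rate = (
            config.pacing_frequency_hz
            if rhythm is Rhythm.PACED
            else config.spontaneous_rate_hz
        )
        nominal_rr = 1.0 / rate
        # templates for even/odd beats under alternans
        scales = (1.0 + alternans_eps, 1.0 - alternans_eps)
        templates = []
        for s in scales:
            p = replace(
                params,
                apd30_ms=params.apd30_ms * s,
                apd80_ms=params.apd80_ms * s,
                amplitude=params.amplitude * s * amplitude_factor,
            )
            templates.append(BeatTemplate(p))
        max_duration_s = max(
            (tpl.t_end + tpl.u / 2.0) / 1000.0 for tpl in templates
        )
        if max_duration_s + 0.02 > nominal_rr:
            raise ValueError(
                f"beats overlap: template spans {max_duration_s:.3f} s but the "
                f"beat period is {nominal_rr:.3f} s"
            )

        # activation times
        acts: List[float] = []
        t_act = config.start_s
        while t_act + max_duration_s + 0.02 <= length_s:
            acts.append(t_act)
            if rhythm is Rhythm.PACED or config.rr_jitter == 0:
                t_act += nominal_rr
            else:
                rr = nominal_rr * (1.0 + config.rr_jitter * rng.standard_normal())
                t_act += max(rr, max_duration_s + 0.03)

        events_by_beat: Dict[int, List[EventSpec]] = {}
        for ev in events:
            if not 0 <= ev.beat_index < len(acts):
                raise ValueError(
                    f"event beat_index {ev.beat_index} outside 0..{len(acts) - 1}"
                )
            events_by_beat.setdefault(ev.beat_index, []).append(ev)

        for bi, t_act in enumerate(acts):
            tpl = templates[bi % 2]
            i_lo = max(0, int(math.floor((t_act - tpl.u / 2000.0) * fps)))
            i_hi = min(n, int(math.ceil((t_act + tpl.t_end / 1000.0) * fps)) + 2)
            taus = (t[i_lo:i_hi] - t_act) * 1000.0
            signal[i_lo:i_hi] += tpl.value(taus)

            next_act = acts[bi + 1] if bi + 1 < len(acts) else length_s
            for ev in events_by_beat.get(bi, ()):
                if ev.kind == "EAD":
                    bump, peak_tau = _ead_bump(tpl, ev.amplitude_fraction, ev.timing, taus)
                    signal[i_lo:i_hi] += bump
                    gt_events.append(
                        {
                            "kind": "EAD",
                            "time_s": t_act + peak_tau / 1000.0,
                            "relative_amplitude": ev.amplitude_fraction,
                            "beat_index": bi,
                        }
                    )
                else:  # DAD
                    dia_start = t_act + tpl.apd(0.9) / 1000.0
                    dia = next_act - dia_start
                    if dia < 2.5 * _DAD_WIDTH_MS / 1000.0:
                        raise ValueError("diastolic interval too short for a DAD")
                    margin = _DAD_WIDTH_MS / 1000.0
                    c = dia_start + margin + ev.timing * (dia - 2 * margin)
                    w = _DAD_WIDTH_MS / 1000.0
                    sel = (t >= c - w / 2) & (t <= c + w / 2)
                    hann = 0.5 * (1 - np.cos(2 * np.pi * (t[sel] - c + w / 2) / w))
                    signal[sel] += ev.amplitude_fraction * tpl.A * hann
                    gt_events.append(
                        {
                            "kind": "DAD",
                            "time_s": c,
                            "relative_amplitude": ev.amplitude_fraction,
                            "beat_index": bi,
                        }
                    )

            gt_beats.append(
                {
                    "beat_index": bi,
                    "activation_time_s": t_act,
                    "peak_time_s": t_act + tpl.peak_tau_ms / 1000.0,
                    "amplitude": tpl.A,
                    "apd30_ms": tpl.apd30,
                    "apd50_ms": tpl.apd(0.5),
                    "apd80_ms": tpl.apd80,
                    "apd90_ms": tpl.apd(0.9),
                    "max_upstroke_per_s": tpl.max_upstroke_per_s,
                }
            )
    elif events:
        raise ValueError("cannot inject events into a silent trace")

    fluor = (config.baseline_fluorescence + config.beat_scale * signal) * np.exp(
        -config.bleach_per_s * t
    )
    if config.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, config.noise_sd * config.beat_scale, n)

    trace = FluorescenceTrace(fluor, sampling_rate=fps, channel=params.channel)
    gt = TraceGroundTruth(
        beats=gt_beats,
        events=gt_events,
        silent=silent,
        alternans_eps=alternans_eps,
        params=params,
    )
    return trace, gt


# ---------------------------------------------------------------------------
# drug-effect model

def _hill(dose: float, ec50: float, slope: float) -> float:
    if dose <= 0:
        return 0.0
    r = (dose / ec50) ** slope
    return r / (1.0 + r)


@dataclass(frozen=True)
class DrugEffectModel:
    """Phenomenological dose-response model for one drug arm.

    Every component is a Hill curve in dose (equivalently a logistic in
    log-dose), hence monotone; probabilities saturate at their ``*_max``.
    """

    apd_emax: float = 1.0          # APD multiplier at saturating dose
    apd_ec50_uM: float = 1.0
    apd_hill: float = 1.0
    tri_shift_max: float = 0.0     # added to baseline triangulation
    tri_ec50_uM: float = 10.0
    tri_hill: float = 1.0
    p_ead_max: float = 0.0
    ead_ec50_uM: float = 10.0
    ead_hill: float = 2.0
    p_dad_max: float = 0.0
    dad_ec50_uM: float = 10.0
    dad_hill: float = 2.0
    amp_drop_max: float = 0.0      # amplitude_factor = 1 - amp_drop_max * hill
    amp_ec50_uM: float = 100.0
    amp_hill: float = 1.0
    p_silent_max: float = 1.0
    silent_ec50_uM: float = 1e9    # effectively "never" unless set
    silent_hill: float = 3.0
    alternans_max: float = 0.0
    alternans_ec50_uM: float = 10.0
    alternans_hill: float = 2.0

    def apd_multiplier(self, dose_uM: float) -> float:
        return 1.0 + (self.apd_emax - 1.0) * _hill(dose_uM, self.apd_ec50_uM, self.apd_hill)

    def triangulation_shift(self, dose_uM: float) -> float:
        return self.tri_shift_max * _hill(dose_uM, self.tri_ec50_uM, self.tri_hill)

    def p_ead(self, dose_uM: float) -> float:
        return self.p_ead_max * _hill(dose_uM, self.ead_ec50_uM, self.ead_hill)

    def p_dad(self, dose_uM: float) -> float:
        return self.p_dad_max * _hill(dose_uM, self.dad_ec50_uM, self.dad_hill)

    def amplitude_factor(self, dose_uM: float) -> float:
        return 1.0 - self.amp_drop_max * _hill(dose_uM, self.amp_ec50_uM, self.amp_hill)

    def p_silent(self, dose_uM: float) -> float:
        return self.p_silent_max * _hill(dose_uM, self.silent_ec50_uM, self.silent_hill)

    def alternans_eps(self, dose_uM: float) -> float:
        return self.alternans_max * _hill(dose_uM, self.alternans_ec50_uM, self.alternans_hill)


def hcq_like_model() -> DrugEffectModel:
    """APD-prolonging, EAD-generating profile (hERG-block-like).

    APD Hill with EC50 at the 1 µM clinical Cmax and a 1.4x ceiling; EADs
    emerge around 10 µM; beating ceases near the 1000 µM top dose.
    """
    return DrugEffectModel(
        apd_emax=1.4,
        apd_ec50_uM=1.0,
        apd_hill=1.0,
        tri_shift_max=0.12,
        tri_ec50_uM=10.0,
        tri_hill=1.0,
        p_ead_max=0.9,
        ead_ec50_uM=10.0,
        ead_hill=2.0,
        amp_drop_max=0.3,
        amp_ec50_uM=100.0,
        amp_hill=1.0,
        p_silent_max=1.0,
        silent_ec50_uM=300.0,
        silent_hill=3.0,
    )


def polytherapy_like_model() -> DrugEffectModel:
    """Combination profile (dose = total µM): APD prolongation present from
    the first step, triangulation and EADs rising with the escalating
    component, partial loss of signal at the top dose."""
    return DrugEffectModel(
        apd_emax=1.45,
        apd_ec50_uM=0.8,
        apd_hill=1.0,
        tri_shift_max=0.15,
        tri_ec50_uM=2.0,
        tri_hill=1.5,
        p_ead_max=0.6,
        ead_ec50_uM=2.0,
        ead_hill=2.0,
        alternans_max=0.10,
        alternans_ec50_uM=3.0,
        alternans_hill=2.0,
        amp_drop_max=0.3,
        amp_ec50_uM=6.0,
        amp_hill=1.5,
        p_silent_max=1.0,
        silent_ec50_uM=12.0,
        silent_hill=3.0,
    )


def default_effect_models(design: DoseEscalationDesign) -> Dict[str, DrugEffectModel]:
    """Preset effect model per arm, chosen by arm name."""
    models: Dict[str, DrugEffectModel] = {}
    for arm in design.drugs:
        if len(arm.components) > 1:
            models[arm.name] = polytherapy_like_model()
        elif arm.name.upper().startswith("AZM"):
            models[arm.name] = azm_like_model()
        elif arm.name.upper().startswith("HCQ"):
            models[arm.name] = hcq_like_model()
        else:
            models[arm.name] = DrugEffectModel()
    return models


def azm_like_model() -> DrugEffectModel:
    """Instability-without-QT-prolongation profile: flat APD, rising DADs
    and alternans, beating cessation near 67 µM (100x Cmax)."""
    return DrugEffectModel(
        apd_emax=1.0,
        tri_shift_max=0.10,
        tri_ec50_uM=5.0,
        tri_hill=1.5,
        p_dad_max=0.8,
        dad_ec50_uM=3.0,
        dad_hill=2.0,
        alternans_max=0.12,
        alternans_ec50_uM=5.0,
        alternans_hill=2.0,
        amp_drop_max=0.35,
        amp_ec50_uM=30.0,
        amp_hill=1.5,
        p_silent_max=1.0,
        silent_ec50_uM=30.0,
        silent_hill=3.0,
    )


# ---------------------------------------------------------------------------
# cohorts

#: baseline tissue APD80 distribution: Normal(350, 60) truncated to [200, 600] ms
BASELINE_APD80_MEAN = 350.0
BASELINE_APD80_SD = 60.0
BASELINE_APD80_RANGE = (200.0, 600.0)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated normal rejection failed")


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass
class CohortSim:
    """A simulated dose-escalation cohort with its ground-truth tables."""

    traces: TraceSet
    tissues: pd.DataFrame       # per tissue: baseline APD80/30, rate, chip/chamber
    tissue_dose: pd.DataFrame   # per tissue x dose: realized effect parameters
    events: pd.DataFrame        # injected events on the classification recording
    design: DoseEscalationDesign
    config: SimConfig

    def write_dir(self, path) -> None:
        """Write the trace CSV dialect, the design YAML and ground truth."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        trace_dir = path / "traces"
        trace_dir.mkdir(exist_ok=True)
        for meta, trace in self.traces:
            name = (
                f"{meta.tissue_id}_d{meta.dose_index}_{trace.channel.value}"
                f"_{meta.rhythm.value}_{meta.recording_length_s:g}s.csv"
            )
            write_trace_csv(meta, trace, trace_dir / name)
        save_design(self.design, path / "design.yaml")
        self.tissues.to_csv(path / "ground_truth_tissues.csv", index=False)
        self.tissue_dose.to_csv(path / "ground_truth_tissue_dose.csv", index=False)
        self.events.to_csv(path / "ground_truth_events.csv", index=False)


def _plan_events(
    kind: str, n_beats: int, rng: np.random.Generator, max_events: int = 6
) -> List[EventSpec]:
    """Spread 1..max_events afterdepolarizations over the beats of a trace."""
    n_events = min(max_events, max(1, n_beats // 4))
    # skip the first/last beat; space events out evenly
    candidates = np.linspace(1, max(1, n_beats - 2), n_events).astype(int)
    specs = []
    for bi in np.unique(candidates):
        h = float(rng.uniform(0.10, 0.25))
        timing = float(rng.uniform(0.3, 0.5))
        specs.append(EventSpec(kind=kind, beat_index=int(bi), amplitude_fraction=h, timing=timing))
    return specs


def simulate_cohort(
    design: DoseEscalationDesign,
    effects: Mapping[str, DrugEffectModel],
    config: SimConfig,
) -> CohortSim:
    """Simulate every recording of a dose-escalation study.

    For each arm, ``design.n_tissues`` tissues are drawn; each tissue x dose
    step realizes the drug-effect model (APD multiplier, triangulation,
    amplitude factor, silence, events, alternans) once and renders every
    recording of the protocol with a deterministic per-recording RNG
    substream.  Arrhythmic events are injected into the spontaneous calcium
    recordings — the ones the classifier reads.  Realized APD80 is capped so
    repolarization completes within the shortest beat period of the
    protocol (a tissue cannot repolarize past its cycle length).
    """
    traces = TraceSet()
    tissue_rows, dose_rows, event_rows = [], [], []

    for arm_idx, arm in enumerate(design.drugs):
        model = effects[arm.name]
        totals = arm.total_uM
        for t_idx in range(design.n_tissues):
            tissue_id = f"{arm.name}-T{t_idx + 1:02d}"
            chip_id = f"{arm.name}-C{t_idx // design.chambers_per_chip + 1}"
            chamber = t_idx % design.chambers_per_chip + 1
            rng_t = _substream(config.seed, arm_idx, t_idx)
            apd80_0 = _truncated_normal(
                rng_t, BASELINE_APD80_MEAN, BASELINE_APD80_SD, *BASELINE_APD80_RANGE
            )
            tri_0 = float(np.clip(rng_t.normal(0.35, 0.05), 0.2, 0.5))
            rate = float(np.clip(rng_t.normal(0.75, 0.08), 0.55, 1.0))
            tissue_rows.append(
                {
                    "drug": arm.name,
                    "tissue_id": tissue_id,
                    "chip_id": chip_id,
                    "chamber_index": chamber,
                    "baseline_apd80_ms": apd80_0,
                    "baseline_triangulation": tri_0,
                    "spontaneous_rate_hz": rate,
                }
            )

            cfg_t = replace(config, spontaneous_rate_hz=rate,
                            pacing_frequency_hz=design.pacing_frequency_hz)
            # shortest beat period across the protocol bounds repolarization
            min_rr_s = min(
                1.0 / design.pacing_frequency_hz,
                (1.0 / rate) * (1.0 - 4.0 * config.rr_jitter),
            )

            for d_idx, dose_total in enumerate(totals):
                rng_td = _substream(config.seed, arm_idx, t_idx, d_idx)
                m = model.apd_multiplier(dose_total)
                tri = float(np.clip(tri_0 + model.triangulation_shift(dose_total), 0.05, 0.8))
                apd80_cap = 0.8 * min_rr_s * 1000.0 / (1.0 + 0.5 * tri)
                apd80_d = min(apd80_0 * m, apd80_cap)
                apd30_d = (1.0 - tri) * apd80_d
                amp_f = model.amplitude_factor(dose_total)
                silent = bool(rng_td.random() < model.p_silent(dose_total))
                has_ead = bool(rng_td.random() < model.p_ead(dose_total))
                has_dad = bool(rng_td.random() < model.p_dad(dose_total))
                eps = model.alternans_eps(dose_total)
                dose_rows.append(
                    {
                        "drug": arm.name,
                        "tissue_id": tissue_id,
                        "dose_index": d_idx,
                        "dose_uM": dose_total,
                        **{f"dose_{c.name}_uM": c.doses_uM[d_idx] for c in arm.components},
                        "apd_multiplier_realized": apd80_d / apd80_0,
                        "apd80_ms": apd80_d,
                        "triangulation": tri,
                        "amplitude_factor": amp_f,
                        "alternans_eps": eps,
                        "silent": silent,
                        "has_ead": has_ead,
                        "has_dad": has_dad,
                    }
                )

                for rec_idx, (ch, rhythm, length) in enumerate(design.recording_protocol):
                    rng_rec = _substream(config.seed, arm_idx, t_idx, d_idx, rec_idx)
                    params = BeatTemplateParams(
                        channel=Channel(ch),
                        apd30_ms=apd30_d,
                        apd80_ms=apd80_d,
                        amplitude=1.0,
                    )
                    specs: List[EventSpec] = []
                    if (
                        not silent
                        and Channel(ch) is Channel.CALCIUM
                        and Rhythm(rhythm) is Rhythm.SPONTANEOUS
                    ):
                        n_beats_est = int((length - config.start_s) * rate) - 1
                        if has_ead and n_beats_est >= 3:
                            specs += _plan_events("EAD", n_beats_est, rng_rec)
                        if has_dad and n_beats_est >= 3:
                            specs += _plan_events("DAD", n_beats_est, rng_rec)
                    trace, gt = simulate_trace(
                        params,
                        cfg_t,
                        rhythm=rhythm,
                        events=specs,
                        length_s=length,
                        alternans_eps=eps,
                        amplitude_factor=amp_f,
                        silent=silent,
                        rng=rng_rec,
                    )
                    meta = RecordingMeta(
                        tissue_id=tissue_id,
                        chip_id=chip_id,
                        chamber_index=chamber,
                        drug=arm.name,
                        dose=dose_total,
                        dose_index=d_idx,
                        rhythm=Rhythm(rhythm),
                        pacing_frequency=(
                            design.pacing_frequency_hz
                            if Rhythm(rhythm) is Rhythm.PACED
                            else None
                        ),
                        recording_length_s=length,
                    )
                    traces.add(meta, trace)
                    for ev in gt.events:
                        event_rows.append(
                            {
                                "drug": arm.name,
                                "tissue_id": tissue_id,
                                "dose_index": d_idx,
                                "channel": ch,
                                "rhythm": rhythm,
                                "recording_length_s": length,
                                **ev,
                            }
                        )

    return CohortSim(
        traces=traces,
        tissues=pd.DataFrame(tissue_rows),
        tissue_dose=pd.DataFrame(dose_rows),
        events=pd.DataFrame(
            event_rows,
            columns=[
                "drug",
                "tissue_id",
                "dose_index",
                "channel",
                "rhythm",
                "recording_length_s",
                "kind",
                "time_s",
                "relative_amplitude",
                "beat_index",
            ],
        ),
        design=design,
        config=config,
    )


# ---------------------------------------------------------------------------
# biomarker panels

def simulate_biomarker_panel(
    n_markers: int,
    n_samples: int,
    n_neg_controls: int,
    detect_fractions: Sequence[float],
    seed: int = 0,
) -> Tuple[BiomarkerPanel, pd.DataFrame]:
    """Simulate a marker x sample panel realizing requested detection rates.

    Negative controls are Normal(mu_m, sigma_m); study samples are placed a
    clear margin above or below the marker's population LOD
    (mu_m + 3 sigma_m) so that approximately ``detect_fractions[m]`` of the
    samples are detected.  Ground truth records the intended retention under
    the >65% rule.
    """
    if n_neg_controls < 2:
        raise ValueError("need at least 2 negative controls (SD undefined)")
    detect_fractions = list(detect_fractions)
    if len(detect_fractions) != n_markers:
        raise ValueError("one detect_fraction per marker required")
    if any(not 0 <= f <= 1 for f in detect_fractions):
        raise ValueError("detect_fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    markers = [f"M{i + 1:03d}" for i in range(n_markers)]
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    controls = [f"NC{i + 1:02d}" for i in range(n_neg_controls)]

    ctrl = np.empty((n_markers, n_neg_controls))
    vals = np.empty((n_markers, n_samples))
    gt_rows = []
    for mi, f in enumerate(detect_fractions):
        mu = rng.uniform(2.0, 6.0)
        sigma = rng.uniform(0.10, 0.30)
        ctrl[mi] = rng.normal(mu, sigma, n_neg_controls)
        lod_true = mu + 3.0 * sigma
        n_above = int(round(f * n_samples))
        above = lod_true + rng.uniform(1.0, 3.0, n_above) * sigma
        below = lod_true - rng.uniform(1.0, 3.0, n_samples - n_above) * sigma
        row = np.concatenate([above, below])
        rng.shuffle(row)
        vals[mi] = row
        gt_rows.append(
            {
                "marker": markers[mi],
                "requested_detect_fraction": f,
                "n_above_true_lod": n_above,
                "intended_retained": f > 0.65,
            }
        )

    panel = BiomarkerPanel(
        values=pd.DataFrame(vals, index=markers, columns=samples),
        negative_controls=pd.DataFrame(ctrl, index=markers, columns=controls),
        sample_meta=pd.DataFrame({"sample": samples}),
    )
    return panel, pd.DataFrame(gt_rows)
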