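"""Afterdepolarization detection, beat-to-beat instability, and tissue calls.

Arrhythmia-like behaviour in the optical traces is read three ways, following
standard safety-pharmacology practice for hiPSC-CM preparations:

* **EADs** — early afterdepolarizations: depolarizing deflections during
  phase 3, i.e. between the beat peak and the APD90 crossing.  Detected as a
  local minimum followed by a rise of at least ``theta_ead`` times the parent
  beat amplitude.
* **DADs** — delayed afterdepolarizations: sub-threshold deflections in the
  diastolic interval (APD90 crossing to the next activation).  Deflections
  with prominence of at least ``theta_dad`` of the preceding beat amplitude
  count; deflections at or above ``beat_threshold`` are full beats and are
  the segmenter's business, not events.
* **TdP-like shape change** — continuous variation of amplitude and
  configuration (loss of plateau), quantified as the larger of the
  coefficient of variation of beat amplitudes and of APD50.

Beat-to-beat instability is quantified on the Poincaré construction: each
APD80 is plotted against its predecessor, both normalized to the recording's
mean APD80.  The instability index is the RMS perpendicular distance of the
pairs from the identity line (an SD1-style short-term variability); for
perfect alternans ``a(1 ± eps)`` it equals ``eps * sqrt(2)``.

A tissue x dose recording is called exactly one of ``normal``,
``arrhythmic``, or ``weak_or_silent``; weakness takes precedence: a
datapoint with no beating or a maximal amplitude below 60% of the same
tissue's drug-free control is weak-or-silent regardless of events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .beats import BeatSeries, _smooth
from .config import AnalysisConfig
from .traces import FluorescenceTrace

__all__ = [
    "EventKind",
    "TissueCategory",
    "ArrhythmicEvent",
    "PoincarePairs",
    "TissueCall",
    "detect_eads",
    "detect_dads",
    "shape_irregularity",
    "poincare_pairs",
    "instability_index",
    "classify_tissue",
    "cohort_incidence",
]


class EventKind(str, Enum):
    EAD = "EAD"
    DAD = "DAD"


class TissueCategory(str, Enum):
    NORMAL = "normal"
    ARRHYTHMIC = "arrhythmic"
    WEAK_OR_SILENT = "weak_or_silent"


@dataclass(frozen=True)
class ArrhythmicEvent:
    kind: EventKind
    time_s: float
    relative_amplitude: float  # fraction of the parent/preceding beat amplitude
    beat_index: int

    def __post_init__(self) -> None:
        if not 0 < self.relative_amplitude < 1:
            raise ValueError("relative_amplitude must be in (0, 1)")


@dataclass(frozen=True)
class PoincarePairs:
    """Successive mean-normalized APD80 pairs, ``(APD_{n-1}, APD_n) / mean``."""

    pairs: np.ndarray  # shape (n-1, 2)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be an (n, 2) array")
        object.__setattr__(self, "pairs", arr)


@dataclass
class TissueCall:
    category: TissueCategory
    events: List[ArrhythmicEvent]
    amplitude_vs_control: float
    shape_irregularity: float
    instability_index: float
    instability_flag: bool
    n_beats: int = 0


def _beat_windows(trace: FluorescenceTrace, series: BeatSeries):
    """Per beat: (peak_idx, apd90_idx_or_None, next_activation_idx)."""
    fs = trace.sampling_rate
    n = trace.samples.size
    out = []
    for i, b in enumerate(series.beats):
        nxt = (
            series.beats[i + 1].activation_index if i + 1 < len(series.beats) else n - 1
        )
        if b.apd90_ms is not None:
            idx90 = int(round((b.activation_time_s - trace.t0 + b.apd90_ms / 1000.0) * fs))
            idx90 = min(idx90, nxt)
        else:
            idx90 = None
        out.append((b.peak_index, idx90, nxt))
    return out


def detect_eads(
    trace: FluorescenceTrace,
    series: BeatSeries,
    theta_ead: float = 0.05,
    smooth_samples: int = 3,
    min_width_samples: int = 2,
) -> List[ArrhythmicEvent]:
    """Early afterdepolarizations within each beat's phase-3 window.

    For every beat, the window is ``(peak, APD90 crossing]`` (clipped at the
    next activation).  Any local minimum followed by a rise of at least
    ``theta_ead`` of the parent beat amplitude before the signal resumes
    falling is one EAD; its relative amplitude is the rise as a fraction of
    the beat amplitude.
    """
    x = trace.samples
    xs = _smooth(x, smooth_samples)
    fs = trace.sampling_rate
    back = int(round(0.12 * fs))  # search window for the pre-event local min
    events: List[ArrhythmicEvent] = []
    for bi, (p, idx90, nxt) in enumerate(_beat_windows(trace, series)):
        end = idx90 if idx90 is not None else nxt
        if end - p < 3:
            continue
        seg = xs[p : end + 1]
        amp = series.beats[bi].amplitude
        peaks, props = signal.find_peaks(
            seg,
            prominence=theta_ead * amp * 0.8,
            width=(min_width_samples, None),
            rel_height=0.5,
        )
        for k, pk in enumerate(peaks):
            # the rise: refined on raw samples, from the local minimum just
            # before the deflection (smoothing at 100 frames/s attenuates a
            # narrow bump riding a steep repolarization)
            abs_pk = p + pk
            lo = max(p + 1, abs_pk - back)
            min_idx = lo + int(np.argmin(xs[lo : abs_pk + 1]))
            peak_v = float(x[max(0, abs_pk - 1) : abs_pk + 2].max())
            min_v = float(x[max(0, min_idx - 1) : min_idx + 2].min())
            rel = (peak_v - min_v) / amp
            if rel < theta_ead:
                continue
            events.append(
                ArrhythmicEvent(
                    kind=EventKind.EAD,
                    time_s=trace.t0 + abs_pk / fs,
                    relative_amplitude=min(float(rel), 1.0 - 1e-9),
                    beat_index=bi,
                )
            )
    return events


def detect_dads(
    trace: FluorescenceTrace,
    series: BeatSeries,
    theta_dad: float = 0.10,
    beat_threshold: float = 0.60,
    smooth_samples: int = 3,
    min_width_samples: int = 2,
) -> List[ArrhythmicEvent]:
    """Delayed afterdepolarizations in each diastolic interval.

    The window runs from a beat's APD90 crossing to the next activation (or
    the end of the trace).  A positive deflection with prominence of at least
    ``theta_dad`` — and below ``beat_threshold`` — of the preceding beat's
    amplitude is one DAD.
    """
    xs = _smooth(trace.samples, smooth_samples)
    fs = trace.sampling_rate
    events: List[ArrhythmicEvent] = []
    for bi, (p, idx90, nxt) in enumerate(_beat_windows(trace, series)):
        start = idx90 if idx90 is not None else None
        if start is None or nxt - start < 3:
            continue
        seg = xs[start : nxt + 1]
        amp = series.beats[bi].amplitude
        peaks, props = signal.find_peaks(
            seg,
            prominence=theta_dad * amp,
            width=(min_width_samples, None),
            rel_height=0.5,
        )
        for k, pk in enumerate(peaks):
            rel = float(props["prominences"][k] / amp)
            if rel >= beat_threshold:
                continue  # that is a beat, the segmenter's business
            events.append(
                ArrhythmicEvent(
                    kind=EventKind.DAD,
                    time_s=trace.t0 + (start + pk) / fs,
                    relative_amplitude=rel,
                    beat_index=bi,
                )
            )
    return events


def shape_irregularity(series: BeatSeries, trace: Optional[FluorescenceTrace] = None) -> float:
    """Beat-to-beat waveform irregularity, the TdP-like trait.

    The larger of the coefficient of variation (population) of beat
    amplitudes and of APD50 over the recording.  Requires at least 4 beats;
    returns NaN ("not evaluable") otherwise.
    """
    if len(series) < 4:
        return math.nan
    amps = np.array([b.amplitude for b in series.beats], dtype=float)
    cv_amp = float(np.std(amps) / np.mean(amps))
    apd50 = np.array(
        [b.apd50_ms for b in series.beats if b.apd50_ms is not None], dtype=float
    )
    cv_apd = (
        float(np.std(apd50) / np.mean(apd50)) if apd50.size >= 4 else -math.inf
    )
    return max(cv_amp, cv_apd)


def poincare_pairs(apd80_sequence: Sequence[float]) -> PoincarePairs:
    """Mean-normalized successive APD80 pairs for the Poincaré plot."""
    arr = np.asarray(apd80_sequence, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 APD80 values for a Poincaré plot")
    norm = arr / arr.mean()
    return PoincarePairs(np.column_stack([norm[:-1], norm[1:]]))


def instability_index(
    pairs: PoincarePairs, threshold: float = 0.05
) -> tuple[float, bool]:
    """Short-term beat-to-beat variability read from the Poincaré pairs.

    The index is the RMS perpendicular distance of the mean-normalized pairs
    from the identity line (SD1-like).  A constant APD sequence gives exactly
    0; perfect alternans ``a(1 ± eps)`` gives ``eps * sqrt(2)``.  ``unstable``
    is True above ``threshold`` (default 0.05, i.e. 5% of the mean APD).
    """
    prev = pairs.pairs[:, 0]
    curr = pairs.pairs[:, 1]
    d = (curr - prev) / math.sqrt(2.0)
    index = float(np.sqrt(np.mean(d * d)))
    return index, index > threshold


def classify_tissue(
    trace: FluorescenceTrace,
    series: BeatSeries,
    control_amplitude: float,
    config: Optional[AnalysisConfig] = None,
) -> TissueCall:
    """Call one tissue x dose recording: normal, arrhythmic, or weak_or_silent.

    Precedence: (1) weak_or_silent if no beats were detected or the maximal
    beat amplitude is below 60% of the same tissue's drug-free control
    amplitude; else (2) arrhythmic if any EAD or DAD is detected or the
    shape irregularity exceeds its threshold; else (3) normal.  The
    classification is meant for the 30-s spontaneous calcium recording; the
    amplitude comparison requires both recordings on the same (detrended,
    un-normalized) intensity scale.
    """
    cfg = config or AnalysisConfig()
    if not control_amplitude > 0:
        raise ValueError("control (dose 0) amplitude is required and must be > 0")

    if len(series) == 0:
        return TissueCall(
            category=TissueCategory.WEAK_OR_SILENT,
            events=[],
            amplitude_vs_control=0.0,
            shape_irregularity=math.nan,
            instability_index=math.nan,
            instability_flag=False,
            n_beats=0,
        )

    max_amp = max(b.amplitude for b in series.beats)
    ratio = max_amp / control_amplitude

    events = detect_eads(
        trace, series, cfg.theta_ead, cfg.smooth_samples, cfg.event_min_width_samples
    ) + detect_dads(
        trace,
        series,
        cfg.theta_dad,
        cfg.dad_beat_threshold,
        cfg.smooth_samples,
        cfg.event_min_width_samples,
    )
    events.sort(key=lambda e: e.time_s)
    irregularity = shape_irregularity(series, trace)

    apd_seq = series.apd80_sequence()
    if apd_seq.size >= 3:
        index, unstable = instability_index(
            poincare_pairs(apd_seq), cfg.instability_threshold
        )
    else:
        index, unstable = math.nan, False

    if ratio < cfg.weak_amplitude_ratio:
        category = TissueCategory.WEAK_OR_SILENT
    elif len(events) >= cfg.arrhythmic_min_events or (
        not math.isnan(irregularity)
        and irregularity > cfg.shape_irregularity_threshold
    ):
        category = TissueCategory.ARRHYTHMIC
    else:
        category = TissueCategory.NORMAL

    return TissueCall(
        category=category,
        events=events,
        amplitude_vs_control=ratio,
        shape_irregularity=irregularity,
        instability_index=index,
        instability_flag=unstable,
        n_beats=len(series),
    )


def cohort_incidence(
    calls_by_dose: Mapping[object, Sequence[TissueCall | TissueCategory | str]]
) -> pd.DataFrame:
    """Per-dose fractions of arrhythmic / weak-or-silent / normal tissues.

    Fractions sum to 1 per dose; the ``*_pct`` columns report the same
    numbers as percentages of the total number of MPS at that dose.
    """
    rows = []
    for dose, calls in calls_by_dose.items():
        if len(calls) == 0:
            raise ValueError(f"empty dose group {dose!r}")
        cats = [
            TissueCategory(c.category if isinstance(c, TissueCall) else c)
            for c in calls
        ]
        n = len(cats)
        row = {"dose": dose, "n": n}
        for cat in TissueCategory:
            frac = sum(c is cat for c in cats) / n
            row[cat.value] = frac
            row[f"{cat.value}_pct"] = 100.0 * frac
        rows.append(row)
    return pd.DataFrame(rows)
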