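"""Dose-escalation study orchestration.

Composes the full analysis the way the wet-lab protocol is read out:

1. **Inclusion** — tissues whose drug-free baseline APD80 is 500 ms or more
   are excluded (QT > 500 ms marks TdP risk; such tissues are outside the
   assay's calibrated range).
2. **Per-recording beat analysis** with per-channel detrending, amplitude
   scaling against the same tissue's dose-0 recording, and metric routing:
   APD80 and upstroke velocities come from paced recordings when the tissue
   captures the stimulus (then RR is the pacing period), otherwise from
   spontaneous recordings with measured RR; triangulation from spontaneous
   voltage traces; beat rate, Poincaré instability and the arrhythmia
   classification from the 30-s spontaneous calcium recording.
3. **Baseline normalization** — each tissue's metric divided by its own
   dose-0 value (dose 0 maps to exactly 1).
4. **Statistics** — one-way ANOVA with Dunnett many-to-one comparisons
   against dose 0 per metric, pairwise chi-squared on arrhythmia incidence.
5. **Biomarkers** — the limit-of-detection retention filter, if a panel is
   supplied.

Doses where a tissue shows no or weak signal are reported as not evaluable
with a reason, never imputed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .arrhythmia import TissueCall, TissueCategory, classify_tissue, cohort_incidence
from .beats import (
    BeatSeries,
    capture_check,
    detrend,
    fridericia_correct,
    normalize,
    segment_beats,
    triangulation,
)
from .biomarkers import BiomarkerPanel, LodResult, lod_filter
from .config import AnalysisConfig
from .design import DoseEscalationDesign
from .stats import anova_dunnett, chi_square_pairwise
from .traces import Channel, FluorescenceTrace, RecordingMeta, Rhythm, TraceSet

__all__ = [
    "StudyReport",
    "StudyDesignError",
    "inclusion_filter",
    "normalize_to_baseline",
    "run_study",
]


class StudyDesignError(ValueError):
    """Traces do not cover the study design (e.g. a missing dose-0 recording)."""


def inclusion_filter(
    baseline_apd80_ms: Mapping[str, Optional[float]],
    threshold_ms: float = 500.0,
) -> Tuple[Set[str], Dict[str, str]]:
    """Select tissues whose baseline APD80 is strictly below the threshold.

    Returns ``(included tissue ids, excluded tissue id -> reason)``.  A
    missing baseline excludes the tissue with a logged reason.
    """
    included: Set[str] = set()
    excluded: Dict[str, str] = {}
    for tissue, apd in baseline_apd80_ms.items():
        if apd is None or (isinstance(apd, float) and math.isnan(apd)):
            excluded[tissue] = "no baseline APD80 (no resolvable dose-0 beats)"
        elif apd < threshold_ms:
            included.add(tissue)
        else:
            excluded[tissue] = (
                f"baseline APD80 {apd:.1f} ms >= {threshold_ms:g} ms inclusion limit"
            )
    return included, excluded


def normalize_to_baseline(
    metrics: pd.DataFrame,
    columns: Sequence[str],
    tissue_col: str = "tissue_id",
    dose_col: str = "dose_index",
) -> pd.DataFrame:
    """Divide each tissue's metric by its own dose-0 value.

    Adds ``<column>_norm`` columns; dose 0 maps to exactly 1.  Raises when a
    tissue lacks a dose-0 value or its baseline is zero.
    """
    out = metrics.copy()
    for col in columns:
        norm = np.full(len(out), np.nan)
        for tissue, group in out.groupby(tissue_col):
            base_rows = group[group[dose_col] == 0]
            if base_rows.empty:
                raise StudyDesignError(f"tissue {tissue!r}: no dose-0 row")
            base = float(base_rows[col].iloc[0])
            if math.isnan(base):
                raise StudyDesignError(
                    f"tissue {tissue!r}: dose-0 value of {col!r} is missing"
                )
            if base == 0:
                raise StudyDesignError(
                    f"tissue {tissue!r}: dose-0 value of {col!r} is zero"
                )
            norm[group.index] = group[col] / base
        out[f"{col}_norm"] = norm
        # exactness at baseline (guard against float division wobble)
        out.loc[out[dose_col] == 0, f"{col}_norm"] = 1.0
    return out


# ---------------------------------------------------------------------------
# per-recording analysis

@dataclass
class _Recording:
    meta: RecordingMeta
    scaled: FluorescenceTrace    # detrended, divided by the dose-0 amplitude
    series: BeatSeries
    captured: Optional[bool]     # None for spontaneous recordings


def _detrend_method(channel: Channel, cfg: AnalysisConfig) -> str:
    return (
        cfg.detrend_method_calcium
        if channel is Channel.CALCIUM
        else cfg.detrend_method_voltage
    )


def _control_amplitude(
    trace: FluorescenceTrace, cfg: AnalysisConfig
) -> Optional[float]:
    """Median beat amplitude of a dose-0 recording, in detrended units."""
    d = detrend(trace, _detrend_method(trace.channel, cfg), cfg.detrend_window_s)
    span = d.samples.max() - d.samples.min()
    if span <= 0:
        return None
    series = segment_beats(
        normalize(d), cfg.min_prominence, cfg.refractory_ms, cfg.smooth_samples
    )
    if len(series) == 0:
        return None
    amps = np.array([b.amplitude for b in series.beats])
    return float(np.median(amps) * span)


def _analyze_recording(
    meta: RecordingMeta,
    trace: FluorescenceTrace,
    scale: float,
    cfg: AnalysisConfig,
) -> _Recording:
    d = detrend(trace, _detrend_method(trace.channel, cfg), cfg.detrend_window_s)
    scaled = d.with_samples(d.samples / scale)
    series = segment_beats(
        scaled, cfg.min_prominence, cfg.refractory_ms, cfg.smooth_samples
    )
    captured = None
    if meta.rhythm is Rhythm.PACED:
        captured = capture_check(series, meta.pacing_frequency, cfg.capture_tol)
    return _Recording(meta=meta, scaled=scaled, series=series, captured=captured)


def _median_triangulation(series: BeatSeries) -> float:
    values = [
        triangulation(b.apd30_ms, b.apd80_ms)
        for b in series.beats
        if b.apd30_ms is not None and b.apd80_ms is not None and b.apd30_ms > 0
    ]
    return float(np.median(values)) if values else math.nan


def _mean_rr(series: BeatSeries) -> float:
    if len(series) < 2:
        return math.nan
    return float(np.mean(series.rr_intervals_s))


# ---------------------------------------------------------------------------
# report

_STAT_METRICS = (
    "apd80_corrected_ms_norm",
    "triangulation",
    "beat_rate_hz",
    "v_max_upstroke",
    "ca_max_upstroke",
    "instability_index",
)


@dataclass
class StudyReport:
    metrics: pd.DataFrame          # one row per tissue x dose
    events: pd.DataFrame           # one row per detected EAD/DAD
    incidence: pd.DataFrame        # per drug x dose category fractions
    anova: pd.DataFrame            # Dunnett table per drug x metric
    chi_square: pd.DataFrame       # pairwise incidence tests per drug
    inclusion: pd.DataFrame        # per tissue: included flag, reason
    lod: Optional[LodResult]
    config: AnalysisConfig
    log: dict

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(path / "metrics.csv", index=False)
        self.events.to_csv(path / "events.csv", index=False)
        self.incidence.to_csv(path / "incidence.csv", index=False)
        self.anova.to_csv(path / "anova_dunnett.csv", index=False)
        self.chi_square.to_csv(path / "chi_square_pairwise.csv", index=False)
        self.inclusion.to_csv(path / "inclusion.csv", index=False)
        if self.lod is not None:
            pd.DataFrame(
                {
                    "marker": self.lod.detection_fraction.index,
                    "detection_fraction": self.lod.detection_fraction.values,
                    "lod": self.lod.lod.values,
                    "retained": [
                        m in set(self.lod.retained)
                        for m in self.lod.detection_fraction.index
                    ],
                }
            ).to_csv(path / "biomarkers_lod.csv", index=False)
        (path / "run_log.json").write_text(json.dumps(self.log, indent=2, sort_keys=True))


def run_study(
    design: DoseEscalationDesign,
    traces: TraceSet,
    panel: Optional[BiomarkerPanel] = None,
    config: Optional[AnalysisConfig] = None,
) -> StudyReport:
    """Run the complete dose-escalation analysis over a trace set.

    Raises :class:`StudyDesignError` when the traces do not cover the design
    (every tissue needs its dose-0 recordings).
    """
    cfg = config or AnalysisConfig()
    metric_rows: List[dict] = []
    event_rows: List[dict] = []
    inclusion_rows: List[dict] = []
    anova_rows: List[dict] = []
    chi_rows: List[dict] = []
    incidence_frames: List[pd.DataFrame] = []

    for arm in design.drugs:
        arm_tissues = sorted(
            {meta.tissue_id for meta, _ in traces if meta.drug == arm.name}
        )
        if not arm_tissues:
            continue
        totals = arm.total_uM

        # --- dose-0 amplitude scales and baseline APD80 per tissue
        scales: Dict[Tuple[str, Channel], float] = {}
        baseline_apd: Dict[str, Optional[float]] = {}
        missing: List[str] = []
        for tissue in arm_tissues:
            entry = traces.get(tissue, 0, Channel.CALCIUM, Rhythm.SPONTANEOUS, 30.0)
            if entry is None:
                missing.append(tissue)
                continue
            for channel in Channel:
                amp = None
                for rhythm, length in (
                    (Rhythm.SPONTANEOUS, 30.0),
                    (Rhythm.SPONTANEOUS, 6.0),
                    (Rhythm.PACED, 6.0),
                ):
                    e = traces.get(tissue, 0, channel, rhythm, length)
                    if e is not None:
                        amp = _control_amplitude(e[1], cfg)
                        if amp is not None:
                            break
                if amp is not None:
                    scales[(tissue, channel)] = amp
        if missing:
            raise StudyDesignError(
                f"arm {arm.name!r}: missing dose-0 30-s spontaneous calcium "
                f"recording for tissues {missing}"
            )

        # --- per tissue x dose analysis
        rows_by_tissue: Dict[str, List[dict]] = {t: [] for t in arm_tissues}
        for tissue in arm_tissues:
            for d_idx, dose_total in enumerate(totals):
                row: dict = {
                    "drug": arm.name,
                    "tissue_id": tissue,
                    "dose_index": d_idx,
                    "dose_uM": dose_total,
                }
                recs: Dict[Tuple[Channel, Rhythm, float], _Recording] = {}
                for ch, rhythm, length in design.recording_protocol:
                    entry = traces.get(tissue, d_idx, ch, rhythm, length)
                    if entry is None:
                        continue
                    scale = scales.get((tissue, Channel(ch)))
                    if scale is None:
                        continue
                    recs[(Channel(ch), Rhythm(rhythm), length)] = _analyze_recording(
                        entry[0], entry[1], scale, cfg
                    )

                def pick(channel: Channel, prefer_paced: bool) -> Optional[_Recording]:
                    order = []
                    if prefer_paced and cfg.prefer_paced_metrics:
                        order += [
                            k for k in recs if k[0] is channel and k[1] is Rhythm.PACED
                        ]
                    order += [
                        k
                        for k in sorted(recs, key=lambda k: -k[2])
                        if k[0] is channel and k[1] is Rhythm.SPONTANEOUS
                    ]
                    for key in order:
                        rec = recs[key]
                        if key[1] is Rhythm.PACED and not rec.captured:
                            continue
                        if len(rec.series) > 0:
                            return rec
                    return None

                # APD80 and rate correction
                apd_rec = pick(Channel.VOLTAGE, prefer_paced=True)
                if apd_rec is not None:
                    apd80 = apd_rec.series.aggregate("apd80_ms", cfg.apd_aggregate)
                    if apd_rec.meta.rhythm is Rhythm.PACED and apd_rec.captured:
                        rr = 1.0 / apd_rec.meta.pacing_frequency
                        source = "paced"
                    else:
                        rr = _mean_rr(apd_rec.series)
                        source = "spontaneous"
                    row["apd80_ms"] = apd80
                    row["rr_s"] = rr
                    row["apd80_source"] = source
                    row["apd80_corrected_ms"] = (
                        fridericia_correct(apd80, rr)
                        if not (math.isnan(apd80) or math.isnan(rr) or rr <= 0)
                        else math.nan
                    )
                else:
                    row.update(
                        apd80_ms=math.nan,
                        rr_s=math.nan,
                        apd80_source="none",
                        apd80_corrected_ms=math.nan,
                    )

                # triangulation from spontaneous voltage
                tri_rec = pick(Channel.VOLTAGE, prefer_paced=False)
                row["triangulation"] = (
                    _median_triangulation(tri_rec.series) if tri_rec else math.nan
                )

                # upstroke velocities from paced recordings
                v_rec = pick(Channel.VOLTAGE, prefer_paced=True)
                ca_rec = pick(Channel.CALCIUM, prefer_paced=True)
                row["v_max_upstroke"] = (
                    v_rec.series.aggregate("max_upstroke", cfg.apd_aggregate)
                    if v_rec
                    else math.nan
                )
                row["ca_max_upstroke"] = (
                    ca_rec.series.aggregate("max_upstroke", cfg.apd_aggregate)
                    if ca_rec
                    else math.nan
                )

                # classification trace: 30-s spontaneous calcium
                cls = recs.get((Channel.CALCIUM, Rhythm.SPONTANEOUS, 30.0))
                if cls is not None:
                    call = classify_tissue(cls.scaled, cls.series, 1.0, cfg)
                    row["beat_rate_hz"] = (
                        cls.series.beat_rate_hz if len(cls.series) >= 2 else math.nan
                    )
                    row["category"] = call.category.value
                    row["n_ead"] = sum(e.kind.value == "EAD" for e in call.events)
                    row["n_dad"] = sum(e.kind.value == "DAD" for e in call.events)
                    row["amplitude_vs_control"] = call.amplitude_vs_control
                    row["shape_irregularity"] = call.shape_irregularity
                    row["instability_index"] = call.instability_index
                    row["instability_flag"] = call.instability_flag
                    row["evaluable"] = call.category is not TissueCategory.WEAK_OR_SILENT
                    row["not_evaluable_reason"] = (
                        ""
                        if row["evaluable"]
                        else (
                            "no beating signal"
                            if call.n_beats == 0
                            else "weak signal (<60% of control amplitude)"
                        )
                    )
                    for ev in call.events:
                        event_rows.append(
                            {
                                "drug": arm.name,
                                "tissue_id": tissue,
                                "dose_index": d_idx,
                                "dose_uM": dose_total,
                                "kind": ev.kind.value,
                                "time_s": ev.time_s,
                                "relative_amplitude": ev.relative_amplitude,
                                "beat_index": ev.beat_index,
                            }
                        )
                else:
                    row.update(
                        beat_rate_hz=math.nan,
                        category="missing",
                        n_ead=0,
                        n_dad=0,
                        amplitude_vs_control=math.nan,
                        shape_irregularity=math.nan,
                        instability_index=math.nan,
                        instability_flag=False,
                        evaluable=False,
                        not_evaluable_reason="classification recording missing",
                    )
                rows_by_tissue[tissue].append(row)

        # --- inclusion on baseline APD80
        for tissue in arm_tissues:
            base_row = rows_by_tissue[tissue][0]
            baseline_apd[tissue] = base_row["apd80_ms"]
        included, excluded = inclusion_filter(baseline_apd, cfg.inclusion_apd80_ms)
        for tissue in arm_tissues:
            inclusion_rows.append(
                {
                    "drug": arm.name,
                    "tissue_id": tissue,
                    "baseline_apd80_ms": baseline_apd[tissue],
                    "included": tissue in included,
                    "reason": excluded.get(tissue, ""),
                }
            )

        arm_metrics = pd.DataFrame(
            [row for t in arm_tissues if t in included for row in rows_by_tissue[t]]
        )
        if arm_metrics.empty:
            continue
        arm_metrics = normalize_to_baseline(arm_metrics, ["apd80_corrected_ms"])
        metric_rows.extend(arm_metrics.to_dict("records"))

        # --- incidence and chi-squared over included tissues
        inc_calls: Dict[float, List[str]] = {}
        counts: Dict[float, Tuple[int, int]] = {}
        for d_idx in sorted({r["dose_index"] for r in arm_metrics.to_dict("records")}):
            cats = [
                r["category"]
                for r in arm_metrics.to_dict("records")
                if r["dose_index"] == d_idx and r["category"] != "missing"
            ]
            if not cats:
                continue
            inc_calls[totals[d_idx]] = cats
            counts[totals[d_idx]] = (
                sum(c == TissueCategory.ARRHYTHMIC.value for c in cats),
                len(cats),
            )
        if inc_calls:
            inc = cohort_incidence(inc_calls)
            inc.insert(0, "drug", arm.name)
            incidence_frames.append(inc)
        if len(counts) >= 2:
            chi = chi_square_pairwise(counts, correction=cfg.chi2_correction)
            chi.insert(0, "drug", arm.name)
            chi_rows.append(chi)

        # --- ANOVA + Dunnett per metric
        for metric in _STAT_METRICS:
            if metric not in arm_metrics.columns:
                continue
            groups = {}
            for d_idx, grp in arm_metrics.groupby("dose_index"):
                values = grp[metric].to_numpy(dtype=float)
                values = values[~np.isnan(values)]
                if values.size >= 2:
                    groups[int(d_idx)] = values
            if 0 not in groups or len(groups) < 2:
                continue
            result = anova_dunnett(groups, reference=0)
            for _, r in result.table.iterrows():
                anova_rows.append(
                    {
                        "drug": arm.name,
                        "metric": metric,
                        "dose_index": int(r["group"]),
                        "dose_uM": totals[int(r["group"])],
                        "n": int(r["n"]),
                        "mean": r["mean"],
                        "diff_vs_dose0": r["diff_vs_reference"],
                        "t": r["t"],
                        "p_adjusted": r["p_adjusted"],
                        "stars": r["stars"],
                        "anova_F": result.anova_f,
                        "anova_p": result.anova_p,
                    }
                )

    lod_result = None
    if panel is not None:
        lod_result = lod_filter(
            panel, cfg.lod_sd_multiplier, cfg.lod_min_detect_fraction
        )

    metrics_df = pd.DataFrame(metric_rows)
    report = StudyReport(
        metrics=metrics_df,
        events=pd.DataFrame(
            event_rows,
            columns=[
                "drug",
                "tissue_id",
                "dose_index",
                "dose_uM",
                "kind",
                "time_s",
                "relative_amplitude",
                "beat_index",
            ],
        ),
        incidence=(
            pd.concat(incidence_frames, ignore_index=True)
            if incidence_frames
            else pd.DataFrame()
        ),
        anova=pd.DataFrame(anova_rows),
        chi_square=(
            pd.concat(chi_rows, ignore_index=True) if chi_rows else pd.DataFrame()
        ),
        inclusion=pd.DataFrame(inclusion_rows),
        lod=lod_result,
        config=cfg,
        log={
            "package_version": _pkg_version,
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "n_recordings": len(traces),
        },
    )
    return report
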