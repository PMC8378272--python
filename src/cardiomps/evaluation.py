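"""End-to-end evaluation harnesses on synthetic data with known ground truth.

Each function regenerates its inputs from a seed, runs the package's own
analysis path, and reports summary numbers: APD80 recovery error, detector
operating characteristics, Dunnett family-wise error calibration,
limit-of-detection oracle agreement, dose-escalation parameter recovery,
and pipeline determinism.  The same harnesses back the acceptance test
suite and the reproduction script.
"""

from __future__ import annotations

import hashlib
import math
import tempfile
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .arrhythmia import detect_dads, detect_eads
from .beats import detrend, normalize, segment_beats
from .biomarkers import lod_filter
from .config import AnalysisConfig
from .design import DoseEscalationDesign, DrugArm
from .stats import anova_dunnett
from .study import run_study
from .synth import (
    BeatTemplateParams,
    EventSpec,
    SimConfig,
    hcq_like_model,
    simulate_biomarker_panel,
    simulate_cohort,
    simulate_trace,
)
from .traces import FluorescenceTrace

__all__ = [
    "apd_recovery",
    "detector_calibration",
    "dunnett_fwer",
    "lod_oracle_agreement",
    "brute_force_lod_retained",
    "hcq_study_recovery",
    "determinism_check",
]


# ---------------------------------------------------------------------------
# APD80 recovery

def apd_recovery(
    seed: int,
    n_beats: int = 100,
    noise_sd: float = 0.02,
    apd80_range: tuple = (200.0, 480.0),
    channel: str = "voltage",
) -> Dict[str, float]:
    """Recover APD80 on isolated synthetic beats with random targets.

    One beat per 3-s trace; targets uniform over ``apd80_range`` ms with
    triangulation uniform in [0.25, 0.5]; analysis runs the full
    detrend -> normalize -> segment path.
    """
    rng = np.random.default_rng(seed)
    errors: List[float] = []
    n_missed = 0
    for i in range(n_beats):
        apd80 = float(rng.uniform(*apd80_range))
        tri = float(rng.uniform(0.25, 0.5))
        params = BeatTemplateParams(
            channel=channel, apd30_ms=(1 - tri) * apd80, apd80_ms=apd80
        )
        cfg = SimConfig(
            seed=seed, noise_sd=noise_sd, spontaneous_rate_hz=0.4, rr_jitter=0.0
        )
        trace, _ = simulate_trace(
            params, cfg, rhythm="spontaneous", length_s=3.0, rng=rng
        )
        series = segment_beats(normalize(detrend(trace, "linear")))
        resolved = [b for b in series.beats if b.apd80_ms is not None]
        if len(resolved) != 1:
            n_missed += 1
            continue
        errors.append(resolved[0].apd80_ms - apd80)
    arr = np.abs(np.array(errors))
    return {
        "n": len(errors),
        "n_missed": n_missed,
        "median_abs_error_ms": float(np.median(arr)),
        "max_abs_error_ms": float(arr.max()),
        "bias_ms": float(np.mean(errors)),
    }


# ---------------------------------------------------------------------------
# EAD / DAD detector operating characteristics

def _event_detection(trace: FluorescenceTrace, cfg: AnalysisConfig):
    d = detrend(trace, "exponential", cfg.detrend_window_s)
    nz = normalize(d)
    series = segment_beats(
        nz, cfg.min_prominence, cfg.refractory_ms, cfg.smooth_samples
    )
    eads = detect_eads(
        nz, series, cfg.theta_ead, cfg.smooth_samples, cfg.event_min_width_samples
    )
    dads = detect_dads(
        nz,
        series,
        cfg.theta_dad,
        cfg.dad_beat_threshold,
        cfg.smooth_samples,
        cfg.event_min_width_samples,
    )
    return series, eads, dads


def detector_calibration(
    seed: int,
    n_event_traces: int = 200,
    n_clean_traces: int = 200,
    noise_sd: float = 0.02,
    amplitude_range: tuple = (0.10, 0.30),
    match_tol_s: float = 0.15,
) -> Dict[str, float]:
    """Sensitivity and false-positive rate of the afterdepolarization detectors.

    Event traces are 30-s spontaneous calcium recordings with three injected
    events each (half of the traces carry EADs, half DADs, amplitudes
    uniform over ``amplitude_range``); clean traces carry none.  A clean
    trace counts as a false positive when any event of either kind is
    reported.
    """
    rng = np.random.default_rng(seed)
    cfg = AnalysisConfig()
    hits = {"EAD": 0, "DAD": 0}
    totals = {"EAD": 0, "DAD": 0}
    for i in range(n_event_traces):
        kind = "EAD" if i % 2 == 0 else "DAD"
        sim_cfg = SimConfig(seed=seed, noise_sd=noise_sd, spontaneous_rate_hz=0.75)
        specs = [
            EventSpec(
                kind=kind,
                beat_index=b,
                amplitude_fraction=float(rng.uniform(*amplitude_range)),
                timing=float(rng.uniform(0.3, 0.5)),
            )
            for b in (2, 8, 14)
        ]
        trace, gt = simulate_trace(
            BeatTemplateParams(), sim_cfg, "spontaneous", specs, 30.0, rng=rng
        )
        _, eads, dads = _event_detection(trace, cfg)
        detected = eads if kind == "EAD" else dads
        for ev in gt.events:
            totals[kind] += 1
            if any(abs(e.time_s - ev["time_s"]) < match_tol_s for e in detected):
                hits[kind] += 1

    false_positives = 0
    for i in range(n_clean_traces):
        sim_cfg = SimConfig(seed=seed, noise_sd=noise_sd, spontaneous_rate_hz=0.75)
        trace, _ = simulate_trace(
            BeatTemplateParams(), sim_cfg, "spontaneous", [], 30.0, rng=rng
        )
        _, eads, dads = _event_detection(trace, cfg)
        if eads or dads:
            false_positives += 1

    return {
        "n_event_traces": n_event_traces,
        "n_clean_traces": n_clean_traces,
        "ead_sensitivity": hits["EAD"] / max(totals["EAD"], 1),
        "dad_sensitivity": hits["DAD"] / max(totals["DAD"], 1),
        "false_positive_rate": false_positives / max(n_clean_traces, 1),
    }


# ---------------------------------------------------------------------------
# Dunnett null calibration

def dunnett_fwer(
    seed: int,
    n_sims: int = 10000,
    k_groups: int = 5,
    n_per_group: int = 7,
    alpha: float = 0.05,
) -> Dict[str, float]:
    """Family-wise type-I error of the Dunnett procedure under the null.

    ``k_groups`` includes the dose-0 control; every simulation draws all
    groups from the same normal distribution and counts a family-wise error
    when any adjusted p-value falls below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    n_errors = 0
    for _ in range(n_sims):
        data = rng.standard_normal((k_groups, n_per_group))
        groups = {i: data[i] for i in range(k_groups)}
        result = anova_dunnett(groups, reference=0)
        if (result.table["p_adjusted"] < alpha).any():
            n_errors += 1
    return {
        "n_sims": n_sims,
        "alpha": alpha,
        "fwer": n_errors / n_sims,
    }


# ---------------------------------------------------------------------------
# limit-of-detection filter vs brute force

def brute_force_lod_retained(panel, sd_multiplier=3.0, min_detect=0.65) -> List[str]:
    """Deliberately naive re-implementation of the retention rule (oracle)."""
    retained = []
    for marker in panel.values.index:
        ctrl = [
            v for v in panel.negative_controls.loc[marker].tolist() if not math.isnan(v)
        ]
        mean = sum(ctrl) / len(ctrl)
        var = sum((v - mean) ** 2 for v in ctrl) / (len(ctrl) - 1)
        lod = mean + sd_multiplier * math.sqrt(var)
        values = [v for v in panel.values.loc[marker].tolist() if not math.isnan(v)]
        n_above = sum(1 for v in values if v > lod)
        if n_above / len(values) > min_detect:
            retained.append(marker)
    return retained


def lod_oracle_agreement(seed: int, n_panels: int = 50) -> Dict[str, float]:
    """Agreement of ``lod_filter`` with the brute-force rule on random panels."""
    rng = np.random.default_rng(seed)
    n_agree = 0
    for i in range(n_panels):
        n_markers = int(rng.integers(5, 30))
        n_samples = int(rng.integers(6, 40))
        fractions = rng.uniform(0.0, 1.0, n_markers)
        panel, _ = simulate_biomarker_panel(
            n_markers,
            n_samples,
            n_neg_controls=int(rng.integers(2, 8)),
            detect_fractions=fractions,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        mine = set(lod_filter(panel).retained)
        oracle = set(brute_force_lod_retained(panel))
        if mine == oracle:
            n_agree += 1
    return {"n_panels": n_panels, "n_agree": n_agree, "agreement": n_agree / n_panels}


# ---------------------------------------------------------------------------
# dose-escalation parameter recovery

def _predicted_apd_sd_ms(
    apd80_ms: float, apd30_ms: float, noise_sd: float, smooth: int, fps: float
) -> float:
    """Noise-propagated SD of one APD80 estimate.

    The APD80 crossing sits on the repolarization segment with slope
    ``0.5 A / (APD80 - APD30)`` per ms; additive noise of SD ``noise_sd``
    (boxcar-averaged over ``smooth`` samples) moves the interpolated
    crossing accordingly.  Frame quantization adds ``(1000/fps)/sqrt(12)``.
    """
    span = apd80_ms - apd30_ms
    slope_per_ms = 0.5 / span
    sigma_noise = noise_sd / math.sqrt(smooth) / slope_per_ms
    sigma_frame = (1000.0 / fps) / math.sqrt(12.0)
    return math.sqrt(sigma_noise**2 + sigma_frame**2)


def hcq_study_recovery(seed: int, n_tissues: int = 24) -> Dict[str, object]:
    """Run a full APD-prolonging (hERG-block-like) dose-escalation study and
    compare the recovered dose response with the generator's ground truth.

    Returns per-dose measured mean normalized APD80, the ground-truth means,
    a 95% noise-prediction band (measurement noise propagated through the
    per-tissue baseline ratio, plus a 1% discretization allowance), the
    arrhythmic-incidence curve, and the index of the first dose where the
    majority of tissues fell silent or weak.
    """
    design = DoseEscalationDesign(
        drugs=(DrugArm.single("HCQ", 1.0, (0, 0.1, 1, 10, 100, 1000)),),
        n_tissues=n_tissues,
    )
    model = hcq_like_model()
    sim_cfg = SimConfig(seed=seed)
    sim = simulate_cohort(design, {"HCQ": model}, sim_cfg)
    cfg = AnalysisConfig(seed=seed)
    report = run_study(design, sim.traces, config=cfg)

    gt = sim.tissue_dose.merge(
        sim.tissues[["tissue_id", "baseline_apd80_ms", "baseline_triangulation"]],
        on="tissue_id",
    )
    metrics = report.metrics.merge(
        gt, on=["tissue_id", "dose_index"], suffixes=("", "_gt")
    )

    doses = sorted(metrics["dose_index"].unique())
    measured_means, truth_means, bands, arr_frac, weak_frac = [], [], [], [], []
    for d in doses:
        sub = metrics[metrics["dose_index"] == d]
        ok = sub[~sub["apd80_corrected_ms_norm"].isna() & ~sub["silent"]]
        inc = report.incidence[report.incidence["dose"] == sub["dose_uM"].iloc[0]]
        arr_frac.append(float(inc["arrhythmic"].iloc[0]) if not inc.empty else math.nan)
        weak_frac.append(
            float(inc["weak_or_silent"].iloc[0]) if not inc.empty else math.nan
        )
        if len(ok) < 2:
            measured_means.append(math.nan)
            truth_means.append(math.nan)
            bands.append(math.nan)
            continue
        measured_means.append(float(ok["apd80_corrected_ms_norm"].mean()))
        truth_means.append(float(ok["apd_multiplier_realized"].mean()))
        # noise-predicted SD of the per-tissue ratio, averaged over tissues
        sds = []
        for _, row in ok.iterrows():
            s_d = _predicted_apd_sd_ms(
                row["apd80_ms_gt"],
                (1 - row["triangulation_gt"]) * row["apd80_ms_gt"],
                sim_cfg.noise_sd,
                cfg.smooth_samples,
                sim_cfg.fps,
            )
            base30 = (1 - row["baseline_triangulation"]) * row["baseline_apd80_ms"]
            s_0 = _predicted_apd_sd_ms(
                row["baseline_apd80_ms"], base30, sim_cfg.noise_sd,
                cfg.smooth_samples, sim_cfg.fps,
            )
            m = row["apd_multiplier_realized"]
            sds.append(
                math.sqrt(s_d**2 + (m * s_0) ** 2) / row["baseline_apd80_ms"]
            )
        band = 1.96 * float(np.mean(sds)) / math.sqrt(len(ok)) + 0.01
        bands.append(band)

    # first dose where most tissues are weak/silent ends the evaluable range
    silent_from = next(
        (i for i, w in enumerate(weak_frac) if not math.isnan(w) and w > 0.5),
        len(doses),
    )
    deviations = [
        abs(m - t)
        for m, t, b in zip(measured_means[:silent_from], truth_means[:silent_from], bands[:silent_from])
        if not math.isnan(m)
    ]
    within = [
        abs(m - t) <= b
        for m, t, b in zip(measured_means[:silent_from], truth_means[:silent_from], bands[:silent_from])
        if not math.isnan(m)
    ]
    arr_curve = [a for a in arr_frac[:silent_from] if not math.isnan(a)]
    monotone = all(b >= a - 1e-12 for a, b in zip(arr_curve, arr_curve[1:]))

    return {
        "n_tissues": n_tissues,
        "doses_uM": [float(metrics[metrics["dose_index"] == d]["dose_uM"].iloc[0]) for d in doses],
        "measured_apd80_norm": measured_means,
        "truth_apd80_norm": truth_means,
        "band_95": bands,
        "max_abs_deviation": max(deviations) if deviations else math.nan,
        "all_within_band": bool(all(within)) if within else False,
        "arrhythmic_fraction": arr_frac,
        "weak_fraction": weak_frac,
        "silent_from_dose_index": silent_from,
        "incidence_monotone": bool(monotone),
    }


# ---------------------------------------------------------------------------
# determinism

def _hash_dir(path: Path) -> str:
    digest = hashlib.sha256()
    for f in sorted(Path(path).rglob("*")):
        if f.is_file():
            digest.update(f.name.encode())
            digest.update(f.read_bytes())
    return digest.hexdigest()


def determinism_check(seed: int) -> Dict[str, object]:
    """Simulate + analyze a small cohort twice with one seed; compare bytes."""
    design = DoseEscalationDesign(
        drugs=(DrugArm.single("HCQ", 1.0, (0, 1, 10)),), n_tissues=4
    )
    model = {"HCQ": hcq_like_model()}
    hashes = []
    with tempfile.TemporaryDirectory() as tmp:
        for run in ("a", "b"):
            sim = simulate_cohort(design, model, SimConfig(seed=seed))
            out = Path(tmp) / run
            sim.write_dir(out / "sim")
            report = run_study(design, sim.traces, config=AnalysisConfig(seed=seed))
            report.to_dir(out / "analysis")
            hashes.append(_hash_dir(out))
    return {"identical": hashes[0] == hashes[1], "sha256": hashes[0]}
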