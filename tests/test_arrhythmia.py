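import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomps import (
    AnalysisConfig,
    Beat,
    TissueCategory,
    classify_tissue,
    cohort_incidence,
    detect_dads,
    detect_eads,
    detrend,
    instability_index,
    normalize,
    poincare_pairs,
    segment_beats,
    shape_irregularity,
)
from cardiomps.beats import BeatSeries
from cardiomps.synth import BeatTemplateParams, SimConfig, simulate_trace


def _analyzed(events=(), seed=0, noise=0.02, length=30.0, **sim_kwargs):
    cfg = SimConfig(seed=seed, noise_sd=noise, spontaneous_rate_hz=0.75, **sim_kwargs)
    trace, gt = simulate_trace(
        BeatTemplateParams(), cfg, "spontaneous", events, length,
        rng=np.random.default_rng(seed + 7000),
    )
    nz = normalize(detrend(trace, "exponential"))
    series = segment_beats(nz)
    return nz, series, gt


class TestDetectEads:
    def test_single_injected_ead(self):
        nz, series, gt = _analyzed([dict(kind="EAD", beat_index=5, amplitude_fraction=0.15)])
        events = detect_eads(nz, series)
        assert len(events) == 1
        assert events[0].relative_amplitude == pytest.approx(0.15, abs=0.03)
        assert abs(events[0].time_s - gt.events[0]["time_s"]) < 0.1

    def test_clean_monotone_beats_have_no_events(self):
        nz, series, _ = _analyzed([])
        assert detect_eads(nz, series) == []

    def test_two_eads_ordered_by_time(self):
        nz, series, gt = _analyzed(
            [
                dict(kind="EAD", beat_index=3, amplitude_fraction=0.10),
                dict(kind="EAD", beat_index=9, amplitude_fraction=0.20),
            ]
        )
        events = detect_eads(nz, series)
        assert len(events) == 2
        assert events[0].time_s < events[1].time_s
        # single-sample noise at 100 frames/s limits per-event amplitude precision
        assert events[0].relative_amplitude == pytest.approx(0.10, abs=0.06)
        assert events[1].relative_amplitude == pytest.approx(0.20, abs=0.06)

    def test_event_lies_in_phase3_window(self):
        nz, series, _ = _analyzed([dict(kind="EAD", beat_index=5, amplitude_fraction=0.2)])
        ev = detect_eads(nz, series)[0]
        beat = series.beats[ev.beat_index]
        assert beat.peak_time_s < ev.time_s
        assert ev.time_s <= beat.activation_time_s + beat.apd90_ms / 1000.0 + 0.02


class TestDetectDads:
    def test_single_injected_dad(self):
        nz, series, gt = _analyzed([dict(kind="DAD", beat_index=6, amplitude_fraction=0.25)])
        events = detect_dads(nz, series)
        assert len(events) == 1
        assert events[0].relative_amplitude == pytest.approx(0.25, abs=0.05)

    def test_quiescent_diastole_has_no_events(self):
        nz, series, _ = _analyzed([])
        assert detect_dads(nz, series) == []

    def test_large_deflection_is_a_beat_not_a_dad(self):
        nz, series, gt = _analyzed(
            [dict(kind="DAD", beat_index=6, amplitude_fraction=0.80)], noise=0.0,
            bleach_per_s=0.0, rr_jitter=0.0,
        )
        # the 80% deflection is segmented as an extra beat...
        assert len(series) == len(gt.beats) + 1
        # ...and therefore not reported as a DAD
        assert detect_dads(nz, series) == []


def _series_with(amplitudes, apd50=200.0):
    beats = []
    for i, a in enumerate(amplitudes):
        beats.append(
            Beat(
                activation_time_s=float(i),
                peak_time_s=i + 0.05,
                baseline_value=0.0,
                amplitude=float(a),
                max_upstroke=10.0,
                apd30_ms=apd50 * 0.8,
                apd50_ms=apd50,
                apd80_ms=apd50 * 1.5,
                apd90_ms=apd50 * 1.6,
            )
        )
    return BeatSeries.from_beats(beats)


class TestShapeIrregularity:
    def test_identical_beats_below_noise_floor(self):
        nz, series, _ = _analyzed([], noise=0.0, bleach_per_s=0.0, rr_jitter=0.0)
        assert shape_irregularity(series) < 0.02

    def test_alternating_amplitude_closed_form(self):
        series = _series_with([1.0, 0.5] * 4)
        # population CV of {1.0, 0.5}: sd 0.25, mean 0.75 -> 1/3
        assert shape_irregularity(series) == pytest.approx(1 / 3, abs=0.01)

    def test_tdp_like_modulation_flags(self):
        # amplitude and APD alternating by +/-40%: configuration change
        cfg = SimConfig(seed=2, noise_sd=0.02, spontaneous_rate_hz=0.75)
        trace, _ = simulate_trace(
            BeatTemplateParams(), cfg, "spontaneous", [], 30.0,
            alternans_eps=0.4, rng=np.random.default_rng(2),
        )
        series = segment_beats(normalize(detrend(trace, "exponential")))
        assert shape_irregularity(series) > 0.2

    def test_too_few_beats_not_evaluable(self):
        series = _series_with([1.0, 1.0, 1.0])
        assert math.isnan(shape_irregularity(series))


class TestPoincare:
    def test_constant_sequence(self):
        pairs = poincare_pairs([300.0, 300.0, 300.0, 300.0])
        assert np.allclose(pairs.pairs, 1.0)
        index, unstable = instability_index(pairs)
        assert index == 0.0
        assert not unstable

    def test_alternating_sequence_pairs(self):
        pairs = poincare_pairs([300.0, 360.0, 300.0, 360.0])  # mean 330
        lo, hi = 300 / 330, 360 / 330
        assert pairs.pairs == pytest.approx(
            np.array([[lo, hi], [hi, lo], [lo, hi]])
        )

    def test_alternans_closed_form(self):
        eps = 0.1
        seq = [350 * (1 + eps * (-1) ** i) for i in range(20)]
        index, unstable = instability_index(poincare_pairs(seq))
        assert index == pytest.approx(eps * math.sqrt(2), abs=0.005)
        assert unstable

    def test_iid_jitter_stable(self):
        rng = np.random.default_rng(0)
        seq = rng.normal(300.0, 3.0, 300)  # sigma/mean = 0.01
        index, unstable = instability_index(poincare_pairs(seq))
        assert index == pytest.approx(0.01, abs=0.003)
        assert not unstable

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(100.0, 600.0), min_size=3, max_size=30), st.floats(0.5, 3.0))
    def test_scale_invariance_and_brute_force(self, seq, scale):
        pairs = poincare_pairs(seq)
        # brute force: index-shifted zip, normalized by the mean
        mean = sum(seq) / len(seq)
        expected = np.array([(a / mean, b / mean) for a, b in zip(seq, seq[1:])])
        assert pairs.pairs == pytest.approx(expected, rel=1e-12)
        i1, _ = instability_index(pairs)
        i2, _ = instability_index(poincare_pairs([scale * v for v in seq]))
        assert i1 == pytest.approx(i2, rel=1e-9, abs=1e-12)

    def test_too_short_sequence(self):
        with pytest.raises(ValueError):
            poincare_pairs([300.0, 310.0])


class TestClassifyTissue:
    def _normal_recording(self, **kwargs):
        return _analyzed([], **kwargs)

    def test_no_beats_is_weak_or_silent(self):
        rng = np.random.default_rng(1)
        from cardiomps import FluorescenceTrace

        trace = FluorescenceTrace(rng.normal(0, 0.02, 3000))
        series = segment_beats(trace)
        call = classify_tissue(trace, series, control_amplitude=1.0)
        assert call.category is TissueCategory.WEAK_OR_SILENT
        assert call.amplitude_vs_control == 0.0

    @pytest.mark.parametrize("ratio,expected", [
        (0.59, TissueCategory.WEAK_OR_SILENT),
        (0.61, TissueCategory.NORMAL),
    ])
    def test_60_percent_amplitude_boundary(self, ratio, expected):
        nz, series, _ = self._normal_recording()
        max_amp = max(b.amplitude for b in series.beats)
        call = classify_tissue(nz, series, control_amplitude=max_amp / ratio)
        assert call.category is expected
        assert call.amplitude_vs_control == pytest.approx(ratio, rel=1e-9)

    def test_ead_with_healthy_amplitude_is_arrhythmic(self):
        nz, series, _ = _analyzed([dict(kind="EAD", beat_index=5, amplitude_fraction=0.2)])
        max_amp = max(b.amplitude for b in series.beats)
        call = classify_tissue(nz, series, control_amplitude=max_amp / 0.9)
        assert call.category is TissueCategory.ARRHYTHMIC
        assert len(call.events) == 1

    def test_weak_takes_precedence_over_arrhythmic(self):
        nz, series, _ = _analyzed([dict(kind="EAD", beat_index=5, amplitude_fraction=0.2)])
        max_amp = max(b.amplitude for b in series.beats)
        call = classify_tissue(nz, series, control_amplitude=max_amp / 0.5)
        assert call.category is TissueCategory.WEAK_OR_SILENT

    def test_missing_control_errors(self):
        nz, series, _ = self._normal_recording()
        with pytest.raises(ValueError):
            classify_tissue(nz, series, control_amplitude=0.0)


class TestCohortIncidence:
    def test_counting(self):
        calls = {
            1.0: ["arrhythmic", "normal", "normal", "weak_or_silent"],
        }
        inc = cohort_incidence(calls)
        row = inc.iloc[0]
        assert row["arrhythmic_pct"] == 25.0
        assert row["weak_or_silent_pct"] == 25.0
        assert row["normal_pct"] == 50.0

    def test_all_normal(self):
        inc = cohort_incidence({0.0: ["normal"] * 5})
        assert inc.iloc[0]["normal"] == 1.0
        assert inc.iloc[0]["arrhythmic"] == 0.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        cats = ["normal", "arrhythmic", "weak_or_silent"]
        calls = {d: [cats[i] for i in rng.integers(0, 3, 9)] for d in range(4)}
        inc = cohort_incidence(calls)
        sums = inc["normal"] + inc["arrhythmic"] + inc["weak_or_silent"]
        assert np.allclose(sums, 1.0)

    def test_binomial_cohort_recovery(self):
        # p = 0.5, n = 200: estimate within the exact binomial 95% CI of 0.5
        rng = np.random.default_rng(42)
        draws = rng.random(200) < 0.5
        calls = {1.0: ["arrhythmic" if d else "normal" for d in draws]}
        frac = cohort_incidence(calls).iloc[0]["arrhythmic"]
        from scipy.stats import binom

        lo, hi = binom.ppf([0.025, 0.975], 200, 0.5) / 200
        assert lo <= frac <= hi

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            cohort_incidence({1.0: []})
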