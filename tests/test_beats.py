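import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomps import (
    Beat,
    FluorescenceTrace,
    apd,
    capture_check,
    detrend,
    fridericia_correct,
    max_upstroke_velocity,
    normalize,
    segment_beats,
    triangulation,
)
from cardiomps.beats import BeatSeries
from cardiomps.synth import BeatTemplateParams, SimConfig, simulate_trace


def _beat_at(trace, act_idx, amplitude=1.0, baseline=0.0, end=None):
    """Hand-built Beat for traces constructed without the segmenter."""
    fs = trace.sampling_rate
    return Beat(
        activation_time_s=trace.t0 + act_idx / fs,
        peak_time_s=trace.t0 + act_idx / fs,
        baseline_value=baseline,
        amplitude=amplitude,
        max_upstroke=1.0,
        activation_index=act_idx,
        peak_index=act_idx,
        window_end_index=end if end is not None else trace.n - 1,
    )


class TestDetrend:
    def test_linear_drift_removed(self):
        t = np.arange(600) / 100.0
        k = 5.0  # units per second
        trace = FluorescenceTrace(100.0 + k * t)
        out = detrend(trace, "linear")
        residual_slope = np.polyfit(t, out.samples, 1)[0]
        assert abs(residual_slope) < 0.01 * k

    def test_exponential_decay_removed(self):
        t = np.arange(1500) / 100.0
        x = 80.0 * np.exp(-0.1 * t) + 20.0
        trace = FluorescenceTrace(x)
        out = detrend(trace, "exponential")
        assert np.ptp(out.samples) < 0.01 * np.ptp(x)

    def test_drift_free_train_unchanged(self):
        cfg = SimConfig(noise_sd=0.0, bleach_per_s=0.0, spontaneous_rate_hz=1.0, rr_jitter=0.0)
        trace, _ = simulate_trace(BeatTemplateParams(), cfg, "spontaneous", length_s=10.0)
        out = detrend(trace, "linear")
        amplitude = 50.0  # beat_scale
        assert np.max(np.abs(out.samples - trace.samples)) < 0.01 * amplitude

    def test_window_too_long(self):
        trace = FluorescenceTrace(np.arange(100, dtype=float), sampling_rate=100.0)
        with pytest.raises(ValueError):
            detrend(trace, "linear", window_s=2.0)


class TestNormalize:
    def test_affine_map(self):
        out = normalize(FluorescenceTrace(np.array([2.0, 4.0, 6.0])))
        assert np.allclose(out.samples, [0.0, 0.5, 1.0])

    def test_idempotent(self):
        tr = FluorescenceTrace(np.linspace(0, 1, 50))
        assert np.allclose(normalize(tr).samples, tr.samples)

    def test_constant_trace_errors(self):
        with pytest.raises(ValueError):
            normalize(FluorescenceTrace(np.ones(10)))


class TestSegmentBeats:
    def test_regular_train_counts_and_rr(self):
        cfg = SimConfig(seed=5, noise_sd=0.02, spontaneous_rate_hz=1.0, rr_jitter=0.0)
        trace, gt = simulate_trace(
            BeatTemplateParams(), cfg, "spontaneous", length_s=6.5,
            rng=np.random.default_rng(5),
        )
        series = segment_beats(normalize(trace))
        assert len(series) == len(gt.beats) == 6
        assert np.allclose(series.rr_intervals_s, 1.0, atol=0.01)
        assert series.beat_rate_hz == pytest.approx(1.0, abs=0.01)

    def test_noise_only_trace_has_no_beats(self):
        rng = np.random.default_rng(3)
        trace = FluorescenceTrace(rng.normal(0.0, 0.02, 3000))
        series = segment_beats(trace, min_prominence=0.3)
        assert len(series) == 0

    def test_dad_not_counted_as_beat(self):
        cfg = SimConfig(noise_sd=0.0, bleach_per_s=0.0, spontaneous_rate_hz=1.0, rr_jitter=0.0)
        trace, gt = simulate_trace(
            BeatTemplateParams(), cfg, "spontaneous",
            events=[dict(kind="DAD", beat_index=2, amplitude_fraction=0.10)],
            length_s=6.5,
        )
        series = segment_beats(normalize(trace), min_prominence=0.3)
        assert len(series) == len(gt.beats)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_count_matches_generator(self, seed):
        """Segmentation count equals the generator's beat count (noise <= 0.05)."""
        rng = np.random.default_rng(seed)
        noise = float(rng.uniform(0.0, 0.05))
        cfg = SimConfig(seed=seed, noise_sd=noise, spontaneous_rate_hz=1.0, rr_jitter=0.0)
        trace, gt = simulate_trace(
            BeatTemplateParams(), cfg, "spontaneous", length_s=6.5, rng=rng
        )
        series = segment_beats(normalize(trace), min_prominence=0.3)
        assert len(series) == len(gt.beats)


class TestApd:
    def _linear_decay_trace(self, decay_ms=400, fs=100.0):
        # instant upstroke to 1 at sample 50, then linear decay to 0
        n_decay = int(decay_ms / 1000.0 * fs)
        x = np.concatenate(
            [np.zeros(50), 1.0 - np.arange(n_decay + 1) / n_decay, np.zeros(50)]
        )
        return FluorescenceTrace(x, sampling_rate=fs)

    def test_linear_decay_geometry(self):
        trace = self._linear_decay_trace()
        beat = _beat_at(trace, 50)
        assert apd(trace, beat, 0.3) == pytest.approx(120.0, abs=1.0)
        assert apd(trace, beat, 0.8) == pytest.approx(320.0, abs=1.0)

    def test_square_pulse(self):
        w_ms = 200
        x = np.concatenate([np.zeros(50), np.ones(int(w_ms / 10)), np.zeros(50)])
        trace = FluorescenceTrace(x, sampling_rate=100.0)
        beat = _beat_at(trace, 50)
        a30 = apd(trace, beat, 0.3)
        a80 = apd(trace, beat, 0.8)
        assert a30 == pytest.approx(w_ms, abs=11.0)  # one-sample interpolation
        assert a80 == pytest.approx(w_ms, abs=11.0)
        assert a30 <= a80

    def test_generator_beat_recovery(self):
        params = BeatTemplateParams(channel="voltage", apd30_ms=227.5, apd80_ms=350.0)
        cfg = SimConfig(seed=1, noise_sd=0.02, spontaneous_rate_hz=0.5, rr_jitter=0.0)
        trace, _ = simulate_trace(params, cfg, "spontaneous", length_s=4.0,
                                  rng=np.random.default_rng(1))
        series = segment_beats(normalize(detrend(trace, "linear")))
        for b in series.beats:
            assert b.apd80_ms == pytest.approx(350.0, abs=10.0)

    def test_monotone_in_fraction(self):
        trace = self._linear_decay_trace()
        beat = _beat_at(trace, 50)
        values = [apd(trace, beat, r) for r in (0.1, 0.3, 0.5, 0.8, 0.9)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_unresolved_apd_is_none(self):
        # signal never repolarizes below the threshold: step that stays high
        x = np.concatenate([np.zeros(50), np.ones(200)])
        trace = FluorescenceTrace(x, sampling_rate=100.0)
        beat = _beat_at(trace, 50)
        assert apd(trace, beat, 0.8) is None

    def test_invalid_fraction(self):
        trace = self._linear_decay_trace()
        with pytest.raises(ValueError):
            apd(trace, _beat_at(trace, 50), 1.0)


class TestMaxUpstroke:
    def test_linear_ramp(self):
        # 0 -> 1 over 50 ms at 100 Hz: slope 20 /s
        x = np.concatenate([np.zeros(50), np.linspace(0, 1, 6), np.ones(30) - np.arange(30) / 60.0])
        trace = FluorescenceTrace(x, sampling_rate=100.0)
        beat = _beat_at(trace, 50)
        beat.peak_index = 55
        beat.peak_time_s = 0.55
        assert max_upstroke_velocity(trace, beat) == pytest.approx(20.0, rel=1e-6)

    def test_half_sine_upstroke(self):
        # half sine over 200 ms, amplitude 1: max slope = pi / 0.2 / 2
        fs = 100.0
        t_up = np.arange(0, 0.2 + 1e-9, 1 / fs)
        up = 0.5 * (1 - np.cos(np.pi * t_up / 0.2))
        x = np.concatenate([np.zeros(50), up, np.ones(20), np.zeros(1)])
        trace = FluorescenceTrace(x, sampling_rate=fs)
        beat = _beat_at(trace, 55)
        beat.peak_index = 70
        beat.peak_time_s = 0.70
        expected = math.pi / 0.2 / 2.0  # ~15.71 /s
        assert max_upstroke_velocity(trace, beat) == pytest.approx(expected, rel=0.05)

    def test_calcium_slower_than_voltage(self):
        cfg = SimConfig(noise_sd=0.0, bleach_per_s=0.0, spontaneous_rate_hz=0.5, rr_jitter=0.0)
        out = {}
        for ch in ("voltage", "calcium"):
            trace, _ = simulate_trace(
                BeatTemplateParams(channel=ch, apd30_ms=230, apd80_ms=350),
                cfg, "spontaneous", length_s=4.0,
            )
            series = segment_beats(normalize(trace))
            out[ch] = series.beats[0].max_upstroke
        assert out["calcium"] < out["voltage"]


class TestFridericia:
    @pytest.mark.parametrize(
        "apd_ms,rr_s,expected",
        [(300.0, 1.0, 300.0), (300.0, 8.0, 150.0), (300.0, 0.512, 375.0)],
    )
    def test_closed_form(self, apd_ms, rr_s, expected):
        assert fridericia_correct(apd_ms, rr_s) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(100.0, 600.0),
        st.floats(0.3, 3.0),
        st.floats(0.5, 2.0),
    )
    def test_scaling_property(self, a, rr, c):
        """f(a, c^3 r) = f(a, r) / c."""
        assert fridericia_correct(a, c**3 * rr) == pytest.approx(
            fridericia_correct(a, rr) / c, rel=1e-9
        )

    def test_nonpositive_rr_errors(self):
        with pytest.raises(ValueError):
            fridericia_correct(300.0, 0.0)


class TestTriangulation:
    def test_degenerate_square_beat(self):
        assert triangulation(320.0, 320.0) == 0.0

    def test_linear_decay_value(self):
        assert triangulation(120.0, 320.0) == pytest.approx(0.625, rel=1e-12)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            triangulation(330.0, 320.0)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(1.0, 500.0), st.floats(0.0, 400.0))
    def test_bounds_and_formula(self, apd30, extra):
        apd80 = apd30 + extra
        v = triangulation(apd30, apd80)
        assert 0.0 <= v < 1.0
        assert v == pytest.approx((apd80 - apd30) / apd80, rel=1e-12)

    def test_generator_target_recovered(self):
        apd80, tri = 350.0, 0.4
        params = BeatTemplateParams(apd30_ms=(1 - tri) * apd80, apd80_ms=apd80)
        cfg = SimConfig(seed=2, noise_sd=0.02, spontaneous_rate_hz=0.75, rr_jitter=0.0)
        trace, _ = simulate_trace(params, cfg, "spontaneous", length_s=10.0,
                                  rng=np.random.default_rng(2))
        series = segment_beats(normalize(detrend(trace, "exponential")))
        values = [
            triangulation(b.apd30_ms, b.apd80_ms)
            for b in series.beats
            if b.apd80_ms is not None
        ]
        assert np.median(values) == pytest.approx(tri, abs=0.05)


class TestCaptureCheck:
    def _series(self, activation_times):
        beats = [
            Beat(
                activation_time_s=t,
                peak_time_s=t + 0.05,
                baseline_value=0.0,
                amplitude=1.0,
                max_upstroke=10.0,
            )
            for t in activation_times
        ]
        return BeatSeries.from_beats(beats)

    def test_exact_capture(self):
        series = self._series(np.arange(10) * 1.0)
        assert capture_check(series, 1.0, tol=0.05) is True

    def test_rate_mismatch(self):
        series = self._series(np.arange(10) * 0.667)  # 2:3 pattern vs 1 Hz
        assert capture_check(series, 1.0, tol=0.05) is False

    def test_two_to_one_block(self):
        series = self._series(np.arange(6) * 2.0)  # beats every 2 s under 1 Hz pacing
        assert capture_check(series, 1.0, tol=0.05) is False

    def test_too_few_beats(self):
        series = self._series([0.0, 1.0])
        assert capture_check(series, 1.0) is False
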