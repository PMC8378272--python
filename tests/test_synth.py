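import numpy as np
import pytest
from scipy.stats import norm

from cardiomps.design import DoseEscalationDesign, DrugArm, DrugComponent, table1_design
from cardiomps.synth import (
    BASELINE_APD80_MEAN,
    BASELINE_APD80_RANGE,
    BASELINE_APD80_SD,
    BeatTemplateParams,
    SimConfig,
    _truncated_normal,
    azm_like_model,
    hcq_like_model,
    make_beat_template,
    simulate_cohort,
    simulate_trace,
)


class TestBeatTemplate:
    def test_analytic_apd_equals_targets(self):
        tpl = make_beat_template(BeatTemplateParams(apd30_ms=120, apd80_ms=320))
        assert tpl.apd(0.3) == pytest.approx(120.0, rel=1e-12)
        assert tpl.apd(0.8) == pytest.approx(320.0, rel=1e-12)
        assert tpl.apd(0.9) == pytest.approx(320 + 0.25 * 200, rel=1e-12)

    def test_plateau_beat_triangulation(self):
        p = BeatTemplateParams(apd30_ms=0.9 * 320, apd80_ms=320)
        assert p.plateau
        assert p.triangulation == pytest.approx(0.1)

    def test_sampled_waveform_crosses_levels_at_targets(self):
        tpl = make_beat_template(BeatTemplateParams(apd30_ms=230, apd80_ms=350))
        taus = np.array([230.0, 350.0])
        assert tpl.value(taus) == pytest.approx([0.7, 0.2], rel=1e-12)

    def test_calcium_upstroke_slower(self):
        v = make_beat_template(BeatTemplateParams(channel="voltage", apd30_ms=230, apd80_ms=350))
        c = make_beat_template(BeatTemplateParams(channel="calcium", apd30_ms=230, apd80_ms=350))
        assert c.max_upstroke_per_s < v.max_upstroke_per_s

    def test_invalid_apd_order_errors(self):
        with pytest.raises(ValueError):
            BeatTemplateParams(apd30_ms=350, apd80_ms=350)


class TestSimulateTrace:
    def test_noise_free_beat_count_and_recovery(self, clean_train):
        from cardiomps import normalize, segment_beats

        trace, gt = clean_train
        assert len(gt.beats) == 30
        series = segment_beats(normalize(trace))
        assert len(series) == 30
        est = np.array([b.apd80_ms for b in series.beats])
        assert np.max(np.abs(est - 350.0)) <= 1.0  # interpolation error only

    def test_event_bookkeeping(self):
        events = [
            dict(kind="EAD", beat_index=2, amplitude_fraction=0.15),
            dict(kind="DAD", beat_index=5, amplitude_fraction=0.2),
            dict(kind="EAD", beat_index=8, amplitude_fraction=0.1),
        ]
        cfg = SimConfig(seed=0)
        _, gt = simulate_trace(BeatTemplateParams(), cfg, "spontaneous", events, 30.0)
        assert len(gt.events) == len(events)
        kinds = sorted(e["kind"] for e in gt.events)
        assert kinds == ["DAD", "EAD", "EAD"]

    def test_silent_trace_has_no_beats(self):
        from cardiomps import detrend, segment_beats

        cfg = SimConfig(seed=0, noise_sd=0.02)
        trace, gt = simulate_trace(BeatTemplateParams(), cfg, "spontaneous", [], 30.0, silent=True)
        assert gt.beats == []
        flat = detrend(trace, "exponential")
        # noise plus removed bleaching drift only; nothing beat-sized remains
        assert np.ptp(flat.samples) < 10 * 0.02 * cfg.beat_scale
        assert len(segment_beats(flat.with_samples(flat.samples / cfg.beat_scale))) == 0

    def test_overlapping_beats_error(self):
        cfg = SimConfig(pacing_frequency_hz=2.0)  # 500 ms period
        with pytest.raises(ValueError, match="overlap"):
            simulate_trace(
                BeatTemplateParams(apd30_ms=400, apd80_ms=600), cfg, "paced", [], 10.0
            )

    def test_alternans_ground_truth(self):
        cfg = SimConfig(noise_sd=0.0, bleach_per_s=0.0, spontaneous_rate_hz=1.0, rr_jitter=0.0)
        _, gt = simulate_trace(
            BeatTemplateParams(apd30_ms=160, apd80_ms=250), cfg, "spontaneous",
            [], 10.0, alternans_eps=0.1,
        )
        apds = np.array([b["apd80_ms"] for b in gt.beats])
        assert apds[0] == pytest.approx(250 * 1.1)
        assert apds[1] == pytest.approx(250 * 0.9)

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(seed=9, noise_sd=0.02)
        t1, _ = simulate_trace(BeatTemplateParams(), cfg, "spontaneous", [], 10.0)
        t2, _ = simulate_trace(BeatTemplateParams(), cfg, "spontaneous", [], 10.0)
        assert np.array_equal(t1.samples, t2.samples)


class TestDesign:
    def test_table1_ladders_resolved_to_uM(self):
        design = table1_design()
        hcq, azm, combo = design.drugs
        assert hcq.total_uM == (0, 0.1, 1, 10, 100, 1000)
        assert azm.total_uM == pytest.approx((0, 0.067, 0.67, 6.7, 67))
        # polytherapy arm: HCQ held at Cmax while AZM escalates
        hcq_c = combo.components[0].doses_uM
        azm_c = combo.components[1].doses_uM
        assert hcq_c == (0, 1, 1, 1, 1, 1, 1)
        assert azm_c == pytest.approx((0, 0, 0.067, 0.201, 0.67, 2.01, 6.7))

    def test_ladder_must_start_at_zero(self):
        with pytest.raises(ValueError, match="start at 0"):
            DrugArm.single("X", 1.0, (0.1, 1, 10))

    def test_ladder_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            DrugArm.single("X", 1.0, (0, 10, 1))

    def test_yaml_round_trip(self, tmp_path):
        from cardiomps.design import load_design, save_design

        design = table1_design()
        save_design(design, tmp_path / "d.yaml")
        back = load_design(tmp_path / "d.yaml")
        assert back == design


@pytest.fixture(scope="module")
def small_sim():
    design = DoseEscalationDesign(
        drugs=(DrugArm.single("HCQ", 1.0, (0, 1, 10)),), n_tissues=4
    )
    return simulate_cohort(design, {"HCQ": hcq_like_model()}, SimConfig(seed=2))


class TestSimulateCohort:
    def test_protocol_coverage(self, small_sim):
        # 4 tissues x 3 doses x 5 recordings
        assert len(small_sim.traces) == 4 * 3 * 5

    def test_dose0_multiplier_is_one(self, small_sim):
        gt = small_sim.tissue_dose
        base = gt[gt["dose_index"] == 0]
        assert (base["apd_multiplier_realized"] == 1.0).all()

    def test_effect_monotone_in_dose(self, small_sim):
        for _, grp in small_sim.tissue_dose.groupby("tissue_id"):
            m = grp.sort_values("dose_index")["apd_multiplier_realized"].to_numpy()
            assert np.all(np.diff(m) >= -1e-12)

    def test_determinism(self):
        design = DoseEscalationDesign(
            drugs=(DrugArm.single("HCQ", 1.0, (0, 1)),), n_tissues=2
        )
        sims = [
            simulate_cohort(design, {"HCQ": hcq_like_model()}, SimConfig(seed=5))
            for _ in range(2)
        ]
        for (m1, t1), (m2, t2) in zip(sims[0].traces, sims[1].traces):
            assert m1 == m2
            assert np.array_equal(t1.samples, t2.samples)

    def test_event_bookkeeping_matches_ground_truth(self, small_sim):
        gt = small_sim.tissue_dose
        ev = small_sim.events
        flagged = gt[gt["has_ead"] & ~gt["silent"]]
        for _, row in flagged.iterrows():
            n = len(
                ev[
                    (ev["tissue_id"] == row["tissue_id"])
                    & (ev["dose_index"] == row["dose_index"])
                    & (ev["kind"] == "EAD")
                    & (ev["recording_length_s"] == 30.0)
                ]
            )
            assert n >= 1

    def test_baseline_exclusion_fraction_matches_truncated_normal(self):
        """Fraction of baselines >= 500 ms agrees with the analytic tail."""
        rng = np.random.default_rng(123)
        n = 1000
        draws = np.array(
            [
                _truncated_normal(
                    rng, BASELINE_APD80_MEAN, BASELINE_APD80_SD, *BASELINE_APD80_RANGE
                )
                for _ in range(n)
            ]
        )
        lo, hi = BASELINE_APD80_RANGE
        z = lambda x: (x - BASELINE_APD80_MEAN) / BASELINE_APD80_SD
        p_tail = (norm.cdf(z(hi)) - norm.cdf(z(500.0))) / (norm.cdf(z(hi)) - norm.cdf(z(lo)))
        observed = float(np.mean(draws >= 500.0))
        # exact binomial 95% interval around the analytic tail probability
        from scipy.stats import binom

        lo_ci, hi_ci = binom.ppf([0.025, 0.975], n, p_tail) / n
        assert lo_ci <= observed <= hi_ci
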