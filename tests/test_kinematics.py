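import numpy as np
import pytest

from conftest import brute_force_scan, brute_force_secondaries
from sacerr import synth
from sacerr.io import EyeTrace
from sacerr.kinematics import (KinematicsConfig, Saccade, apply_trial_filters,
                               compute_velocity, detect_primary_saccade,
                               detect_secondary_saccades)

CFG = KinematicsConfig()


def _noiseless_trial(end_x=10.0, latency=200.0, duration=40.0, **spec_kw):
    spec = synth.TrialSpec(direction="right", fp_offset=1500.0,
                           sacc_onset=1500.0 + latency, duration=duration,
                           end_x=end_x, end_y=0.0, target_x=10.0, **spec_kw)
    gen = synth.GeneratorConfig(eye_noise_sd=0.0, drift_amplitude=0.0)
    return synth.generate_eye_trace(spec, gen, np.random.default_rng(0))


class TestVelocity:
    def test_linear_ramp(self):
        x = 0.1 * np.arange(500.0)          # 0.1 deg/ms
        tr = EyeTrace(0.0, 1.0, x, np.zeros_like(x))
        v = compute_velocity(tr, CFG)
        assert np.allclose(v[10:-10], 100.0, atol=1e-6)

    def test_static_trace(self):
        tr = EyeTrace(0.0, 1.0, np.ones(300), np.zeros(300))
        assert np.all(compute_velocity(tr, CFG) < 1e-9)

    def test_too_short_trace(self):
        tr = EyeTrace(0.0, 1.0, np.ones(2), np.zeros(2))
        with pytest.raises(ValueError):
            compute_velocity(tr, CFG)

    def test_peak_time_matches_profile(self):
        tr = _noiseless_trial()
        v = compute_velocity(tr, CFG)
        # raised-cosine velocity peaks at saccade midpoint
        assert abs(int(np.argmax(v)) - (1700 + 20)) <= 1


class TestPrimaryDetection:
    def test_offset_at_ten_percent_of_peak(self):
        tr = _noiseless_trial()
        v = compute_velocity(tr, CFG)
        s = detect_primary_saccade(tr, 1500.0, CFG)
        i = int(s.offset)
        assert v[i] < 0.1 * s.peak_velocity <= v[i - 1]

    def test_flat_trace_gives_none(self):
        tr = EyeTrace(0.0, 1.0, np.zeros(2500), np.zeros(2500))
        assert detect_primary_saccade(tr, 1500.0, CFG) is None

    def test_oracle_equivalence(self, behavior_only_session):
        _, session, _ = behavior_only_session
        for tr in session.trials:
            speed = compute_velocity(tr.eye, CFG)
            det = detect_primary_saccade(tr.eye, 1500.0, CFG, speed=speed)
            ref = brute_force_scan(speed, 1500, 2100, CFG.onset_threshold,
                                   CFG.offset_fraction)
            assert det is not None and ref is not None
            assert int(det.onset) == ref[0]
            assert int(det.offset) == ref[1]

    def test_end_position_recovers_planted_landing(self):
        tr = _noiseless_trial(end_x=9.3)
        s = detect_primary_saccade(tr, 1500.0, CFG)
        assert s.end_position[0] == pytest.approx(9.3, abs=0.05)


class TestTrialFilters:
    def _sacc(self, duration=40.0, end=(10.0, 0.0), amplitude=9.9, latency=200.0):
        return Saccade(onset=1700.0, offset=1700.0 + duration, duration=duration,
                       amplitude=amplitude, peak_velocity=500.0, latency=latency,
                       end_position=end)

    def test_planted_violations(self):
        cases = [
            (dict(duration=8.0), {"duration"}),
            (dict(duration=120.0), {"duration"}),
            (dict(end=(13.0, 0.0)), {"window"}),
            (dict(end=(10.0, 3.0)), {"window"}),
            (dict(amplitude=4.0), {"amplitude"}),   # strict 'larger than 4'
            (dict(amplitude=3.0), {"amplitude"}),
            (dict(latency=500.0), {"latency"}),
            (dict(latency=650.0), {"latency"}),
        ]
        for kw, expected in cases:
            out = apply_trial_filters(self._sacc(**kw), (10.0, 0.0), CFG)
            assert not out.passed and out.failed_rules == frozenset(expected), kw
        for kw in [dict(), dict(duration=10.0), dict(duration=100.0),
                   dict(end=(12.4, 2.4)), dict(latency=499.0)]:
            assert apply_trial_filters(self._sacc(**kw), (10.0, 0.0), CFG).passed, kw

    def test_no_saccade_reason(self):
        out = apply_trial_filters(None, (10.0, 0.0), CFG)
        assert out.failed_rules == frozenset({"no_saccade"})

    def test_pass_rate_on_generator_defaults(self, small_bundle):
        _, _, _, saccades = small_bundle
        assert saccades["passed"].mean() >= 0.95


class TestSecondaryDetection:
    def test_planted_corrective_saccade_recovered(self, small_bundle):
        _, session, gt, saccades = small_bundle
        merged = saccades.merge(gt.trials, on="trial_id")
        sec = merged[merged["secondary"]]
        assert len(sec) > 0
        assert (sec["n_secondary"] >= 1).all()
        err = (sec["first_secondary_onset_ms"] - sec["secondary_onset_ms"]).abs()
        assert err.max() <= 5.0

    def test_event_within_100ms_excluded(self):
        tr = _noiseless_trial(secondary=True, secondary_onset=1740.0 + 60.0,
                              secondary_duration=15.0, secondary_dx=1.0)
        prim = detect_primary_saccade(tr, 1500.0, CFG)
        assert detect_secondary_saccades(tr, prim, CFG) == []
        tr2 = _noiseless_trial(secondary=True, secondary_onset=1740.0 + 150.0,
                               secondary_duration=15.0, secondary_dx=1.0)
        prim2 = detect_primary_saccade(tr2, 1500.0, CFG)
        assert len(detect_secondary_saccades(tr2, prim2, CFG)) == 1

    def test_oracle_equivalence(self, behavior_only_session):
        _, session, _ = behavior_only_session
        for tr in session.trials:
            speed = compute_velocity(tr.eye, CFG)
            prim = detect_primary_saccade(tr.eye, 1500.0, CFG, speed=speed)
            det = detect_secondary_saccades(tr.eye, prim, CFG, speed=speed)
            ref = brute_force_secondaries(speed, tr.eye.x, tr.eye.y,
                                          int(prim.offset), CFG)
            assert [(int(s.onset), int(s.offset)) for s in det] == ref


def test_noise_robustness_of_detection():
    """Position noise up to 0.02 deg SD moves onset/offset by <= 2 ms."""
    base = dict(n_pps_neurons=0, n_lps_neurons=0, n_trials_per_direction=25,
                rng_seed=5)
    s0, _ = synth.generate_session(synth.GeneratorConfig(eye_noise_sd=0.0, **base))
    s1, _ = synth.generate_session(synth.GeneratorConfig(eye_noise_sd=0.02, **base))
    for ta, tb in zip(s0.trials, s1.trials):
        da = detect_primary_saccade(ta.eye, 1500.0, CFG)
        db = detect_primary_saccade(tb.eye, 1500.0, CFG)
        assert abs(da.onset - db.onset) <= 2.0
        assert abs(da.offset - db.offset) <= 2.0
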