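import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sacerr import io as sio
from sacerr import synth
from sacerr.synth import (GeneratorConfig, LPSParams, PPSParams, TrialSpec,
                          effective_error_gain, error_bump, generate_eye_trace,
                          generate_session, lps_rate_profile, peak_velocity_of,
                          pps_rate_profile, sample_spikes, truncated_parent)


def _noiseless_cfg(**kw):
    return GeneratorConfig(eye_noise_sd=0.0, drift_amplitude=0.0, **kw)


class TestEyeTrace:
    def test_lands_at_requested_position(self):
        spec = TrialSpec(direction="right", fp_offset=1500.0, sacc_onset=1700.0,
                         duration=40.0, end_x=10.0, end_y=0.0, target_x=10.0)
        tr = generate_eye_trace(spec, GeneratorConfig(drift_amplitude=0.0),
                                np.random.default_rng(0))
        t_end = int(spec.sacc_onset + spec.duration)
        assert np.mean(tr.x[t_end:t_end + 20]) == pytest.approx(10.0, abs=0.01)

    def test_peak_velocity_matches_closed_form(self):
        spec = TrialSpec(direction="right", fp_offset=1500.0, sacc_onset=1700.0,
                         duration=40.0, end_x=9.0, end_y=0.0, target_x=10.0)
        tr = generate_eye_trace(spec, _noiseless_cfg(), np.random.default_rng(0))
        # dense numeric maximization of the analytic displacement profile
        speed = np.abs(np.diff(tr.x)) * 1000.0
        assert speed.max() == pytest.approx(peak_velocity_of(9.0, 40.0), rel=0.01)

    def test_rejects_small_amplitude_on_must_pass_trial(self):
        spec = TrialSpec(direction="right", fp_offset=1500.0, sacc_onset=1700.0,
                         duration=40.0, end_x=3.0, end_y=0.0, target_x=10.0,
                         must_pass=True)
        with pytest.raises(ValueError):
            generate_eye_trace(spec, GeneratorConfig(), np.random.default_rng(0))


class TestRateProfiles:
    P = PPSParams("p", "right", baseline=8.0, peak=60.0, decay_ms=75.0,
                  tau_decay_ms=60.0, error_gain=2.5)
    L = LPSParams("l", "right", baseline=8.0, direction_gain=10.0,
                  position_gain=5.0, rise_ms=70.0, tau_rise_ms=25.0)

    def test_pps_baseline_before_ramp(self):
        r = pps_rate_profile(np.array([-500.0]), 0.0, 40.0, 0.5, self.P)
        assert r[0] == 8.0

    def test_pps_zero_error_is_pure_decay(self):
        t = np.array([40.0 + 75.0 + 120.0])
        r = pps_rate_profile(t, 0.0, 40.0, 0.0, self.P)
        assert r[0] == pytest.approx(8.0 + 52.0 * np.exp(-120.0 / 60.0))

    def test_pps_error_difference_equals_gain(self):
        t = np.array([40.0 + 250.0])     # bump plateau, 250 ms after saccade end
        r1 = pps_rate_profile(t, 0.0, 40.0, 0.5, self.P)
        r2 = pps_rate_profile(t, 0.0, 40.0, 1.5, self.P)
        assert r2[0] - r1[0] == pytest.approx(self.P.error_gain * 1.0)

    def test_pps_perisaccadic_rate_ignores_error(self):
        t = np.arange(-150.0, 100.0) + 40.0
        r1 = pps_rate_profile(t, 0.0, 40.0, 0.0, self.P)
        r2 = pps_rate_profile(t, 0.0, 40.0, 2.0, self.P)
        assert np.array_equal(r1, r2)

    def test_lps_silent_pre_saccade(self):
        assert lps_rate_profile(np.array([-100.0]), 0.0, 9.7, self.L)[0] == 8.0

    def test_lps_position_difference(self):
        t = np.array([150.0])
        env = 1.0 - np.exp(-(150.0 - 70.0) / 25.0)
        r9 = lps_rate_profile(t, 0.0, 9.0, self.L)
        r11 = lps_rate_profile(t, 0.0, 11.0, self.L)
        assert r11[0] - r9[0] == pytest.approx(2.0 * 5.0 * env)

    def test_lps_null_below_preferred(self):
        t = np.array([150.0])
        assert (lps_rate_profile(t, 0.0, 9.7, self.L, preferred=False)[0]
                < lps_rate_profile(t, 0.0, 9.7, self.L)[0])

    @given(st.floats(1.0, 100.0), st.floats(0.0, 5.0), st.floats(-300.0, 600.0))
    @settings(max_examples=50, deadline=None)
    def test_rates_never_negative(self, peak_extra, error, t):
        p = PPSParams("p", "right", 8.0, 8.0 + peak_extra, 75.0, 60.0, 2.0)
        assert pps_rate_profile(np.array([t]), 0.0, 40.0, error, p)[0] >= 0.0
        l = LPSParams("l", "right", 8.0, 10.0, 5.0, 70.0, 25.0)
        assert lps_rate_profile(np.array([t]), 0.0, 9.7, l)[0] >= 0.0


class TestSampleSpikes:
    def test_constant_rate_mean_count(self):
        rng = np.random.default_rng(11)
        counts = [sample_spikes(lambda t: np.full(len(t), 20.0), 1000.0, rng,
                                rate_max=20.0).size for _ in range(500)]
        sem = np.std(counts) / np.sqrt(500)
        assert np.mean(counts) == pytest.approx(20.0, abs=3 * sem)

    def test_zero_rate_empty(self):
        st_ = sample_spikes(lambda t: np.zeros(len(t)), 1000.0,
                            np.random.default_rng(0))
        assert st_.size == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sample_spikes(lambda t: np.full(len(t), -1.0), 100.0,
                          np.random.default_rng(0), rate_max=5.0)

    def test_thinning_matches_time_rescaling_oracle(self):
        # same inhomogeneous profile sampled by thinning and by inverting the
        # cumulative rate (time rescaling); binned counts must agree
        def rate(t):
            t = np.asarray(t, dtype=float)
            return 20.0 + 15.0 * np.sin(2 * np.pi * t / 400.0)

        rng = np.random.default_rng(5)
        reps, T = 400, 1000.0
        grid = np.arange(0.0, T, 1.0)
        cum = np.cumsum(rate(grid)) / 1000.0   # expected counts up to t
        bins = np.arange(0.0, T + 50.0, 50.0)
        thin = np.zeros(bins.size - 1)
        resc = np.zeros(bins.size - 1)
        for _ in range(reps):
            thin += np.histogram(sample_spikes(rate, T, rng, rate_max=35.1),
                                 bins)[0]
            # oracle: homogeneous exponential waits in rescaled time
            n = rng.poisson(cum[-1])
            u = np.sort(rng.uniform(0, cum[-1], n))
            spikes = np.interp(u, cum, grid)
            resc += np.histogram(spikes, bins)[0]
        per_bin_sem = np.sqrt(np.maximum(thin + resc, 1.0))
        assert np.all(np.abs(thin - resc) < 4 * per_bin_sem)


class TestSessionGeneration:
    def test_identical_seed_bit_identical_container(self, tmp_path):
        cfg = GeneratorConfig(n_pps_neurons=2, n_lps_neurons=1,
                              n_trials_per_direction=5, rng_seed=1)
        s1, _ = generate_session(cfg)
        s2, _ = generate_session(cfg)
        assert sio.sessions_equal(s1, s2)
        sio.write_session(s1, tmp_path / "a.h5")
        sio.write_session(s2, tmp_path / "b.h5")
        assert (tmp_path / "a.h5").read_bytes() == (tmp_path / "b.h5").read_bytes()

    def test_ground_truth_consistent_with_trials(self, small_bundle):
        _, session, gt, _ = small_bundle
        assert len(gt.trials) == len(session.trials)
        assert set(gt.neurons["neuron_id"]) == set(session.neuron_ids)
        row = gt.trials.iloc[0]
        assert row["error"] == pytest.approx(abs(row["end_motor"] - 10.0))

    def test_zero_slope_decouples_secondary_from_error(self):
        # no neurons -> the literal linear-in-error law; zero slope means the
        # flag frequency cannot depend on the error tercile
        cfg = GeneratorConfig(n_pps_neurons=0, n_lps_neurons=0,
                              n_trials_per_direction=1000, rng_seed=13,
                              secondary_base_prob=0.25, secondary_prob_slope=0.0)
        _, gt = generate_session(cfg)
        g = gt.trials
        terciles = np.quantile(g["error"], [1 / 3, 2 / 3])
        lab = np.digitize(g["error"], terciles)
        table = [[(g["secondary"][lab == k]).sum(),
                  (~g["secondary"][lab == k]).sum()] for k in range(3)]
        _, p, _, _ = stats.chi2_contingency(np.array(table))
        assert p > 0.01

    def test_positive_slope_monotone_secondary_probability(self):
        cfg = GeneratorConfig(n_pps_neurons=0, n_lps_neurons=0,
                              n_trials_per_direction=1000, rng_seed=13)
        _, gt = generate_session(cfg)
        g = gt.trials
        edges = np.quantile(g["error"], np.linspace(0, 1, 6))
        lab = np.clip(np.digitize(g["error"], edges[1:-1]), 0, 4)
        p = np.array([g["secondary"][lab == k].mean() for k in range(5)])
        assert np.all(np.diff(p) > 0)

    def test_endpoint_moments_converge(self):
        cfg = GeneratorConfig(n_pps_neurons=0, n_lps_neurons=0,
                              n_trials_per_direction=1000, rng_seed=21)
        _, gt = generate_session(cfg)
        x = gt.trials["end_motor"].to_numpy()
        sem = cfg.endpoint_std / np.sqrt(x.size)
        assert x.mean() == pytest.approx(cfg.endpoint_mean, abs=3 * sem)
        assert x.std(ddof=1) == pytest.approx(cfg.endpoint_std, rel=0.1)


class TestLatencyDistributions:
    def test_truncated_parent_recovers_moments(self):
        mu, sig = truncated_parent(74.8, 33.1, 35.0)
        a = (35.0 - mu) / sig
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sig, moments="mv")
        assert m == pytest.approx(74.8, abs=1e-6)
        assert np.sqrt(v) == pytest.approx(33.1, abs=1e-6)

    def test_drawn_latencies_truncated_and_centered(self):
        cfg = GeneratorConfig(n_pps_neurons=60, n_lps_neurons=30,
                              n_trials_per_direction=60, rng_seed=9)
        params = synth.default_neuron_params(cfg)
        decays = np.array([p.decay_ms for p in params if p.kind == "PPS"])
        rises = np.array([p.rise_ms for p in params if p.kind == "LPS"])
        assert decays.min() > 35.0 and rises.min() > 35.0
        # stratified draws keep small populations close to the configured mean
        assert decays.mean() == pytest.approx(74.8, abs=5.0)
        assert rises.mean() == pytest.approx(70.9, abs=6.0)

    def test_error_gain_matches_lps_readout_slope(self):
        cfg = GeneratorConfig()
        gain = effective_error_gain(cfg)
        atten = synth.lps_window_attenuation(cfg)
        assert gain == pytest.approx(cfg.lps_position_gain * atten
                                     / synth.bump_window_mean())
        assert 0.0 < atten < 1.0


def test_error_bump_envelope():
    assert error_bump(np.array([100.0]))[0] == 0.0
    assert error_bump(np.array([250.0]))[0] == 1.0
    assert error_bump(np.array([400.0]))[0] == 0.0
    u = np.arange(150.0, 350.0)
    assert error_bump(u).mean() == pytest.approx(synth.bump_window_mean(), abs=0.01)


def test_config_yaml_round_trip(tmp_path):
    import yaml
    cfg = GeneratorConfig(n_pps_neurons=3, rng_seed=42)
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump(synth.config_to_dict(cfg)))
    cfg2 = synth.config_from_yaml(path)
    assert cfg2 == cfg
    path.write_text("n_pps_neurons: 3\nbogus_key: 1\n")
    with pytest.raises(ValueError):
        synth.config_from_yaml(path)
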