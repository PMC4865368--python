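import numpy as np
import pytest

from sacerr import error_analysis as ea
from sacerr import pipeline


class TestSaccadicError:
    def test_arithmetic(self):
        assert ea.saccadic_error(10.0, 10.0) == 0.0
        assert ea.saccadic_error(9.2, 10.0) == pytest.approx(0.8)

    def test_matches_generator_ground_truth(self, small_bundle):
        _, session, gt, saccades = small_bundle
        info = pipeline.labels_from_ground_truth(gt)
        gtt = gt.trials.set_index("trial_id")
        for d in pipeline.neuron_trial_data(session, saccades, info):
            true_err = gtt.loc[d.trial_ids, "error"].to_numpy()
            # detected end positions differ from the planted ones only by
            # trace noise and the 20 ms endpoint average
            assert np.abs(d.errors - true_err).max() < 0.05
            break


class TestBinning:
    def test_exactly_uniform_positions_give_equal_counts(self):
        pos = np.linspace(0.0, 1.0, 1600, endpoint=False)
        b = ea.bin_by_end_position(pos, np.zeros_like(pos), n_bins=16,
                                   edges=np.linspace(0.0, 1.0, 17))
        assert np.all(np.abs(b.counts - 100) <= 2)

    def test_identical_positions_collapse_to_one_bin(self):
        pos = np.full(50, 5.0)
        act = np.arange(50.0)
        b = ea.bin_by_end_position(pos, act, n_bins=16)
        assert b.n_bins == 1
        assert b.counts[0] == 50
        assert b.mean[0] == pytest.approx(act.mean())

    def test_gaussian_positions_center_bins_most_populated(self):
        rng = np.random.default_rng(1)
        pos = rng.normal(9.66, 0.49, 4000)
        b = ea.bin_by_end_position(pos, np.zeros_like(pos), n_bins=16)
        assert abs(b.centers[np.argmax(b.counts)] - 9.66) < 0.3
        assert b.counts.sum() == 4000   # outliers clipped into edge bins

    def test_small_bins_merged(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(0.0, 1.0, 120)
        b = ea.bin_by_end_position(pos, np.zeros_like(pos), n_bins=16,
                                   min_trials=10)
        assert np.all(b.counts >= 10)
        assert b.counts.sum() == 120


class TestReferenceNormalize:
    def _binned(self, means):
        n = len(means)
        edges = np.linspace(8.0, 12.0, n + 1)
        return ea.BinnedActivity(edges, 0.5 * (edges[:-1] + edges[1:]),
                                 np.full(n, 10), np.asarray(means, float),
                                 np.zeros(n))

    def test_target_bin_becomes_zero(self):
        raw = self._binned([1.0, 1.3, 2.0, 0.5])
        k = ea.reference_bin_index(raw, 10.0)
        ref = raw.mean[k]
        b = ea.reference_normalize(raw, 10.0)
        assert b.mean[k] == 0.0
        assert b.mean[0] == pytest.approx(1.0 - ref)

    def test_idempotent(self):
        b1 = ea.reference_normalize(self._binned([1.0, 1.3, 2.0, 0.5]), 10.0)
        b2 = ea.reference_normalize(b1, 10.0)
        assert np.allclose(b1.mean, b2.mean)

    def test_constant_activity_all_zero(self):
        b = ea.reference_normalize(self._binned([2.0] * 4), 10.0)
        assert np.allclose(b.mean, 0.0)

    def test_target_outside_range_raises(self):
        with pytest.raises(ValueError):
            ea.reference_normalize(self._binned([1.0, 2.0]), 99.0)

    def test_commutes_with_rate_rescaling(self):
        raw = np.array([1.0, 1.3, 2.0, 0.5])
        a = ea.reference_normalize(self._binned(raw * 3.0), 10.0)
        b = ea.reference_normalize(self._binned(raw), 10.0)
        assert np.allclose(a.mean, 3.0 * b.mean)


class TestPiecewiseFit:
    def _binned(self, centers, means, counts=None):
        centers = np.asarray(centers, float)
        step = centers[1] - centers[0]
        edges = np.concatenate([centers - step / 2, [centers[-1] + step / 2]])
        n = centers.size
        counts = np.full(n, 10) if counts is None else counts
        return ea.BinnedActivity(edges, centers, counts,
                                 np.asarray(means, float), np.zeros(n))

    def test_v_shape_slopes(self):
        c = np.arange(8.0, 12.01, 0.5)
        b = self._binned(c, np.abs(c - 10.0))
        lo, hi = ea.piecewise_linear_fit(b, 10.0)
        assert lo.slope == pytest.approx(-1.0, abs=1e-9)
        assert hi.slope == pytest.approx(1.0, abs=1e-9)

    def test_linear_data_equal_slopes(self):
        c = np.arange(8.0, 12.01, 0.5)
        b = self._binned(c, 0.3 * c + 1.0)
        lo, hi = ea.piecewise_linear_fit(b, 10.0)
        assert lo.slope == pytest.approx(hi.slope, abs=1e-9)

    def test_insufficient_side_is_none(self):
        c = np.arange(10.5, 12.01, 0.5)
        lo, hi = ea.piecewise_linear_fit(self._binned(c, c), 10.0)
        assert lo is None and hi is not None


class TestSingleTrialCorrelation:
    def test_perfect_correlation(self):
        pos = np.linspace(9, 11, 40)
        res = ea.single_trial_correlation({"n": (2 * pos, pos)})
        assert res.r[0] == pytest.approx(1.0)

    def test_null_population_mean_near_zero(self):
        rng = np.random.default_rng(8)
        per = {f"n{k}": (rng.normal(size=60), rng.normal(size=60))
               for k in range(50)}
        res = ea.single_trial_correlation(per)
        assert abs(res.mean_r) < 0.05

    def test_zero_variance_excluded(self):
        res = ea.single_trial_correlation(
            {"flat": (np.ones(40), np.linspace(0, 1, 40)),
             "ok": (np.linspace(0, 1, 40), np.linspace(0, 1, 40))})
        assert res.n_neurons == 1
        assert res.excluded == [("flat", "zero variance")]

    def test_min_trials_enforced(self):
        res = ea.single_trial_correlation(
            {"few": (np.arange(10.0), np.arange(10.0))}, min_trials=30)
        assert res.n_neurons == 0


class TestSubtractionModel:
    def _binned(self, centers, means):
        centers = np.asarray(centers, float)
        step = centers[1] - centers[0]
        edges = np.concatenate([centers - step / 2, [centers[-1] + step / 2]])
        return ea.BinnedActivity(edges, centers, np.full(centers.size, 20),
                                 np.asarray(means, float), np.zeros(centers.size))

    def test_flat_pps_linear_lps(self):
        c = np.arange(8.0, 12.01, 0.25)
        pps = self._binned(c, np.zeros_like(c))
        lps = self._binned(c, 0.2 * (c - 10.0))
        post = self._binned(c, 0.2 * np.abs(c - 10.0))
        res = ea.subtraction_model(pps, lps, post, split_at=10.0)
        assert np.allclose(res.predicted, 0.2 * np.abs(c - 10.0), atol=1e-9)
        assert res.agreement_rms == pytest.approx(0.0, abs=1e-9)

    def test_zero_lps_gain_degenerate(self):
        c = np.arange(8.0, 12.01, 0.25)
        pps = self._binned(c, np.zeros_like(c))
        lps = self._binned(c, np.zeros_like(c))
        post = self._binned(c, np.zeros_like(c))
        res = ea.subtraction_model(pps, lps, post, split_at=10.0)
        assert np.allclose(res.predicted, 0.0, atol=1e-12)

    def test_grid_mismatch_raises(self):
        c1 = np.arange(8.0, 12.01, 0.25)
        c2 = np.arange(8.0, 12.01, 0.5)
        with pytest.raises(ValueError):
            ea.subtraction_model(self._binned(c1, c1), self._binned(c2, c2),
                                 self._binned(c1, c1), split_at=10.0)


class TestSlidingWindow:
    def _neurons(self, rng, gain, n_neurons=20, n_trials=60, window=(200.0, 300.0)):
        per = {}
        for k in range(n_neurons):
            errors = np.abs(rng.normal(0.35, 0.3, n_trials))
            trains, aligns = [], []
            for e in errors:
                base = rng.uniform(0, 600, rng.poisson(0.6 * 10))  # 10 sp/s
                extra_rate = gain * e
                w0, w1 = window
                extra = rng.uniform(w0, w1, rng.poisson(extra_rate * (w1 - w0) / 1000))
                trains.append(np.sort(np.concatenate([base, extra])))
                aligns.append(0.0)
            per[f"n{k}"] = (trains, np.array(aligns), errors, 10.0)
        return per

    def test_planted_signal_localized(self):
        rng = np.random.default_rng(17)
        per = self._neurons(rng, gain=25.0)
        res = ea.sliding_window_error_correlation(per, span=(0.0, 450.0))
        sig = (res["p"] < 0.001) & (res["mean_r"] > 0)
        assert sig.any()
        # every significant window overlaps the planted [200, 300) epoch
        for mid in res["t_mid"][sig]:
            assert mid + 50.0 > 200.0 and mid - 50.0 < 300.0

    def test_null_signal_no_significant_window(self):
        rng = np.random.default_rng(18)
        per = self._neurons(rng, gain=0.0)
        res = ea.sliding_window_error_correlation(per, span=(0.0, 450.0))
        assert not ((res["p"] < 0.001) & (res["mean_r"] > 0)).any()
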