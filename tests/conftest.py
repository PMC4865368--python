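import numpy as np
import pytest

from sacerr import pipeline, synth


@pytest.fixture(scope="session")
def small_bundle():
    """A small mixed session with ground truth and detected saccades."""
    cfg = synth.GeneratorConfig(n_pps_neurons=4, n_lps_neurons=3, n_null_neurons=2,
                                n_trials_per_direction=40, rng_seed=7)
    session, gt = synth.generate_session(cfg)
    saccades = pipeline.detect_saccades(session)
    return cfg, session, gt, saccades


@pytest.fixture(scope="session")
def behavior_only_session():
    """Trials without neurons (fast): kinematics-only checks."""
    cfg = synth.GeneratorConfig(n_pps_neurons=0, n_lps_neurons=0, n_null_neurons=0,
                                n_trials_per_direction=100, rng_seed=3)
    session, gt = synth.generate_session(cfg)
    return cfg, session, gt


def brute_force_scan(speed, start, stop, onset_thr, offset_frac):
    """Plain-loop threshold scan: (onset_idx, offset_idx) or None.

    Independent reference for the vectorized detectors: first sample above the
    onset threshold, peak until speed returns below it, offset at the first
    sample after the peak below offset_frac * peak.
    """
    onset = None
    for i in range(start, min(stop, len(speed))):
        if speed[i] > onset_thr:
            onset = i
            break
    if onset is None:
        return None
    ret = len(speed)
    for i in range(onset, len(speed)):
        if speed[i] <= onset_thr:
            ret = i
            break
    peak_i, peak = onset, speed[onset]
    for i in range(onset, ret):
        if speed[i] > peak:
            peak, peak_i = speed[i], i
    for i in range(peak_i + 1, len(speed)):
        if speed[i] < offset_frac * peak:
            return onset, i, peak
    return None


def brute_force_secondaries(speed, x, y, primary_offset_idx, cfg):
    """Loop reference for the corrective-saccade detector."""
    events = []
    idx = primary_offset_idx + 1
    while idx < len(speed):
        hit = brute_force_scan(speed, idx, len(speed),
                               cfg.secondary_onset_threshold, cfg.offset_fraction)
        if hit is None:
            break
        onset, off, peak = hit
        idx = off + 1
        amp = float(np.hypot(x[off] - x[onset], y[off] - y[onset]))
        if (onset >= primary_offset_idx + cfg.secondary_min_delay_ms
                and off - onset > cfg.secondary_min_duration_ms
                and amp > cfg.secondary_min_amplitude):
            events.append((onset, off))
    return events
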