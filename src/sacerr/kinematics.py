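"""Saccade detection from eye-velocity traces and trial-inclusion filters.

Detection is threshold-based on 2D eye speed: the primary saccade starts at
the first sample after the go signal where speed exceeds 30 deg/s and ends at
the first sample after the velocity peak where speed drops below 10% of that
peak.  The end point of a saccade is the average eye position over the 20 ms
following its offset.  Corrective (secondary) saccades use an 8 deg/s onset
threshold, must last more than 5 ms, exceed 0.2 deg amplitude, and begin at
least 100 ms after the primary saccade's offset; all qualifying events are
kept regardless of direction.

The differentiator is not part of the published detection rules, so it is a
configurable choice here: positions are smoothed with a short boxcar (default
5 ms) and differenced centrally over +-1 sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import EyeTrace


@dataclass
class KinematicsConfig:
    smoothing_ms: int = 5               # boxcar width for velocity computation
    onset_threshold: float = 30.0       # deg/s, primary saccade
    offset_fraction: float = 0.1        # of peak velocity
    search_window_ms: float = 600.0     # after fp_offset
    secondary_onset_threshold: float = 8.0
    secondary_min_duration_ms: float = 5.0
    secondary_min_amplitude: float = 0.2
    secondary_min_delay_ms: float = 100.0
    endpoint_window_ms: float = 20.0
    inclusion_window_deg: float = 5.0   # full width, centered at the target
    inclusion_window_shape: str = "square"   # "square" | "circular"
    min_amplitude_deg: float = 4.0
    max_latency_ms: float = 500.0
    duration_bounds_ms: tuple = (10.0, 100.0)


@dataclass
class Saccade:
    onset: float            # ms from trial start (first suprathreshold sample)
    offset: float
    duration: float
    amplitude: float        # Euclidean displacement onset -> offset, degrees
    peak_velocity: float    # deg/s
    latency: float          # ms from fp_offset (NaN for secondary saccades)
    end_position: tuple     # (x, y) degrees: mean position 0-20 ms after offset


@dataclass
class FilterOutcome:
    passed: bool
    failed_rules: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        assert self.passed == (len(self.failed_rules) == 0)


def compute_velocity(trace: EyeTrace, config: KinematicsConfig = KinematicsConfig()):
    """2D eye speed (deg/s), same length as the trace (edges one-sided)."""
    k = max(int(round(config.smoothing_ms / trace.dt)), 1)
    if trace.n < max(k, 3):
        raise ValueError("trace shorter than the smoothing kernel")
    xs = uniform_filter1d(trace.x, size=k, mode="nearest")
    ys = uniform_filter1d(trace.y, size=k, mode="nearest")
    dt_s = trace.dt / 1000.0
    vx = np.gradient(xs, dt_s)
    vy = np.gradient(ys, dt_s)
    return np.hypot(vx, vy)


def _endpoint(trace: EyeTrace, offset_idx: int, window_ms: float):
    n = int(round(window_ms / trace.dt))
    seg = slice(offset_idx, min(offset_idx + n, trace.n))
    return (float(np.mean(trace.x[seg])), float(np.mean(trace.y[seg])))


def _scan_event(speed, start_idx, stop_idx, onset_thr, offset_frac):
    """One threshold-scan step: (onset, peak_idx, peak, offset) or None.

    onset: first index in [start, stop) with speed > onset_thr; the peak is
    the max speed from onset until speed first returns below onset_thr; offset
    is the first index after the peak with speed < offset_frac * peak.
    """
    above = speed[start_idx:stop_idx] > onset_thr
    if not above.any():
        return None
    onset = start_idx + int(np.argmax(above))
    below = speed[onset:] <= onset_thr
    ret = onset + int(np.argmax(below)) if below.any() else speed.size
    peak_idx = onset + int(np.argmax(speed[onset:ret]))
    peak = float(speed[peak_idx])
    under = speed[peak_idx + 1:] < offset_frac * peak
    if not under.any():
        return None
    offset = peak_idx + 1 + int(np.argmax(under))
    return onset, peak_idx, peak, offset


def detect_primary_saccade(trace: EyeTrace, fp_offset: float,
                           config: KinematicsConfig = KinematicsConfig(),
                           speed=None):
    """First saccade after the go signal, or None if no threshold crossing."""
    if speed is None:
        speed = compute_velocity(trace, config)
    i0 = int(np.ceil((fp_offset - trace.t0) / trace.dt))
    i1 = min(int(np.ceil((fp_offset + config.search_window_ms - trace.t0) / trace.dt)),
             trace.n)
    hit = _scan_event(speed, max(i0, 0), i1, config.onset_threshold,
                      config.offset_fraction)
    if hit is None:
        return None
    onset, _, peak, offset = hit
    t_on = trace.t0 + onset * trace.dt
    t_off = trace.t0 + offset * trace.dt
    x0, y0 = trace.x[onset], trace.y[onset]
    x1, y1 = trace.x[offset], trace.y[offset]
    return Saccade(
        onset=t_on, offset=t_off, duration=t_off - t_on,
        amplitude=float(np.hypot(x1 - x0, y1 - y0)), peak_velocity=peak,
        latency=t_on - fp_offset,
        end_position=_endpoint(trace, offset, config.endpoint_window_ms))


def detect_secondary_saccades(trace: EyeTrace, primary: Saccade,
                              config: KinematicsConfig = KinematicsConfig(),
                              speed=None):
    """All corrective-saccade candidates after the primary saccade."""
    if speed is None:
        speed = compute_velocity(trace, config)
    out = []
    idx = int(np.ceil((primary.offset - trace.t0) / trace.dt)) + 1
    min_onset = primary.offset + config.secondary_min_delay_ms
    while idx < trace.n:
        hit = _scan_event(speed, idx, trace.n, config.secondary_onset_threshold,
                          config.offset_fraction)
        if hit is None:
            break
        onset, _, peak, offset = hit
        idx = offset + 1
        t_on = trace.t0 + onset * trace.dt
        t_off = trace.t0 + offset * trace.dt
        amp = float(np.hypot(trace.x[offset] - trace.x[onset],
                             trace.y[offset] - trace.y[onset]))
        if (t_on >= min_onset
                and t_off - t_on > config.secondary_min_duration_ms
                and amp > config.secondary_min_amplitude):
            out.append(Saccade(
                onset=t_on, offset=t_off, duration=t_off - t_on, amplitude=amp,
                peak_velocity=peak, latency=float("nan"),
                end_position=_endpoint(trace, offset, config.endpoint_window_ms)))
    return out


def apply_trial_filters(saccade, target_position,
                        config: KinematicsConfig = KinematicsConfig()) -> FilterOutcome:
    """Trial-inclusion rules for the primary saccade.

    Pass iff duration within [10, 100] ms (inclusive), end point inside the
    5 deg window centered at the target, amplitude strictly larger than 4 deg,
    and latency strictly shorter than 500 ms.  ``saccade=None`` fails with
    reason ``no_saccade``.
    """
    if saccade is None:
        return FilterOutcome(False, frozenset({"no_saccade"}))
    failed = set()
    lo, hi = config.duration_bounds_ms
    if not (lo <= saccade.duration <= hi):
        failed.add("duration")
    tx, ty = target_position
    ex, ey = saccade.end_position
    half = config.inclusion_window_deg / 2.0
    if config.inclusion_window_shape == "square":
        inside = abs(ex - tx) <= half and abs(ey - ty) <= half
    else:
        inside = np.hypot(ex - tx, ey - ty) <= half
    if not inside:
        failed.add("window")
    if not saccade.amplitude > config.min_amplitude_deg:
        failed.add("amplitude")
    if not saccade.latency < config.max_latency_ms:
        failed.add("latency")
    return FilterOutcome(not failed, frozenset(failed))
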