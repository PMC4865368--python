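"""Spike-density estimation, epoch rates, alignment and baseline normalization.

The spike density function is the classic Gaussian-kernel estimate: each spike
contributes a unit-area Gaussian (sigma = 5 ms by default, the value the
change-point procedure requires), and the result is expressed in spikes/s on a
1 ms grid.  Spikes are binned to the grid before convolution, so spike times
are effectively rounded to the grid step; total mass is exact.

Analysis epochs, all half-open [a, b) in ms relative to a named alignment:

==================  ==================  =============================
epoch               window              alignment
==================  ==================  =============================
baseline (norm.)    [100, 500)          fixation-point onset
baseline (class.)   [0, 500)            fixation onset
pre-saccadic        [-200, 0)           saccade onset
perisaccadic        [-150, +100)        saccade end
early post          [0, 100)            saccade end
lps tuning          [25, 225)           saccade end
lps correlation     [25, 125)           saccade end
post-subtraction    [150, 350)          saccade end
==================  ==================  =============================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

#: named analysis windows (ms, half-open) and their alignment events
EPOCHS = {
    "baseline_norm": ((100.0, 500.0), "fixation_onset"),
    "baseline_class": ((0.0, 500.0), "fixation_onset"),
    "pre_saccadic": ((-200.0, 0.0), "saccade_onset"),
    "perisaccadic": ((-150.0, 100.0), "saccade_end"),
    "early_post": ((0.0, 100.0), "saccade_end"),
    "lps_tuning": ((25.0, 225.0), "saccade_end"),
    "lps_corr": ((25.0, 125.0), "saccade_end"),
    "post_subtraction": ((150.0, 350.0), "saccade_end"),
}

BASELINE_FLOOR = 1.0  # spikes/s; guards the baseline division for silent cells


@dataclass
class DensityConfig:
    kernel_sigma: float = 5.0   # ms
    time_step: float = 1.0      # ms


def spike_density(spike_times, t_start: float, t_stop: float,
                  config: DensityConfig = DensityConfig()):
    """Gaussian-kernel rate estimate on [t_start, t_stop) at ``time_step``.

    Returns ``(t, rate)`` with rate in spikes/s.  An empty train gives an
    all-zero trace.  Kernel mass falling outside the requested window is
    simply lost (zero padding), so the integral equals the spike count for
    spikes further than a few sigma from the edges.
    """
    if config.kernel_sigma <= 0:
        raise ValueError("kernel_sigma must be > 0")
    dt = config.time_step
    n = int(round((t_stop - t_start) / dt))
    t = t_start + dt * np.arange(n)
    spike_times = np.asarray(spike_times, dtype=float)
    counts = np.zeros(n)
    if spike_times.size:
        idx = np.floor((spike_times - t_start) / dt).astype(int)
        ok = (idx >= 0) & (idx < n)
        np.add.at(counts, idx[ok], 1.0)
    rate = gaussian_filter1d(counts, config.kernel_sigma / dt, mode="constant",
                             truncate=6.0) * (1000.0 / dt)
    return t, rate


def aligned_density_matrix(spike_trains, align_times, window,
                           config: DensityConfig = DensityConfig()):
    """Per-trial densities on a common grid relative to per-trial alignment.

    ``spike_trains``: sequence of spike-time arrays (ms from trial start);
    ``align_times``: one alignment time per train; ``window``: (a, b) ms
    relative to alignment.  Densities are computed on a padded window so the
    returned segment is free of zero-padding artifacts.  Returns
    ``(t_rel, matrix)`` with matrix shape (n_trials, n_samples).
    """
    a, b = window
    pad = 6.0 * config.kernel_sigma
    rows = []
    t_rel = None
    for st, at in zip(spike_trains, align_times):
        t, rate = spike_density(np.asarray(st, dtype=float) - at,
                                a - pad, b + pad, config)
        keep = (t >= a - config.time_step / 2) & (t < b - config.time_step / 2)
        if t_rel is None:
            t_rel = t[keep]
        rows.append(rate[keep])
    return t_rel, np.asarray(rows)


def mean_density(spike_trains, align_times, window,
                 config: DensityConfig = DensityConfig()):
    """Trial-averaged spike density; returns (t_rel, mean, per-trial matrix)."""
    t_rel, mat = aligned_density_matrix(spike_trains, align_times, window, config)
    return t_rel, mat.mean(axis=0), mat


def epoch_rate(spike_times, window, align_time: float) -> float:
    """Mean rate (spikes/s) in a half-open window relative to an alignment."""
    if align_time is None or not np.isfinite(align_time):
        raise ValueError("alignment event missing")
    a, b = window
    st = np.asarray(spike_times, dtype=float)
    n = np.count_nonzero((st >= align_time + a) & (st < align_time + b))
    return n / (b - a) * 1000.0


def epoch_rates(spike_trains, window, align_times) -> np.ndarray:
    """Vector of per-trial epoch rates."""
    return np.array([epoch_rate(st, window, at)
                     for st, at in zip(spike_trains, align_times)])


def normalize_by_baseline(values, baseline_rate: float,
                          floor: float = BASELINE_FLOOR):
    """Dimensionless activity: value / max(baseline, floor)."""
    return np.asarray(values, dtype=float) / max(baseline_rate, floor)


def population_average(traces, ci: float = 0.95):
    """Pointwise mean and normal-approximation CI of stacked rate traces.

    Traces of unequal length are cropped to the shortest common support.
    Returns (mean, half_width) where the CI is mean +- half_width.
    """
    traces = [np.asarray(tr, dtype=float) for tr in traces]
    if len(traces) < 2:
        raise ValueError("need at least 2 traces")
    n = min(tr.size for tr in traces)
    mat = np.vstack([tr[:n] for tr in traces])
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    from scipy.stats import norm
    z = norm.ppf(0.5 + ci / 2.0)
    return mean, z * sem
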