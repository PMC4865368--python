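"""Synthetic session generator with known ground truth.

Emulates a spatial-cue delayed saccade session: two targets on the horizontal
meridian at +-10 deg, primary saccades whose end positions jitter around the
target as a narrow Gaussian, error-dependent corrective (secondary) saccades,
and two families of parietal neurons:

* PPS neurons -- persistent pre- and post-saccadic response.  They ramp up
  ~200 ms before saccade onset, hold a plateau, and decay exponentially
  starting at a per-neuron latency after saccade end.  Their perisaccadic rate
  carries *no* information about the realized end position; in a late
  post-saccadic window (150-350 ms after saccade end) their rate is elevated
  in proportion to the magnitude of the saccadic error -- the comparator
  (post-subtraction) signal.
* LPS neurons -- silent until a per-neuron latency after saccade end, then a
  sustained response whose level grows linearly with the actual horizontal
  end position (a proprioceptive-like position signal).

Per-neuron decay/rise latencies are drawn from the parent normal whose
truncation below ``class_cutoff_ms`` (35 ms, the classification bound) has
exactly the configured population mean and SD: the empirical populations these
defaults describe were themselves selected by that bound, so the reported
moments are post-selection moments.

The corrective-saccade decision is an *activity readout*: the trial's pooled
PPS post-subtraction activity, re-expressed in degrees of error, is pushed
through a clamped linear probability.  Averaged over spiking noise this
reduces to P(secondary) = base + slope * |error|, but trial by trial the
decision covaries with the very signal the analysis measures, which is the
point of the comparator model.  With no PPS neurons (or zero error gain) the
generator falls back to the literal linear-in-error law.

Spike trains are inhomogeneous Poisson, sampled by thinning under an explicit
rate upper bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy import optimize, stats

from .io import EyeTrace, NeuronRecord, Session, Trial

# fixed trial timeline (ms from trial start); the monkey acquires fixation at 0,
# targets appear 500 ms later, the cue flashes for 200 ms, and the fixation
# point goes off 400 ms after cue offset
EVENT_TIMES = {
    "fixation_onset": 0.0,
    "target_onset": 500.0,
    "cue_on": 900.0,
    "cue_off": 1100.0,
    "fp_offset": 1500.0,
}

#: post-subtraction window (ms after saccade end) in which the PPS error
#: signal lives; the bump envelope ramps over the first/last 50 ms
ERROR_EPOCH = (150.0, 350.0)
_RAMP = 50.0


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic session generator.

    Rates are spikes/s, positions degrees, times ms.  ``pps_error_gain=None``
    means "derive it from ``lps_position_gain`` so that the normalized LPS
    position slope, as measured in its 25-125 ms readout window, equals the
    normalized PPS post-subtraction error slope" -- the comparator-consistent
    default (see :func:`effective_error_gain`).
    """

    n_pps_neurons: int = 8
    n_lps_neurons: int = 4
    n_null_neurons: int = 0
    n_trials_per_direction: int = 60
    target_eccentricity: float = 10.0
    endpoint_mean: float = 9.6615
    endpoint_std: float = 0.4894
    endpoint_std_y: float = 0.15
    pps_decay_mean_ms: float = 74.8
    pps_decay_std_ms: float = 33.1
    lps_rise_mean_ms: float = 70.9
    lps_rise_std_ms: float = 31.3
    class_cutoff_ms: float = 35.0
    pps_tau_decay_ms: float = 60.0
    lps_tau_rise_ms: float = 25.0
    pps_ramp_power: float = 1.5
    lps_position_gain: float = 5.0      # (spikes/s)/deg, > 0
    lps_direction_gain: float = 10.0
    pps_error_gain: float | None = None  # (spikes/s)/deg of |error|, >= 0
    error_signal_shape: float = 4.0      # gamma shape of per-trial gain g (mean 1)
    secondary_base_prob: float = 0.05
    secondary_prob_slope: float = 0.30   # per degree of |error|
    secondary_latency_mean_ms: float = 154.0
    secondary_latency_std_ms: float = 25.0
    secondary_min_amplitude: float = 0.3
    baseline_rate: float = 8.0
    peak_rate: float = 60.0
    null_factor: float = 0.1
    heterogeneity: float = 0.2           # half-width of per-neuron uniform factors
    latency_mean_ms: float = 200.0
    latency_std_ms: float = 40.0
    saccade_duration_range: tuple = (25.0, 60.0)
    eye_noise_sd: float = 0.004
    drift_amplitude: float = 0.02
    trial_length_ms: float = 2800.0
    rng_seed: int = 0

    def validate(self) -> None:
        if min(self.baseline_rate, self.peak_rate, self.lps_position_gain) < 0:
            raise ValueError("rates and gains must be non-negative")
        if self.pps_error_gain is not None and self.pps_error_gain < 0:
            raise ValueError("pps_error_gain must be >= 0")
        if self.endpoint_std <= 0:
            raise ValueError("endpoint_std must be > 0")
        if self.lps_position_gain <= 0:
            raise ValueError("lps_position_gain must be > 0")
        lo, hi = self.saccade_duration_range
        if not (0 < lo < hi):
            raise ValueError("bad saccade_duration_range")


# ---------------------------------------------------------------------------
# latency distributions

def truncated_parent(mean: float, sd: float, lower: float):
    """Parameters (mu, sigma) of the normal whose truncation below ``lower``
    has the given mean and sd."""
    def eqs(p):
        mu, logsig = p
        sig = math.exp(logsig)
        a = (lower - mu) / sig
        lam = stats.norm.pdf(a) / stats.norm.sf(a)
        m = mu + sig * lam
        v = sig ** 2 * (1 + a * lam - lam ** 2)
        return [m - mean, math.sqrt(max(v, 1e-12)) - sd]

    sol = optimize.fsolve(eqs, [mean, math.log(sd)], full_output=True)
    x, _, ok, msg = sol
    if ok != 1:
        raise RuntimeError(f"truncated-parent solve failed: {msg}")
    return float(x[0]), float(math.exp(x[1]))


def _draw_truncated(rng, mean, sd, lower, size=None):
    mu, sig = truncated_parent(mean, sd, lower)
    a = (lower - mu) / sig
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sig, size=size,
                               random_state=rng)


def _stratified_truncated(u: float, slot: int, n: int, mean, sd, lower) -> float:
    """Stratified draw: neuron ``slot`` of ``n`` samples the quantile
    ``(slot + u)/n`` of the truncated normal.  Keeps small populations
    representative of the configured latency distribution."""
    mu, sig = truncated_parent(mean, sd, lower)
    a = (lower - mu) / sig
    q = (slot + u) / max(n, 1)
    return float(stats.truncnorm.ppf(q, a, np.inf, loc=mu, scale=sig))


# ---------------------------------------------------------------------------
# neuron parameters and rate profiles

@dataclass
class PPSParams:
    neuron_id: str
    preferred_direction: str
    baseline: float
    peak: float
    decay_ms: float              # start of the decay, ms after saccade end
    tau_decay_ms: float
    error_gain: float            # (spikes/s) per degree of |error| signal
    kind: str = field(default="PPS", init=False)


@dataclass
class LPSParams:
    neuron_id: str
    preferred_direction: str
    baseline: float
    direction_gain: float
    position_gain: float         # (spikes/s) per degree of horizontal end position
    rise_ms: float               # onset of the response, ms after saccade end
    tau_rise_ms: float
    kind: str = field(default="LPS", init=False)


@dataclass
class NullParams:
    neuron_id: str
    preferred_direction: str
    baseline: float
    kind: str = field(default="null", init=False)


def error_bump(u):
    """Smooth envelope of the PPS error signal vs time (ms) after saccade end.

    Raised-cosine ramps over the first and last 50 ms of the 150-350 ms
    post-subtraction epoch, 1 on its interior, 0 outside.
    """
    u = np.asarray(u, dtype=float)
    lo, hi = ERROR_EPOCH
    out = np.zeros_like(u)
    rise = (u >= lo) & (u < lo + _RAMP)
    out[rise] = 0.5 * (1 - np.cos(np.pi * (u[rise] - lo) / _RAMP))
    flat = (u >= lo + _RAMP) & (u < hi - _RAMP)
    out[flat] = 1.0
    fall = (u >= hi - _RAMP) & (u < hi)
    out[fall] = 0.5 * (1 + np.cos(np.pi * (u[fall] - (hi - _RAMP)) / _RAMP))
    return out


def bump_window_mean() -> float:
    lo, hi = ERROR_EPOCH
    return (hi - lo - _RAMP) / (hi - lo)


def pps_rate_profile(t, sacc_onset, sacc_end, error_signal, params: PPSParams,
                     preferred: bool = True, null_factor: float = 0.1,
                     ramp_power: float = 1.5):
    """PPS firing rate (spikes/s) at times ``t`` (ms from trial start).

    Baseline before ``sacc_onset - 200``; a gently accelerating ramp
    (``u**ramp_power``) up to the peak, which is reached at ``sacc_end +
    decay_ms`` where the exponential decay back toward baseline begins.  The
    neuron peaks at its decay time -- there is no flat plateau, so the
    density peak marks the change point.  In the preferred direction an error
    term ``error_gain * error_signal * error_bump(t - sacc_end)`` is added;
    perisaccadic rate never depends on the end position itself.
    """
    t = np.asarray(t, dtype=float)
    ramp_start = sacc_onset - 200.0
    decay_start = sacc_end + params.decay_ms
    shape = np.zeros_like(t)
    up = (t >= ramp_start) & (t < decay_start)
    shape[up] = ((t[up] - ramp_start) / (decay_start - ramp_start)) ** ramp_power
    dn = t >= decay_start
    shape[dn] = np.exp(-(t[dn] - decay_start) / params.tau_decay_ms)
    factor = 1.0 if preferred else null_factor
    rate = params.baseline + (params.peak - params.baseline) * shape * factor
    if preferred and params.error_gain > 0 and error_signal > 0:
        rate = rate + params.error_gain * error_signal * error_bump(t - sacc_end)
    return rate


def lps_rate_profile(t, sacc_end, end_position, params: LPSParams,
                     preferred: bool = True, null_factor: float = 0.1):
    """LPS firing rate (spikes/s) at times ``t`` (ms from trial start).

    Baseline until ``sacc_end + rise_ms``, then a saturating rise (time
    constant ``tau_rise_ms``) to ``baseline + direction_gain +
    position_gain * end_position``; no pre-saccadic modulation.
    ``end_position`` is the horizontal end position in the neuron's motor
    coordinates (preferred direction positive).
    """
    t = np.asarray(t, dtype=float)
    onset = sacc_end + params.rise_ms
    env = np.zeros_like(t)
    post = t >= onset
    env[post] = 1.0 - np.exp(-(t[post] - onset) / params.tau_rise_ms)
    if preferred:
        level = params.direction_gain + params.position_gain * end_position
    else:
        level = null_factor * params.direction_gain
    return params.baseline + max(level, 0.0) * env


def sample_spikes(rate_fn, duration_ms: float, rng, rate_max: float | None = None):
    """Inhomogeneous-Poisson spike times on [0, duration) via thinning.

    ``rate_fn`` maps times (ms) to rates (spikes/s).  ``rate_max`` is the
    thinning bound; if omitted it is taken as 1.05x the maximum of the rate on
    a 1 ms grid.  Raises on negative rates or a violated bound.
    """
    if rate_max is None:
        grid = np.arange(0.0, duration_ms + 1.0)
        vals = np.asarray(rate_fn(grid), dtype=float)
        if np.any(vals < 0):
            raise ValueError("negative rate")
        rate_max = float(vals.max()) * 1.05 + 1e-9
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * duration_ms / 1000.0)
    t = np.sort(rng.uniform(0.0, duration_ms, n))
    r = np.asarray(rate_fn(t), dtype=float)
    if np.any(r < 0):
        raise ValueError("negative rate")
    if np.any(r > rate_max * (1 + 1e-9)):
        raise ValueError("rate exceeds thinning bound")
    keep = rng.uniform(0.0, rate_max, n) < r
    return t[keep]


# ---------------------------------------------------------------------------
# comparator-consistent error gain

def lps_window_attenuation(cfg: GeneratorConfig, window=(25.0, 125.0)) -> float:
    """Expected fraction of the sustained LPS level visible in the readout
    window, averaged over the rise-latency distribution (quadrature on
    quantiles of the truncated normal)."""
    mu, sig = truncated_parent(cfg.lps_rise_mean_ms, cfg.lps_rise_std_ms,
                               cfg.class_cutoff_ms)
    a = (cfg.class_cutoff_ms - mu) / sig
    q = (np.arange(1, 400) / 400.0)
    rts = stats.truncnorm.ppf(q, a, np.inf, loc=mu, scale=sig)
    w0, w1 = window
    tau = cfg.lps_tau_rise_ms
    start = np.maximum(rts, w0)
    live = start < w1
    integral = np.zeros_like(rts)
    s, r = start[live], rts[live]
    integral[live] = (w1 - s) - tau * (np.exp(-(s - r) / tau) - np.exp(-(w1 - r) / tau))
    return float(integral.mean() / (w1 - w0))


def effective_error_gain(cfg: GeneratorConfig) -> float:
    """Resolve ``pps_error_gain``: explicit value, or the comparator-consistent
    default ``lps_position_gain * lps_attenuation / bump_attenuation``."""
    if cfg.pps_error_gain is not None:
        return cfg.pps_error_gain
    return cfg.lps_position_gain * lps_window_attenuation(cfg) / bump_window_mean()


# ---------------------------------------------------------------------------
# eye traces

@dataclass
class TrialSpec:
    """Kinematic plan of one trial, in absolute trial time (ms)."""

    direction: str
    fp_offset: float
    sacc_onset: float
    duration: float
    end_x: float                  # signed landing position of the primary saccade
    end_y: float
    target_x: float
    target_y: float = 0.0
    secondary: bool = False
    secondary_onset: float = 0.0  # ms from trial start
    secondary_duration: float = 15.0
    secondary_dx: float = 0.0
    secondary_dy: float = 0.0
    drift_sign: float = 1.0
    must_pass: bool = False


def _rc_displacement(t, onset, duration):
    """Normalized raised-cosine-velocity displacement profile (0 -> 1)."""
    u = np.clip((t - onset) / duration, 0.0, 1.0)
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


def peak_velocity_of(amplitude: float, duration_ms: float) -> float:
    """Closed-form peak speed (deg/s) of the raised-cosine velocity profile."""
    return 2.0 * abs(amplitude) / duration_ms * 1000.0


def generate_eye_trace(spec: TrialSpec, cfg: GeneratorConfig, rng) -> EyeTrace:
    """1 kHz eye trace realizing a trial plan.

    Stable fixation near 0 deg, a raised-cosine-velocity primary saccade to
    ``(end_x, end_y)``, optional corrective saccade, a small zero-mean
    post-saccadic settling drift, and additive white position noise.
    """
    if spec.must_pass and math.hypot(spec.end_x, spec.end_y) <= 4.0:
        raise ValueError("end position implies amplitude <= 4 deg on a "
                         "must-pass trial")
    n = int(round(cfg.trial_length_ms))
    t = np.arange(n, dtype=float)
    prim = _rc_displacement(t, spec.sacc_onset, spec.duration)
    x = spec.end_x * prim
    y = spec.end_y * prim
    if spec.secondary:
        sec = _rc_displacement(t, spec.secondary_onset, spec.secondary_duration)
        x = x + spec.secondary_dx * sec
        y = y + spec.secondary_dy * sec
    t_end = spec.sacc_onset + spec.duration
    settle = t >= t_end
    drift = np.zeros(n)
    drift[settle] = (spec.drift_sign * cfg.drift_amplitude
                     * (1.0 - np.exp(-(t[settle] - t_end) / 200.0)))
    x = x + drift
    if cfg.eye_noise_sd > 0:
        noise = rng.normal(0.0, cfg.eye_noise_sd, size=(2, n))
        x = x + noise[0]
        y = y + noise[1]
    return EyeTrace(t0=0.0, dt=1.0, x=x, y=y)


# ---------------------------------------------------------------------------
# whole sessions

@dataclass
class GroundTruth:
    """Generative parameters the analysis is supposed to recover.

    ``neurons``: one row per neuron (true class, latencies, gains).
    ``trials``: one row per trial (end position, |error|, secondary flag...).
    """

    neurons: "pd.DataFrame"
    trials: "pd.DataFrame"
    config: GeneratorConfig

    def write_csv(self, prefix) -> tuple:
        import os
        prefix = os.fspath(prefix)
        pn = prefix + "_neurons.csv"
        pt = prefix + "_trials.csv"
        self.neurons.to_csv(pn, index=False)
        self.trials.to_csv(pt, index=False)
        return pn, pt


def _stream(seed: int, *key) -> np.random.Generator:
    """Independent RNG stream for a (namespace, ...indices) key.

    Seeds are derived by hashing the key with SHA-256 rather than through
    ``SeedSequence`` spawn keys: with small integer entropy and structured
    spawn keys, sibling SeedSequence streams showed measurable cross-stream
    correlations (spike counts tracking behavioral draws), which a
    cryptographic hash removes.
    """
    import hashlib
    digest = hashlib.sha256(("/".join(map(str, (seed,) + key))).encode()).digest()
    words = np.frombuffer(digest, dtype=np.uint32)
    return default_rng(SeedSequence(entropy=[int(w) for w in words]))


def _uni(rng, width):
    return 1.0 + width * (2.0 * rng.random() - 1.0)


def default_neuron_params(cfg: GeneratorConfig):
    """Draw the per-neuron generative parameters (deterministic given seed)."""
    gain_err = effective_error_gain(cfg)
    params = []
    for j in range(cfg.n_pps_neurons):
        rng = _stream(cfg.rng_seed, 1, j)
        decay = _stratified_truncated(rng.random(), j, cfg.n_pps_neurons,
                                      cfg.pps_decay_mean_ms,
                                      cfg.pps_decay_std_ms, cfg.class_cutoff_ms)
        params.append(PPSParams(
            neuron_id=f"pps{j:03d}",
            preferred_direction="right" if rng.random() < 0.5 else "left",
            baseline=cfg.baseline_rate,
            peak=cfg.peak_rate * _uni(rng, cfg.heterogeneity),
            decay_ms=decay,
            tau_decay_ms=cfg.pps_tau_decay_ms * _uni(rng, cfg.heterogeneity),
            error_gain=gain_err * _uni(rng, cfg.heterogeneity)))
    for j in range(cfg.n_lps_neurons):
        rng = _stream(cfg.rng_seed, 1, cfg.n_pps_neurons + j)
        rise = _stratified_truncated(rng.random(), j, cfg.n_lps_neurons,
                                     cfg.lps_rise_mean_ms,
                                     cfg.lps_rise_std_ms, cfg.class_cutoff_ms)
        params.append(LPSParams(
            neuron_id=f"lps{j:03d}",
            preferred_direction="right" if rng.random() < 0.5 else "left",
            baseline=cfg.baseline_rate,
            direction_gain=cfg.lps_direction_gain * _uni(rng, cfg.heterogeneity),
            position_gain=cfg.lps_position_gain * _uni(rng, cfg.heterogeneity),
            rise_ms=rise,
            tau_rise_ms=cfg.lps_tau_rise_ms))
    for j in range(cfg.n_null_neurons):
        rng = _stream(cfg.rng_seed, 1, cfg.n_pps_neurons + cfg.n_lps_neurons + j)
        params.append(NullParams(
            neuron_id=f"bg{j:03d}",
            preferred_direction="right" if rng.random() < 0.5 else "left",
            baseline=cfg.baseline_rate * _uni(rng, 0.5)))
    return params


def _pps_decay_window_mean(p: PPSParams, duration: float,
                           window=ERROR_EPOCH, ramp_power: float = 1.5) -> float:
    """Analytic mean of the zero-error PPS profile over a post-end window.

    The ramp runs from 200 ms before saccade onset to the decay point, so the
    pre-decay part of the window depends on the trial's saccade duration.
    """
    w0, w1 = window
    d, tau = p.decay_ms, p.tau_decay_ms
    ramp_len = 200.0 + duration + d      # ramp_start -> decay point, ms
    a = min(max(d, w0), w1)
    # ramp segment [w0, a): shape(u) = ((200 + duration + u)/ramp_len)**power
    ramp_int = 0.0
    if a > w0:
        q = ramp_power + 1.0
        u0 = (200.0 + duration + w0) / ramp_len
        u1 = (200.0 + duration + a) / ramp_len
        ramp_int = ramp_len * (u1 ** q - u0 ** q) / q
    # decay segment [a, w1): shape(u) = exp(-(u - d)/tau)
    tail = 0.0
    if a < w1:
        tail = tau * (math.exp(-(a - d) / tau) - math.exp(-(w1 - d) / tau))
    shape = (ramp_int + tail) / (w1 - w0)
    return p.baseline + (p.peak - p.baseline) * shape


def _neuron_rate_fn(p, spec: TrialSpec, error_signal: float, cfg: GeneratorConfig):
    """(rate_fn, rate_max) for one neuron on one trial."""
    t_end = spec.sacc_onset + spec.duration
    pref = p.preferred_direction == spec.direction
    sign = 1.0 if p.preferred_direction == "right" else -1.0
    if p.kind == "PPS":
        def fn(t, p=p, pref=pref):
            return pps_rate_profile(t, spec.sacc_onset, t_end, error_signal, p,
                                    preferred=pref, null_factor=cfg.null_factor,
                                    ramp_power=cfg.pps_ramp_power)
        bound = p.baseline + (p.peak - p.baseline) * (1.0 if pref else cfg.null_factor)
        if pref:
            bound += p.error_gain * error_signal
    elif p.kind == "LPS":
        pos = sign * spec.end_x
        def fn(t, p=p, pref=pref, pos=pos):
            return lps_rate_profile(t, t_end, pos, p, preferred=pref,
                                    null_factor=cfg.null_factor)
        level = (p.direction_gain + p.position_gain * pos) if pref \
            else cfg.null_factor * p.direction_gain
        bound = p.baseline + max(level, 0.0)
    else:
        def fn(t, p=p):
            return np.full(np.asarray(t, dtype=float).shape, p.baseline)
        bound = p.baseline
    return fn, bound * (1 + 1e-9) + 1e-9


def generate_session(cfg: GeneratorConfig, neuron_params=None,
                     session_id: str = "synthetic"):
    """Generate a complete session plus its ground truth.

    Determinism contract: identical config (seed included) gives a
    bit-identical session.  Behavioral kinematics use per-trial RNG streams
    that do not depend on the neuron count; the secondary-saccade flag reads
    pooled PPS activity and therefore does depend on the PPS population.
    """
    import pandas as pd

    cfg.validate()
    if neuron_params is None:
        neuron_params = default_neuron_params(cfg)
    gain_err = effective_error_gain(cfg)
    pps = {p.neuron_id: p for p in neuron_params if p.kind == "PPS"}

    n_trials = 2 * cfg.n_trials_per_direction
    ecc = cfg.target_eccentricity
    dur_lo, dur_hi = cfg.saccade_duration_range
    w0, w1 = ERROR_EPOCH

    trials, gt_rows = [], []
    for i in range(n_trials):
        direction = "right" if i % 2 == 0 else "left"
        sign = 1.0 if direction == "right" else -1.0
        beh = _stream(cfg.rng_seed, 0, i)
        end_motor = beh.normal(cfg.endpoint_mean, cfg.endpoint_std)
        end_y = beh.normal(0.0, cfg.endpoint_std_y)
        latency = float(np.clip(beh.normal(cfg.latency_mean_ms, cfg.latency_std_ms),
                                80.0, 420.0))
        duration = beh.uniform(dur_lo, dur_hi)
        g = beh.gamma(cfg.error_signal_shape, 1.0 / cfg.error_signal_shape)
        sec_latency = float(np.clip(
            beh.normal(cfg.secondary_latency_mean_ms, cfg.secondary_latency_std_ms),
            115.0, None))
        sec_duration = beh.uniform(12.0, 20.0)
        sec_jitter = beh.normal(0.0, 0.05, size=2)
        drift_sign = 1.0 if beh.random() < 0.5 else -1.0

        error = abs(end_motor - ecc)
        error_signal = error * g
        sacc_onset = EVENT_TIMES["fp_offset"] + latency
        t_end = sacc_onset + duration
        spec = TrialSpec(
            direction=direction, fp_offset=EVENT_TIMES["fp_offset"],
            sacc_onset=sacc_onset, duration=duration,
            end_x=sign * end_motor, end_y=end_y,
            target_x=sign * ecc, target_y=0.0, drift_sign=drift_sign)

        # spike trains for every neuron; the readout pools the PPS neurons
        # whose preferred direction matches this trial (the others carry no
        # error signal here)
        trains = {}
        readout = []
        for j, p in enumerate(neuron_params):
            rng = _stream(cfg.rng_seed, 2, j, i)
            fn, bound = _neuron_rate_fn(p, spec, error_signal, cfg)
            st = sample_spikes(fn, cfg.trial_length_ms, rng, rate_max=bound)
            trains[p.neuron_id] = st
            if p.kind == "PPS" and p.preferred_direction == direction:
                cnt = np.count_nonzero((st >= t_end + w0) & (st < t_end + w1))
                readout.append(cnt / (w1 - w0) * 1000.0
                               - _pps_decay_window_mean(
                                   p, duration, ramp_power=cfg.pps_ramp_power))

        # corrective-saccade decision
        if readout and gain_err > 0:
            s_deg = float(np.mean(readout)) / gain_err / bump_window_mean()
            p_sec = float(np.clip(
                cfg.secondary_base_prob + cfg.secondary_prob_slope * s_deg, 0.0, 1.0))
        else:
            p_sec = float(np.clip(
                cfg.secondary_base_prob + cfg.secondary_prob_slope * error_signal,
                0.0, 1.0))
        make_sec = _stream(cfg.rng_seed, 3, i).random() < p_sec
        if make_sec:
            dx = spec.target_x - spec.end_x + sec_jitter[0]
            dy = spec.target_y - spec.end_y + sec_jitter[1]
            amp = math.hypot(dx, dy)
            if amp < cfg.secondary_min_amplitude:
                scale = cfg.secondary_min_amplitude / max(amp, 1e-9)
                dx, dy = dx * scale, dy * scale
            spec.secondary = True
            spec.secondary_onset = t_end + sec_latency
            spec.secondary_duration = sec_duration
            spec.secondary_dx, spec.secondary_dy = dx, dy

        eye = generate_eye_trace(spec, cfg, _stream(cfg.rng_seed, 4, i))
        tid = f"t{i:05d}"
        trials.append(Trial(
            trial_id=tid, direction=direction,
            target_x=spec.target_x, target_y=spec.target_y,
            events=dict(EVENT_TIMES), eye=eye, spike_trains=trains))
        gt_rows.append(dict(
            trial_id=tid, direction=direction, end_x=spec.end_x, end_y=spec.end_y,
            end_motor=end_motor, error=error, gain=g, error_signal=error_signal,
            latency_ms=latency, duration_ms=duration,
            sacc_onset_ms=sacc_onset, sacc_end_ms=t_end,
            secondary=bool(make_sec), p_secondary=p_sec,
            secondary_onset_ms=spec.secondary_onset if make_sec else np.nan))

    neuron_rows = []
    for p in neuron_params:
        row = dict(neuron_id=p.neuron_id, true_class=p.kind,
                   preferred_direction=p.preferred_direction,
                   baseline=p.baseline,
                   decay_ms=np.nan, rise_ms=np.nan, peak=np.nan,
                   error_gain=np.nan, position_gain=np.nan, direction_gain=np.nan)
        if p.kind == "PPS":
            row.update(decay_ms=p.decay_ms, peak=p.peak, error_gain=p.error_gain)
        elif p.kind == "LPS":
            row.update(rise_ms=p.rise_ms, position_gain=p.position_gain,
                       direction_gain=p.direction_gain)
        neuron_rows.append(row)

    session = Session(
        session_id=session_id, task="SCS_horizontal", sampling_rate=1000.0,
        trials=trials, neurons=[NeuronRecord(p.neuron_id) for p in neuron_params])
    gt = GroundTruth(neurons=pd.DataFrame(neuron_rows),
                     trials=pd.DataFrame(gt_rows), config=cfg)
    return session, gt


def config_from_yaml(path) -> GeneratorConfig:
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(GeneratorConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "saccade_duration_range" in raw:
        raw["saccade_duration_range"] = tuple(raw["saccade_duration_range"])
    return GeneratorConfig(**raw)


def config_to_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["saccade_duration_range"] = list(d["saccade_duration_range"])
    return d
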