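"""Exponential-fit change-point estimation of firing-rate transitions.

The decay (or rise) time of a neuron's activity is estimated from its
trial-averaged spike density (Gaussian kernel, sigma = 5 ms) on a window
around the saccade: the peak is located with a 20 ms moving mean stepped at
1 ms; a "fluctuation period" of admissible change points is delimited by a
2-STE / 80%-of-peak rule; an exponential ``y = A1 * exp(x / A2) + A3`` is fit
from every candidate start in that period to the end point; the start of the
minimum-mean-squared-residual fit is the change point.

For a fixed A2 the model is linear in (A1, A3), so each fit profiles A2 over a
signed log-spaced grid with an exact linear solve, then refines the best A2
with bounded 1-D minimization.  Ties in candidate residuals (relative 1e-9)
break to the earliest start: on a noiseless planted transition every start at
or after the true change point fits exactly, and the earliest of these is the
true one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

#: default analysis windows (ms, half-open) per alignment
FIT_WINDOWS = {
    "saccade_onset": (-200.0, 300.0),
    "saccade_end": (-250.0, 250.0),
}

PEAK_WINDOW_MS = 20.0
MIN_FIT_POINTS = 6


@dataclass
class ExponentialFit:
    A1: float
    A2: float
    A3: float
    start_time: float
    residual: float  # mean squared error over the fitted segment


@dataclass
class ChangePointResult:
    kind: str                      # "decay" | "rise"
    time_ms: float | None          # change point, ms relative to the alignment
    alignment: str
    fluctuation_period: tuple | None
    fit: ExponentialFit | None
    candidates_evaluated: int
    reason: str = ""               # why there is no change point, if time_ms is None

    @property
    def found(self) -> bool:
        return self.time_ms is not None


def _moving_mean(y, width):
    kernel = np.ones(width) / width
    return np.convolve(y, kernel, mode="valid")


def exp_fit_sse(x, y, tau):
    """Best SSE of y ~ A1*exp((x - x[0])/tau) + A3 for fixed tau.

    Linear subproblem in (A1, A3); A1 is the exponential's amplitude at the
    fit start (the x origin is the start time, which keeps the basis bounded).
    """
    b = np.exp((x - x[0]) / tau)
    bm, ym = b.mean(), y.mean()
    db = b - bm
    denom = np.dot(db, db)
    if denom < 1e-300:
        a1 = 0.0
    else:
        a1 = np.dot(db, y - ym) / denom
    a3 = ym - a1 * bm
    r = y - (a1 * b + a3)
    return float(np.dot(r, r)), float(a1), float(a3)


def fit_exponential(x, y, decelerating_only: bool = False):
    """Profile-A2 exponential fit; returns (A1, A2, A3, mse).

    A2 is profiled over log-spaced grids of both signs (positive growth rates
    are floored at span/40 so the basis stays finite; anything faster is
    indistinguishable from a step at this sampling), then refined by bounded
    1-D minimization with exact linear solves for (A1, A3).

    ``decelerating_only`` restricts the fit to A2 < 0 -- the branch whose
    transition is steepest at the fit start (exponential decay toward an
    asymptote, or a saturating rise).  The growing branch (A2 > 0) can defer
    its entire change to the end of the segment, silently absorbing a flat
    lead-in, which makes the start point of such a fit meaningless for
    change-point estimation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    span = max(x[-1] - x[0], 1.0)
    tau_min_pos = span / 40.0
    if decelerating_only:
        taus = -np.geomspace(1.0, 10.0 * span, 24)
    else:
        taus = np.concatenate([
            np.geomspace(tau_min_pos, 10.0 * span, 24),
            -np.geomspace(1.0, 10.0 * span, 24),
        ])
    sses = np.array([exp_fit_sse(x, y, tau)[0] for tau in taus])
    best = int(np.argmin(sses))
    tau0 = taus[best]
    sign = np.sign(tau0)
    lo = np.log(tau_min_pos if sign > 0 else 1.0) - 0.5
    hi = np.log(10.0 * span) + 0.5
    res = minimize_scalar(
        lambda lt: exp_fit_sse(x, y, sign * np.exp(lt))[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4})
    tau = sign * float(np.exp(res.x))
    sse, a1, a3 = exp_fit_sse(x, y, tau)
    if sse > sses[best]:  # refinement should never lose to the grid
        tau = tau0
        sse, a1, a3 = exp_fit_sse(x, y, tau)
    return a1, float(tau), a3, sse / x.size


def _moving_mean_series(y, dt):
    """20 ms moving mean of the density, with the index offset of its centers.

    ``mm[j]`` is the mean over the window centered at sample ``j + c0``.
    """
    width = max(int(round(PEAK_WINDOW_MS / dt)), 1)
    mm = _moving_mean(y, width)
    c0 = (width - 1) // 2
    return mm, c0, width


def _peak_by_moving_mean(y, dt):
    mm, c0, width = _moving_mean_series(y, dt)
    start = int(np.argmax(mm))
    return start + c0, float(mm[start]), width


def _window_ste(trial_matrix, center, width):
    """2-STE building block: across-trial SE of the mean density averaged
    within the 20 ms window around ``center``."""
    if trial_matrix is None or len(trial_matrix) < 2:
        return 0.0
    lo = max(center - width // 2, 0)
    hi = min(lo + width, trial_matrix.shape[1])
    per_trial = np.asarray(trial_matrix)[:, lo:hi].mean(axis=1)
    return float(per_trial.std(ddof=1) / np.sqrt(per_trial.size))


def _segment_ste(trial_matrix, stop, width):
    """Median across-trial bin-SE over the bins ending before ``stop``.

    A per-bin SE evaluated inside a deep trough underestimates the trace's
    sampling noise (few spikes there); the median over the whole pre-peak
    segment is a stable scale for the 2-STE bound.
    """
    if trial_matrix is None or len(trial_matrix) < 2:
        return 0.0
    mat = np.asarray(trial_matrix)[:, :max(stop, width)]
    n = mat.shape[0]
    k = np.ones(width) / width
    binned = np.apply_along_axis(lambda r: np.convolve(r, k, mode="valid"), 1, mat)
    ses = binned.std(axis=0, ddof=1) / np.sqrt(n)
    return float(np.median(ses))


def _select_start(t, y, candidates, seg_end, kind):
    """Fit from every candidate start; earliest within tie tolerance wins."""
    fits = []
    for c in candidates:
        xs, ys = t[c:seg_end + 1], y[c:seg_end + 1]
        if xs.size < MIN_FIT_POINTS:
            continue
        a1, a2, a3, mse = fit_exponential(xs, ys, decelerating_only=True)
        fits.append((c, a1, a2, a3, mse))
    if not fits:
        return None, 0
    mses = np.array([f[4] for f in fits])
    scale = float(np.ptp(y)) or 1.0
    tol = mses.min() * 1e-9 + 1e-12 * scale ** 2
    winner = fits[int(np.argmax(mses <= mses.min() + tol))]
    return winner, len(fits)


def estimate_decay_time(t, y, trial_matrix=None,
                        alignment: str = "saccade_end") -> ChangePointResult:
    """Change point where activity starts its exponential decay.

    ``t``/``y``: trial-averaged density on the analysis window (1 ms grid);
    ``trial_matrix`` (trials x time): used for the 2-STE bound; without it the
    80%-of-peak bound alone delimits the fluctuation period.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    dt = float(t[1] - t[0])
    mm, c0, width = _moving_mean_series(y, dt)
    peak_j = mm.size - 1 - int(np.argmax(mm[::-1]))   # ties -> latest window
    peak_val = float(mm[peak_j])
    # peak point: last maximal raw sample inside the winning 20 ms window
    win = y[peak_j:peak_j + width]
    peak_idx = peak_j + (win.size - 1 - int(np.argmax(win[::-1])))

    if peak_idx >= y.size - MIN_FIT_POINTS or peak_j >= mm.size - 1:
        return ChangePointResult("decay", None, alignment, None, None, 0,
                                 reason="no decay after the peak")
    # end point: lowest 20 ms bin after the peak (raw minimum inside it)
    end_j = peak_j + 1 + int(np.argmin(mm[peak_j + 1:]))
    end_win = y[end_j:end_j + width]
    end_idx = end_j + int(np.argmin(end_win))
    ste = _window_ste(trial_matrix, peak_idx, width)
    bound = max(peak_val - 2.0 * ste, 0.8 * peak_val)
    below = np.nonzero(mm[peak_j + 1:end_j + 1] < bound)[0]
    if below.size == 0:
        return ChangePointResult("decay", None, alignment,
                                 None, None, 0, reason="activity never leaves the peak")
    # refine the crossing on raw samples around the crossing bin
    j = peak_j + 1 + int(below[0])
    lo = max(peak_idx + 1, j + c0 - width)
    hi = min(j + c0 + width, end_idx + 1)
    raw_below = np.nonzero(y[lo:hi] < bound)[0]
    fluct_end = lo + int(raw_below[0]) if raw_below.size else j + c0
    fluct_end = min(max(fluct_end, peak_idx), end_idx)
    candidates = range(peak_idx, fluct_end + 1)
    winner, n_eval = _select_start(t, y, candidates, end_idx, "decay")
    if winner is None:
        return ChangePointResult("decay", None, alignment,
                                 (float(t[peak_idx]), float(t[fluct_end])),
                                 None, 0, reason="fluctuation period too short")
    c, a1, a2, a3, mse = winner
    fit = ExponentialFit(a1, a2, a3, float(t[c]), mse)
    return ChangePointResult("decay", float(t[c]), alignment,
                             (float(t[peak_idx]), float(t[fluct_end])),
                             fit, n_eval)


def estimate_rise_time(t, y, trial_matrix=None, baseline: float | None = None,
                       alignment: str = "saccade_end") -> ChangePointResult:
    """Change point where activity starts its exponential increase.

    Mirror procedure: peak by 20 ms moving mean; lowest point before the peak;
    fluctuation period from the lowest point to the last pre-peak sample below
    (lowest + 2 STE) or (baseline + 2 STE); best exponential fit start (fits
    run from each candidate to the peak) is the rise time.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    dt = float(t[1] - t[0])
    mm, c0, width = _moving_mean_series(y, dt)
    peak_j = int(np.argmax(mm))                       # ties -> earliest window
    # peak point: first maximal raw sample inside the winning 20 ms window
    peak_idx = peak_j + int(np.argmax(y[peak_j:peak_j + width]))
    if peak_j < 2 or peak_idx < MIN_FIT_POINTS:
        return ChangePointResult("rise", None, alignment, None, None, 0,
                                 reason="no pre-peak segment")
    # lowest 20 ms bin before the peak
    trough_j = int(np.argmin(mm[:peak_j]))
    trough_idx = trough_j + c0
    trough_val = float(mm[trough_j])
    ste = _segment_ste(trial_matrix, peak_idx, width)
    eps = 1e-9 * (float(np.ptp(y)) or 1.0)
    bound = trough_val + 2.0 * ste
    if baseline is not None:
        bound = max(bound, baseline + 2.0 * ste)
    below = np.nonzero(mm[trough_j:peak_j] <= bound + eps)[0]
    if below.size == 0:
        return ChangePointResult("rise", None, alignment, None, None, 0,
                                 reason="no quiescent period before the peak")
    # refine the last below-bound point on raw samples within that bin
    j = trough_j + int(below[-1])
    hi = min(j + c0 + width, peak_idx)
    raw_below = np.nonzero(y[j + c0:hi] <= bound + eps)[0]
    fluct_end = j + c0 + int(raw_below[-1]) if raw_below.size else j + c0
    candidates = range(trough_idx, fluct_end + 1)
    winner, n_eval = _select_start(t, y, candidates, peak_idx, "rise")
    if winner is None:
        return ChangePointResult("rise", None, alignment,
                                 (float(t[trough_idx]), float(t[fluct_end])),
                                 None, 0, reason="fluctuation period too short")
    c, a1, a2, a3, mse = winner
    fit = ExponentialFit(a1, a2, a3, float(t[c]), mse)
    return ChangePointResult("rise", float(t[c]), alignment,
                             (float(t[trough_idx]), float(t[fluct_end])),
                             fit, n_eval)


def middle_point_of_change(t, y, kind: str) -> float:
    """Time at which a population trace crosses the midpoint of its change.

    ``kind="rise"``: halfway between the pre-peak trough and the peak;
    ``kind="decay"``: halfway between the peak and the post-peak trough.
    Linear interpolation between samples; raises if there is no crossing.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind == "rise":
        hi = int(np.argmax(y))
        if hi == 0:
            raise ValueError("no rise: trace peaks at its first sample")
        lo = int(np.argmin(y[:hi]))
        seg = slice(lo, hi + 1)
        target = 0.5 * (y[lo] + y[hi])
        above = np.nonzero(y[seg] >= target)[0]
        if above.size == 0:
            raise ValueError("no crossing of the midpoint")
        j = lo + int(above[0])
    elif kind == "decay":
        hi = int(np.argmax(y))
        if hi >= y.size - 1:
            raise ValueError("no decay: trace peaks at its last sample")
        lo = hi + int(np.argmin(y[hi:]))
        target = 0.5 * (y[hi] + y[lo])
        belows = np.nonzero(y[hi:lo + 1] <= target)[0]
        if belows.size == 0:
            raise ValueError("no crossing of the midpoint")
        j = hi + int(belows[0])
    else:
        raise ValueError("kind must be 'rise' or 'decay'")
    if j == 0 or y[j] == y[j - 1]:
        return float(t[j])
    # interpolate between the last sample on the near side and the crossing one
    f = (target - y[j - 1]) / (y[j] - y[j - 1])
    return float(t[j - 1] + f * (t[j] - t[j - 1]))
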