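"""The comparator analysis: end-position binning, single-trial correlations,
reference subtraction, piecewise regression, the subtraction model, and the
sliding-window error correlation.

All positions here are "motor coordinates": horizontal end positions of
preferred-direction trials, sign-flipped so the preferred target sits at
+eccentricity, which lets left- and right-preferring neurons pool.  Activities
are baseline-divided (dimensionless) per neuron before any pooling; the
reference condition (trials ending at the target) is subtracted bin-wise where
stated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .density import BASELINE_FLOOR, EPOCHS, epoch_rates


def saccadic_error(end_position_h, target: float):
    """|end position - target| on the horizontal meridian (degrees)."""
    return np.abs(np.asarray(end_position_h, dtype=float) - target)


@dataclass
class BinnedActivity:
    edges: np.ndarray        # len n_bins + 1, degrees
    centers: np.ndarray      # midpoints of the (possibly merged) bins
    counts: np.ndarray       # trials per bin
    mean: np.ndarray         # mean activity per bin
    sem: np.ndarray
    epoch: str = ""

    @property
    def n_bins(self) -> int:
        return self.centers.size


def make_bin_edges(positions, n_bins: int = 16) -> np.ndarray:
    """Equal-width edges spanning mean +- 3 SD of the end positions.

    Degenerate input (all positions identical) gets a single unit-width bin.
    """
    positions = np.asarray(positions, dtype=float)
    m = positions.mean()
    s = positions.std(ddof=1) if positions.size > 1 else 0.0
    if s == 0.0:
        return np.array([m - 0.5, m + 0.5])
    return np.linspace(m - 3 * s, m + 3 * s, n_bins + 1)


def bin_by_end_position(positions, activity, n_bins: int = 16,
                        min_trials: int = 5, edges=None,
                        epoch: str = "") -> BinnedActivity:
    """Group trials into end-position bins and average their activity.

    Bins span mean +- 3 SD (outliers are clipped into the edge bins, so counts
    always sum to the number of trials); bins with fewer than ``min_trials``
    are merged with their smaller adjacent neighbor until all bins qualify.
    """
    positions = np.asarray(positions, dtype=float)
    activity = np.asarray(activity, dtype=float)
    if positions.size != activity.size:
        raise ValueError("positions and activity must have equal length")
    if edges is None:
        edges = make_bin_edges(positions, n_bins)
    edges = np.asarray(edges, dtype=float)
    eps = 1e-9 * max(edges[-1] - edges[0], 1.0)
    clipped = np.clip(positions, edges[0], edges[-1] - eps)
    idx = np.digitize(clipped, edges) - 1

    groups = [list(np.nonzero(idx == k)[0]) for k in range(edges.size - 1)]
    bounds = [(edges[k], edges[k + 1]) for k in range(edges.size - 1)]
    while len(groups) > 1:
        sizes = [len(g) for g in groups]
        k = int(np.argmin(sizes))
        if sizes[k] >= min_trials:
            break
        if k == 0:
            j = 1
        elif k == len(groups) - 1:
            j = k - 1
        else:
            j = k - 1 if len(groups[k - 1]) <= len(groups[k + 1]) else k + 1
        lo, hi = min(k, j), max(k, j)
        groups[lo] = groups[lo] + groups[hi]
        bounds[lo] = (bounds[lo][0], bounds[hi][1])
        del groups[hi], bounds[hi]
    if len(groups) < 2:
        if sum(len(g) for g in groups) < min_trials:
            raise ValueError("fewer than 2 usable bins")
    merged_edges = np.array([b[0] for b in bounds] + [bounds[-1][1]])
    centers = 0.5 * (merged_edges[:-1] + merged_edges[1:])
    counts = np.array([len(g) for g in groups])
    mean = np.array([activity[g].mean() if g else np.nan for g in groups])
    sem = np.array([activity[g].std(ddof=1) / np.sqrt(len(g))
                    if len(g) > 1 else np.nan for g in groups])
    return BinnedActivity(merged_edges, centers, counts, mean, sem, epoch)


def reference_normalize(binned: BinnedActivity, target: float) -> BinnedActivity:
    """Subtract the target bin's mean activity from every bin.

    The reference condition is the bin containing the target position; its
    normalized activity is 0 by construction.  Idempotent.
    """
    k = reference_bin_index(binned, target)
    ref = binned.mean[k]
    return BinnedActivity(binned.edges.copy(), binned.centers.copy(),
                          binned.counts.copy(), binned.mean - ref,
                          binned.sem.copy(), binned.epoch)


def reference_bin_index(binned: BinnedActivity, target: float) -> int:
    e = binned.edges
    if not (e[0] <= target < e[-1]):
        raise ValueError(f"no bin covers the target position {target}")
    return int(np.searchsorted(e, target, side="right") - 1)


@dataclass
class CorrelationResult:
    r: np.ndarray            # per-neuron Pearson r
    p: np.ndarray            # per-neuron p
    neuron_ids: list
    excluded: list           # (neuron_id, reason)
    mean_r: float
    population_p: float      # one-sample t-test of r values against 0
    n_neurons: int


def single_trial_correlation(per_neuron: dict, min_trials: int = 30) -> CorrelationResult:
    """Per-neuron Pearson correlation of single-trial activity vs a covariate.

    ``per_neuron``: neuron_id -> (activity, covariate) paired arrays.  Neurons
    with fewer than ``min_trials`` trials or zero variance are excluded and
    reported.  The population test is a one-sample t-test of the per-neuron r
    values against 0.
    """
    rs, ps, ids, excluded = [], [], [], []
    for nid, (act, cov) in per_neuron.items():
        act = np.asarray(act, dtype=float)
        cov = np.asarray(cov, dtype=float)
        if act.size < min_trials:
            excluded.append((nid, f"only {act.size} trials"))
            continue
        if act.std() == 0 or cov.std() == 0:
            excluded.append((nid, "zero variance"))
            continue
        r, p = stats.pearsonr(act, cov)
        rs.append(r)
        ps.append(p)
        ids.append(nid)
    rs = np.asarray(rs)
    if rs.size >= 2:
        tstat, pop_p = stats.ttest_1samp(rs, 0.0)
    else:
        pop_p = np.nan
    return CorrelationResult(rs, np.asarray(ps), ids, excluded,
                             float(rs.mean()) if rs.size else np.nan,
                             float(pop_p), rs.size)


@dataclass
class LinearFit:
    slope: float
    intercept: float
    n_bins: int

    def __call__(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def weighted_linear_fit(x, y, w) -> LinearFit:
    """Count-weighted OLS line; bins with undefined means are dropped."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    w = np.atleast_1d(np.asarray(w, dtype=float))
    ok = np.isfinite(y) & (w > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 populated bins for a linear fit")
    coef = np.polyfit(x[ok], y[ok], 1, w=np.sqrt(w[ok]))
    return LinearFit(float(coef[0]), float(coef[1]), int(ok.sum()))


def piecewise_linear_fit(binned: BinnedActivity, split_at: float):
    """Count-weighted OLS on bin centers, separately below/above the split.

    Returns (fit_below, fit_above); a side with fewer than 2 bins is None.
    """
    ok = np.isfinite(binned.mean)
    lo = ok & (binned.centers < split_at)
    hi = ok & (binned.centers >= split_at)
    fits = []
    for mask in (lo, hi):
        if mask.sum() < 2:
            fits.append(None)
            continue
        fits.append(weighted_linear_fit(binned.centers[mask], binned.mean[mask],
                                        binned.counts[mask]))
    return tuple(fits)


@dataclass
class SubtractionModelResult:
    pps_peri_fit: LinearFit
    lps_post_fit: LinearFit
    predicted: np.ndarray          # |lps fit - pps fit| on the bin centers
    observed: np.ndarray           # post-subtraction bin means
    centers: np.ndarray
    hypo_fit: LinearFit | None     # piecewise fits of the observed signal
    hyper_fit: LinearFit | None
    agreement_rms: float


def subtraction_model(pps_peri: BinnedActivity, lps_post: BinnedActivity,
                      pps_postsub: BinnedActivity,
                      split_at: float) -> SubtractionModelResult:
    """Compare observed post-subtraction activity with |LPS - PPS| fits.

    All three inputs must be reference-normalized on a common bin grid.  The
    prediction is the absolute difference of the two (count-weighted) linear
    fits evaluated on the bin centers; agreement is the RMS deviation from the
    observed post-subtraction bin means.
    """
    for other in (lps_post, pps_postsub):
        if not np.allclose(pps_peri.edges, other.edges):
            raise ValueError("binned activities are not on a common grid")
    pfit = weighted_linear_fit(pps_peri.centers, pps_peri.mean, pps_peri.counts)
    lfit = weighted_linear_fit(lps_post.centers, lps_post.mean, lps_post.counts)
    centers = pps_postsub.centers
    predicted = np.abs(lfit(centers) - pfit(centers))
    observed = pps_postsub.mean
    hypo, hyper = piecewise_linear_fit(pps_postsub, split_at)
    ok = np.isfinite(observed)
    rms = float(np.sqrt(np.mean((predicted[ok] - observed[ok]) ** 2)))
    return SubtractionModelResult(pfit, lfit, predicted, observed, centers,
                                  hypo, hyper, rms)


def sliding_window_error_correlation(per_neuron, window_ms: float = 100.0,
                                     step_ms: float = 10.0,
                                     span=(0.0, 450.0), min_trials: int = 30):
    """Mean correlation of post-saccadic activity with |error| over time.

    ``per_neuron``: neuron_id -> (spike_trains, align_times, errors, baseline)
    where spike trains are per preferred-direction trial, alignment is the
    saccade end, and ``baseline`` is the neuron's mean baseline rate.  Windows
    ``[s, s + window)`` slide from span[0] until span[1]; each is stamped by
    its midpoint.  Returns a dict of arrays: t_mid, mean_r, p, n_neurons.
    """
    starts = np.arange(span[0], span[1] - window_ms + step_ms / 2, step_ms)
    t_mid = starts + window_ms / 2
    mean_r = np.full(starts.size, np.nan)
    pop_p = np.full(starts.size, np.nan)
    n_used = np.zeros(starts.size, dtype=int)
    for k, s in enumerate(starts):
        per = {}
        for nid, (trains, aligns, errors, baseline) in per_neuron.items():
            act = epoch_rates(trains, (s, s + window_ms), aligns)
            act = act / max(baseline, BASELINE_FLOOR)
            per[nid] = (act, errors)
        res = single_trial_correlation(per, min_trials=min_trials)
        mean_r[k] = res.mean_r
        pop_p[k] = res.population_p
        n_used[k] = res.n_neurons
    return {"t_mid": t_mid, "mean_r": mean_r, "p": pop_p, "n_neurons": n_used}
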