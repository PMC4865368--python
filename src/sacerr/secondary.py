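"""Coupling between post-subtraction PPS activity and corrective saccades.

Trials that pass the primary-saccade filters are partitioned with the same
end-position bins as the comparator analysis, so per-bin secondary-saccade
probability and per-bin post-subtraction activity are computed on identical
partitions.  Secondary saccades of any direction count; the fraction directed
toward the target is reported descriptively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .error_analysis import BinnedActivity, bin_by_end_position, piecewise_linear_fit


@dataclass
class SecondaryStats:
    edges: np.ndarray
    centers: np.ndarray
    n_with: np.ndarray            # trials with a secondary saccade, per bin
    n_without: np.ndarray
    probability: np.ndarray       # empirical P(secondary) per bin
    mean_activity: np.ndarray     # post-subtraction activity per bin
    activity_with: np.ndarray     # split by secondary presence
    activity_without: np.ndarray
    compare_p: np.ndarray         # per-bin rank-sum p (NaN if untestable)
    hypo_fit: object              # piecewise fits of probability vs position
    hyper_fit: object
    toward_target_fraction: float


def secondary_probability_by_bin(positions, has_secondary, activity, edges,
                                 split_at: float, min_trials: int = 5,
                                 toward_target_fraction: float = np.nan) -> SecondaryStats:
    """Per-bin secondary-saccade probability and activity split.

    ``positions``: horizontal end positions (motor coordinates) of included
    trials; ``has_secondary``: boolean per trial; ``activity``: per-trial
    post-subtraction activity (pooled across PPS neurons).  ``edges`` should
    come from the comparator analysis so both use one partition.
    """
    positions = np.asarray(positions, dtype=float)
    has_secondary = np.asarray(has_secondary, dtype=bool)
    activity = np.asarray(activity, dtype=float)
    binned = bin_by_end_position(positions, activity, min_trials=min_trials,
                                 edges=edges, epoch="post_subtraction")
    e = binned.edges
    eps = 1e-9 * max(e[-1] - e[0], 1.0)
    idx = np.digitize(np.clip(positions, e[0], e[-1] - eps), e) - 1

    nb = binned.n_bins
    n_with = np.zeros(nb, dtype=int)
    n_without = np.zeros(nb, dtype=int)
    act_with = np.full(nb, np.nan)
    act_without = np.full(nb, np.nan)
    comp_p = np.full(nb, np.nan)
    for k in range(nb):
        sel = idx == k
        w = activity[sel & has_secondary]
        wo = activity[sel & ~has_secondary]
        n_with[k], n_without[k] = w.size, wo.size
        if w.size:
            act_with[k] = w.mean()
        if wo.size:
            act_without[k] = wo.mean()
        if w.size and wo.size:
            _, comp_p[k] = stats.ranksums(w, wo)
    prob = n_with / np.maximum(n_with + n_without, 1)
    prob_binned = BinnedActivity(binned.edges, binned.centers, binned.counts,
                                 prob, np.full(nb, np.nan))
    hypo, hyper = piecewise_linear_fit(prob_binned, split_at)
    return SecondaryStats(binned.edges, binned.centers, n_with, n_without,
                          prob, binned.mean, act_with, act_without, comp_p,
                          hypo, hyper, toward_target_fraction)


def correlate_activity_with_probability(stats_: SecondaryStats):
    """Pearson r across bins between post-subtraction activity and P(secondary)."""
    ok = np.isfinite(stats_.mean_activity) & np.isfinite(stats_.probability)
    if ok.sum() < 4:
        raise ValueError("need at least 4 bins")
    a, p = stats_.mean_activity[ok], stats_.probability[ok]
    if a.std() == 0 or p.std() == 0:
        return np.nan, np.nan
    r, pv = stats.pearsonr(a, p)
    return float(r), float(pv)


def compare_with_without_secondary(stats_: SecondaryStats, alpha: float = 0.05):
    """Summary of the per-bin with-vs-without activity comparison.

    Returns (n_testable, n_with_higher, n_significant): bins where both
    subgroups are non-empty; where the with-secondary mean is at least the
    without-secondary mean; and where the rank-sum test rejects at ``alpha``.
    """
    testable = (stats_.n_with > 0) & (stats_.n_without > 0)
    higher = testable & (stats_.activity_with >= stats_.activity_without)
    sig = testable & (stats_.compare_p < alpha)
    return int(testable.sum()), int(higher.sum()), int(sig.sum())
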