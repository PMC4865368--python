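"""End-to-end glue: detection -> classification -> comparator -> secondary.

These functions operate on a :class:`~sacerr.io.Session` and plain DataFrames
so each stage can also be run (and tested) in isolation.  Neuron labels may
come from :func:`classify_all` or from generator ground truth -- the analysis
stages only need (neuron_id, label, preferred_direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify as cl
from . import error_analysis as ea
from . import secondary as sec
from .density import BASELINE_FLOOR, EPOCHS, epoch_rates
from .io import Session
from .kinematics import (KinematicsConfig, apply_trial_filters, compute_velocity,
                         detect_primary_saccade, detect_secondary_saccades)


def detect_saccades(session: Session,
                    config: KinematicsConfig = KinematicsConfig()) -> pd.DataFrame:
    """Detect primary/secondary saccades and apply the inclusion filters.

    Returns one row per trial; also updates each trial's ``included`` state.
    """
    rows = []
    for tr in session.trials:
        speed = compute_velocity(tr.eye, config)
        primary = detect_primary_saccade(tr.eye, tr.events["fp_offset"], config,
                                         speed=speed)
        outcome = apply_trial_filters(primary, (tr.target_x, tr.target_y), config)
        secondaries = (detect_secondary_saccades(tr.eye, primary, config, speed=speed)
                       if primary is not None else [])
        tr.included = "pass" if outcome.passed else "fail"
        tr.included_reasons = tuple(sorted(outcome.failed_rules))
        rows.append(dict(
            trial_id=tr.trial_id, direction=tr.direction,
            onset_ms=primary.onset if primary else np.nan,
            offset_ms=primary.offset if primary else np.nan,
            duration_ms=primary.duration if primary else np.nan,
            amplitude_deg=primary.amplitude if primary else np.nan,
            peak_velocity_dps=primary.peak_velocity if primary else np.nan,
            latency_ms=primary.latency if primary else np.nan,
            end_x_deg=primary.end_position[0] if primary else np.nan,
            end_y_deg=primary.end_position[1] if primary else np.nan,
            passed=outcome.passed,
            failed_rules=";".join(sorted(outcome.failed_rules)),
            n_secondary=len(secondaries),
            has_secondary=len(secondaries) > 0,
            first_secondary_onset_ms=secondaries[0].onset if secondaries else np.nan,
        ))
    return pd.DataFrame(rows)


def _included(saccades: pd.DataFrame) -> pd.DataFrame:
    return saccades[saccades["passed"]].reset_index(drop=True)


def _direction_bundles(session: Session, saccades: pd.DataFrame, neuron_id: str):
    incl = _included(saccades)
    by_id = {t.trial_id: t for t in session.trials}
    trains, onsets, ends = {}, {}, {}
    for d in ("left", "right"):
        sub = incl[incl["direction"] == d]
        trains[d] = [by_id[tid].spike_trains[neuron_id] for tid in sub["trial_id"]]
        onsets[d] = sub["onset_ms"].to_numpy()
        ends[d] = sub["offset_ms"].to_numpy()
    return trains, onsets, ends


def classify_all(session: Session, saccades: pd.DataFrame):
    """Classify every neuron; returns (labels DataFrame, list of NeuronLabel)."""
    labels, rows = [], []
    for nid in session.neuron_ids:
        trains, onsets, ends = _direction_bundles(session, saccades, nid)
        rates = cl.collect_rates(trains, onsets, ends)
        lab = cl.classify_neuron(nid, rates)
        labels.append(lab)
        for ruleset in (lab.pps_criteria, lab.lps_criteria):
            for rule, c in ruleset.items():
                rows.append(dict(
                    neuron_id=nid, label=lab.label,
                    preferred_direction=lab.preferred_direction,
                    n_preferred_trials=lab.n_preferred_trials,
                    rule=rule, passed=c.passed, statistic=c.statistic, p=c.p))
    return pd.DataFrame(rows), labels


def labels_to_frame(labels) -> pd.DataFrame:
    """Compact one-row-per-neuron table from NeuronLabel objects."""
    return pd.DataFrame([dict(
        neuron_id=l.neuron_id, label=l.label,
        preferred_direction=l.preferred_direction,
        n_preferred_trials=l.n_preferred_trials,
        decay_ms=l.decay.time_ms if l.decay is not None and l.decay.found else np.nan,
        rise_ms=l.rise.time_ms if l.rise is not None and l.rise.found else np.nan,
    ) for l in labels])


def labels_from_ground_truth(gt) -> pd.DataFrame:
    """Neuron-info table from generator ground truth (class + preference)."""
    df = gt.neurons.copy()
    df["label"] = df["true_class"].map({"PPS": "PPS", "LPS": "LPS"}).fillna("neither")
    return df[["neuron_id", "label", "preferred_direction"]]


@dataclass
class NeuronTrialData:
    """Preferred-direction included trials of one neuron, analysis-ready."""

    neuron_id: str
    label: str
    trial_ids: list
    trains: list
    onsets: np.ndarray
    ends: np.ndarray
    positions: np.ndarray      # motor coordinates, degrees
    errors: np.ndarray
    amplitudes: np.ndarray
    baseline: float            # mean rate in the normalization baseline window


def neuron_trial_data(session: Session, saccades: pd.DataFrame,
                      neuron_info: pd.DataFrame) -> list:
    """Assemble per-neuron preferred-direction data for PPS/LPS neurons."""
    incl = _included(saccades)
    by_id = {t.trial_id: t for t in session.trials}
    base_w, _ = EPOCHS["baseline_norm"]
    out = []
    for _, row in neuron_info.iterrows():
        if row["label"] not in ("PPS", "LPS"):
            continue
        d = row["preferred_direction"]
        sign = 1.0 if d == "right" else -1.0
        sub = incl[incl["direction"] == d]
        trials = [by_id[tid] for tid in sub["trial_id"]]
        trains = [t.spike_trains[row["neuron_id"]] for t in trials]
        fix = np.array([t.events["fixation_onset"] for t in trials])
        baseline = float(np.mean(epoch_rates(trains, base_w, fix))) if trains else np.nan
        out.append(NeuronTrialData(
            neuron_id=row["neuron_id"], label=row["label"],
            trial_ids=list(sub["trial_id"]), trains=trains,
            onsets=sub["onset_ms"].to_numpy(), ends=sub["offset_ms"].to_numpy(),
            positions=sign * sub["end_x_deg"].to_numpy(),
            errors=np.abs(sign * sub["end_x_deg"].to_numpy()
                          - abs(by_id[sub["trial_id"].iloc[0]].target_x))
            if len(sub) else np.empty(0),
            amplitudes=sub["amplitude_deg"].to_numpy(), baseline=baseline))
    return out


def estimate_changepoints(session: Session, saccades: pd.DataFrame,
                          neuron_info: pd.DataFrame) -> pd.DataFrame:
    """Decay (PPS) / rise (LPS) time estimates for every labeled neuron."""
    from . import changepoint as cp
    from .density import mean_density

    rows = []
    for d in neuron_trial_data(session, saccades, neuron_info):
        t, m, mat = mean_density(d.trains, d.ends, cp.FIT_WINDOWS["saccade_end"])
        if d.label == "PPS":
            res = cp.estimate_decay_time(t, m, mat)
        else:
            res = cp.estimate_rise_time(t, m, mat, baseline=d.baseline)
        fit = res.fit
        rows.append(dict(
            neuron_id=d.neuron_id, kind=res.kind,
            time_ms=res.time_ms if res.found else np.nan,
            A1=fit.A1 if fit else np.nan, A2=fit.A2 if fit else np.nan,
            A3=fit.A3 if fit else np.nan,
            residual=fit.residual if fit else np.nan,
            candidates_evaluated=res.candidates_evaluated))
    return pd.DataFrame(rows)


@dataclass
class ComparatorResult:
    target: float
    edges: np.ndarray
    peri_corr: ea.CorrelationResult          # PPS perisaccadic vs end position
    lps_corr: ea.CorrelationResult           # LPS post-saccadic vs end position
    postsub_err_corr: ea.CorrelationResult   # PPS post-subtraction vs |error|
    postsub_pos_corr: ea.CorrelationResult   # ... vs signed end position
    postsub_amp_corr: ea.CorrelationResult   # ... vs amplitude
    binned_pps_peri: ea.BinnedActivity       # reference-normalized
    binned_lps_post: ea.BinnedActivity
    binned_pps_postsub: ea.BinnedActivity
    model: ea.SubtractionModelResult
    trial_ids: list                          # per unique included pref-dir trial
    trial_positions: np.ndarray
    trial_postsub: np.ndarray                # pooled normalized activity


def _norm_epoch(nd: NeuronTrialData, epoch: str) -> np.ndarray:
    w, _ = EPOCHS[epoch]
    return epoch_rates(nd.trains, w, nd.ends if epoch != "pre_saccadic" else nd.onsets) \
        / max(nd.baseline, BASELINE_FLOOR)


def comparator_analysis(session: Session, saccades: pd.DataFrame,
                        neuron_info: pd.DataFrame, n_bins_pps: int = 16,
                        min_trials_per_bin: int = 5,
                        min_trials_corr: int = 30) -> ComparatorResult:
    """Figure-4-style comparator analysis on one session.

    Pools preferred-direction included trials across neurons in motor
    coordinates.  PPS perisaccadic and post-subtraction activities and the
    LPS post-saccadic activity are baseline-divided, binned on a common
    end-position grid, reference-subtracted, and compared via the
    subtraction model.
    """
    data = neuron_trial_data(session, saccades, neuron_info)
    pps = [d for d in data if d.label == "PPS"]
    lps = [d for d in data if d.label == "LPS"]
    if not pps:
        raise ValueError("no PPS neurons to analyze")
    target = float(np.mean([abs(t.target_x) for t in session.trials]))

    peri = {d.neuron_id: (_norm_epoch(d, "perisaccadic"), d.positions) for d in pps}
    postsub = {d.neuron_id: _norm_epoch(d, "post_subtraction") for d in pps}
    lpost = {d.neuron_id: (_norm_epoch(d, "lps_corr"), d.positions) for d in lps}

    peri_corr = ea.single_trial_correlation(peri, min_trials_corr)
    lps_corr = ea.single_trial_correlation(lpost, min_trials_corr)
    postsub_err = ea.single_trial_correlation(
        {n: (postsub[n], d.errors) for n, d in zip(postsub, pps)}, min_trials_corr)
    postsub_pos = ea.single_trial_correlation(
        {n: (postsub[n], d.positions) for n, d in zip(postsub, pps)}, min_trials_corr)
    postsub_amp = ea.single_trial_correlation(
        {n: (postsub[n], d.amplitudes) for n, d in zip(postsub, pps)}, min_trials_corr)

    # common bin grid: edges from the pooled positions, merged once on
    # trial-level counts so every binned quantity shares one partition
    all_pos = np.concatenate([d.positions for d in pps])
    raw_edges = ea.make_bin_edges(all_pos, n_bins_pps)
    trial_pos = {}
    for d in pps + lps:
        for tid, pos_ in zip(d.trial_ids, d.positions):
            trial_pos[tid] = pos_
    tp = np.array(list(trial_pos.values()))
    base_bins = ea.bin_by_end_position(tp, np.zeros_like(tp),
                                       min_trials=min_trials_per_bin,
                                       edges=raw_edges)
    edges = base_bins.edges

    def pooled(datas, values_by_id, epoch):
        pos = np.concatenate([d.positions for d in datas])
        act = np.concatenate([values_by_id[d.neuron_id] for d in datas])
        b = ea.bin_by_end_position(pos, act, min_trials=0, edges=edges,
                                   epoch=epoch)
        return ea.reference_normalize(b, target)

    b_peri = pooled(pps, {k: v[0] for k, v in peri.items()}, "perisaccadic")
    b_post = pooled(pps, postsub, "post_subtraction")
    b_lps = pooled(lps, {k: v[0] for k, v in lpost.items()}, "lps_corr") if lps \
        else None
    if b_lps is None:
        raise ValueError("no LPS neurons to analyze")
    model = ea.subtraction_model(b_peri, b_lps, b_post, split_at=target)

    # pooled per-trial post-subtraction activity for the secondary analysis
    per_trial = {}
    for d, acts in zip(pps, postsub.values()):
        for tid, pos_, a in zip(d.trial_ids, d.positions, acts):
            per_trial.setdefault(tid, (pos_, []))[1].append(a)
    tids = sorted(per_trial)
    positions = np.array([per_trial[t][0] for t in tids])
    activity = np.array([np.mean(per_trial[t][1]) for t in tids])

    return ComparatorResult(
        target=target, edges=edges, peri_corr=peri_corr, lps_corr=lps_corr,
        postsub_err_corr=postsub_err, postsub_pos_corr=postsub_pos,
        postsub_amp_corr=postsub_amp, binned_pps_peri=b_peri,
        binned_lps_post=b_lps, binned_pps_postsub=b_post, model=model,
        trial_ids=tids, trial_positions=positions, trial_postsub=activity)


def sliding_error_correlation(session: Session, saccades: pd.DataFrame,
                              neuron_info: pd.DataFrame, **kw):
    """Sliding-window correlation of PPS activity with |error| (Fig-4-fs1 style)."""
    data = neuron_trial_data(session, saccades, neuron_info)
    per = {d.neuron_id: (d.trains, d.ends, d.errors, d.baseline)
           for d in data if d.label == "PPS"}
    return ea.sliding_window_error_correlation(per, **kw)


def secondary_analysis(session: Session, saccades: pd.DataFrame,
                       comp: ComparatorResult,
                       min_trials_per_bin: int = 30) -> sec.SecondaryStats:
    """Fig-5-style secondary-saccade statistics on the comparator's bins.

    Starts from the comparator's bin edges; bins are merged up to
    ``min_trials_per_bin`` trials (default 30 -- higher than the activity
    analyses because an empirical probability needs a real denominator).
    """
    incl = _included(saccades).set_index("trial_id")
    has_sec = incl.loc[comp.trial_ids, "has_secondary"].to_numpy(dtype=bool)
    # post-subtraction activity, reference-normalized like the binned curves
    b = ea.bin_by_end_position(comp.trial_positions, comp.trial_postsub,
                               min_trials=min_trials_per_bin, edges=comp.edges)
    ref = b.mean[ea.reference_bin_index(b, comp.target)]
    return sec.secondary_probability_by_bin(
        comp.trial_positions, has_sec, comp.trial_postsub - ref,
        edges=comp.edges, split_at=comp.target, min_trials=min_trials_per_bin)
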