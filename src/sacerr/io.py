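"""Trial-structured session container and result tables.

A :class:`Session` holds everything recorded in one experimental session:
1 kHz horizontal/vertical eye traces, per-neuron spike trains and behavioral
event times for every trial, plus task metadata.  Sessions round-trip through
an HDF5 layout::

    /                     attrs: schema_version, session_id, task, sampling_rate
    /neurons              dataset of neuron ids (bytes)
    /trials/<id>/         attrs: trial_id, direction, target_x, target_y,
                                 included, included_reasons
    /trials/<id>/eye/x    float64 (degrees), attrs: t0, dt
    /trials/<id>/eye/y    float64 (degrees)
    /trials/<id>/events   compound dataset (name, time_ms)
    /trials/<id>/spikes/<neuron_id>   float64 spike times (ms from trial start)

All times are milliseconds from trial start (floats); analysis windows are
half-open ``[a, b)``.  Positive x is rightward, positive y upward; left-target
positions are negative.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = "sacerr-session-1"

TASKS = ("SCS_horizontal", "SCS_oblique", "MGS", "CCS")
DIRECTIONS = ("left", "right")

#: events that every trial must define, in their required temporal order
MANDATORY_EVENTS = ("fixation_onset", "target_onset", "cue_on", "cue_off", "fp_offset")


class SessionFormatError(ValueError):
    """Raised when a session container violates the layout or its invariants."""


@dataclass
class EyeTrace:
    """Uniformly sampled 2D eye position, degrees, 1 kHz by default."""

    t0: float
    dt: float
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def validate(self, where: str = "") -> None:
        if self.x.size == 0 or self.x.shape != self.y.shape:
            raise SessionFormatError(f"{where}: eye trace empty or x/y length mismatch")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise SessionFormatError(f"{where}: non-finite eye trace samples")
        if self.dt <= 0:
            raise SessionFormatError(f"{where}: non-positive dt")


@dataclass
class Trial:
    trial_id: str
    direction: str                      # "left" | "right"
    target_x: float                     # degrees, signed
    target_y: float
    events: dict                        # name -> ms from trial start
    eye: EyeTrace
    spike_trains: dict = field(default_factory=dict)   # neuron_id -> np.ndarray
    included: str = "untested"          # "untested" | "pass" | "fail"
    included_reasons: tuple = ()

    def validate(self, neuron_ids=None) -> None:
        w = f"trial {self.trial_id}"
        if self.direction not in DIRECTIONS:
            raise SessionFormatError(f"{w}: bad direction {self.direction!r}")
        missing = [e for e in MANDATORY_EVENTS if e not in self.events]
        if missing:
            raise SessionFormatError(f"{w}: missing mandatory events {missing}")
        times = [self.events[e] for e in MANDATORY_EVENTS]
        if not all(b > a for a, b in zip(times, times[1:])):
            raise SessionFormatError(f"{w}: event times not strictly increasing")
        self.eye.validate(w)
        t_end = self.eye.t0 + self.eye.dt * (self.eye.n - 1)
        if max(times) > t_end:
            raise SessionFormatError(f"{w}: eye trace does not span all events")
        for nid, st in self.spike_trains.items():
            st = np.asarray(st, dtype=float)
            if st.size and (np.any(np.diff(st) < 0)):
                raise SessionFormatError(f"{w}: spike train {nid} not sorted")
            if st.size and (st[0] < self.eye.t0 or st[-1] > t_end + self.eye.dt):
                raise SessionFormatError(f"{w}: spike train {nid} outside trial bounds")
        if neuron_ids is not None:
            extra = set(self.spike_trains) - set(neuron_ids)
            if extra:
                raise SessionFormatError(f"{w}: spike trains for unknown neurons {sorted(extra)}")


@dataclass
class NeuronRecord:
    neuron_id: str


@dataclass
class Session:
    session_id: str
    task: str
    sampling_rate: float
    trials: list
    neurons: list

    @property
    def neuron_ids(self):
        return [n.neuron_id for n in self.neurons]

    def validate(self) -> None:
        if self.task not in TASKS:
            raise SessionFormatError(f"unknown task {self.task!r}")
        ids = self.neuron_ids
        if len(set(ids)) != len(ids):
            raise SessionFormatError("duplicate neuron ids")
        tids = [t.trial_id for t in self.trials]
        if len(set(tids)) != len(tids):
            raise SessionFormatError("duplicate trial ids")
        for t in self.trials:
            if abs(1000.0 / t.eye.dt - self.sampling_rate) > 1e-9:
                raise SessionFormatError(
                    f"trial {t.trial_id}: eye dt inconsistent with session sampling rate")
            t.validate(ids)


def sessions_equal(a: Session, b: Session) -> bool:
    """Exact (bit-level on arrays) equality of two sessions, field by field."""
    if (a.session_id, a.task, a.sampling_rate) != (b.session_id, b.task, b.sampling_rate):
        return False
    if a.neuron_ids != b.neuron_ids or len(a.trials) != len(b.trials):
        return False
    for ta, tb in zip(a.trials, b.trials):
        if (ta.trial_id, ta.direction, ta.target_x, ta.target_y,
                ta.included, tuple(ta.included_reasons)) != \
           (tb.trial_id, tb.direction, tb.target_x, tb.target_y,
                tb.included, tuple(tb.included_reasons)):
            return False
        if ta.events != tb.events:
            return False
        if ta.eye.t0 != tb.eye.t0 or ta.eye.dt != tb.eye.dt:
            return False
        if not (np.array_equal(ta.eye.x, tb.eye.x) and np.array_equal(ta.eye.y, tb.eye.y)):
            return False
        if set(ta.spike_trains) != set(tb.spike_trains):
            return False
        for nid in ta.spike_trains:
            if not np.array_equal(ta.spike_trains[nid], tb.spike_trains[nid]):
                return False
    return True


_EVENT_DTYPE = np.dtype([("name", "S32"), ("time", "f8")])


def write_session(session: Session, path, force: bool = False) -> None:
    """Write a validated session to HDF5.  Refuses to overwrite unless ``force``."""
    path = os.fspath(path)
    if os.path.exists(path) and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    session.validate()
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["session_id"] = session.session_id
        f.attrs["task"] = session.task
        f.attrs["sampling_rate"] = session.sampling_rate
        f.create_dataset(
            "neurons",
            data=np.array([n.encode() for n in session.neuron_ids], dtype="S64"),
            track_times=False)
        trials = f.create_group("trials")
        for tr in session.trials:
            g = trials.create_group(tr.trial_id)
            g.attrs["direction"] = tr.direction
            g.attrs["target_x"] = tr.target_x
            g.attrs["target_y"] = tr.target_y
            g.attrs["included"] = tr.included
            g.attrs["included_reasons"] = ",".join(tr.included_reasons)
            eye = g.create_group("eye")
            eye.attrs["t0"] = tr.eye.t0
            eye.attrs["dt"] = tr.eye.dt
            eye.create_dataset("x", data=tr.eye.x, track_times=False)
            eye.create_dataset("y", data=tr.eye.y, track_times=False)
            ev = np.array(
                sorted(((k.encode(), v) for k, v in tr.events.items()), key=lambda p: p[1]),
                dtype=_EVENT_DTYPE)
            g.create_dataset("events", data=ev, track_times=False)
            spikes = g.create_group("spikes")
            for nid, st in tr.spike_trains.items():
                spikes.create_dataset(nid, data=np.asarray(st, dtype=float),
                                      track_times=False)


def read_session(path) -> Session:
    """Read and validate a session; invariant violations name the trial/neuron."""
    path = os.fspath(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SessionFormatError(
                f"unsupported schema version {version!r} (expected {SCHEMA_VERSION})")
        neurons = [NeuronRecord(x.decode()) for x in f["neurons"][()]]
        trials = []
        tgroup = f["trials"]
        for tid in sorted(tgroup, key=_trial_sort_key):
            g = tgroup[tid]
            ev = {r["name"].decode(): float(r["time"]) for r in g["events"][()]}
            eye = EyeTrace(float(g["eye"].attrs["t0"]), float(g["eye"].attrs["dt"]),
                           g["eye/x"][()], g["eye/y"][()])
            reasons = tuple(r for r in g.attrs["included_reasons"].split(",") if r)
            spikes = {nid: g["spikes"][nid][()] for nid in g["spikes"]}
            trials.append(Trial(
                trial_id=tid, direction=g.attrs["direction"],
                target_x=float(g.attrs["target_x"]), target_y=float(g.attrs["target_y"]),
                events=ev, eye=eye, spike_trains=spikes,
                included=g.attrs["included"], included_reasons=reasons))
        session = Session(
            session_id=f.attrs["session_id"], task=f.attrs["task"],
            sampling_rate=float(f.attrs["sampling_rate"]),
            trials=trials, neurons=neurons)
    session.validate()
    return session


def _trial_sort_key(tid: str):
    # trial ids are "t0003"-style in generated sessions; fall back to lexical
    tail = tid.lstrip("t")
    return (0, int(tail)) if tail.isdigit() else (1, tid)


# ---------------------------------------------------------------------------
# result tables

#: column dictionaries for the CSV result tables
RESULT_SCHEMAS = {
    "saccades": [
        "trial_id", "direction", "onset_ms", "offset_ms", "duration_ms",
        "amplitude_deg", "peak_velocity_dps", "latency_ms", "end_x_deg",
        "end_y_deg", "passed", "failed_rules", "n_secondary", "has_secondary",
        "first_secondary_onset_ms",
    ],
    "labels": [
        "neuron_id", "label", "preferred_direction", "n_preferred_trials",
        "rule", "passed", "statistic", "p",
    ],
    "changepoints": [
        "neuron_id", "kind", "time_ms", "A1", "A2", "A3", "residual",
        "candidates_evaluated",
    ],
    "correlations": [
        "analysis", "neuron_id", "r", "p", "n_trials",
    ],
    "binned": [
        "analysis", "bin_lo", "bin_hi", "bin_center", "n_trials",
        "mean_activity", "sem_activity",
    ],
}


def write_results(tables: dict, outdir) -> dict:
    """Write result DataFrames as CSV files with fixed, documented headers.

    ``tables`` maps a schema name from :data:`RESULT_SCHEMAS` to a DataFrame
    with (at least) the schema's columns.  NaN is written as an empty cell.
    Returns {name: path}.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        if name not in RESULT_SCHEMAS:
            raise KeyError(f"unknown result table {name!r}")
        cols = RESULT_SCHEMAS[name]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"table {name!r} missing columns {missing}")
        path = os.path.join(outdir, f"{name}.csv")
        df.loc[:, cols].to_csv(path, index=False, na_rep="")
        paths[name] = path
    return paths


def copy_session(session: Session) -> Session:
    """Deep-ish copy (arrays copied) used by tests that mutate sessions."""
    trials = [replace(
        t,
        events=dict(t.events),
        eye=EyeTrace(t.eye.t0, t.eye.dt, t.eye.x.copy(), t.eye.y.copy()),
        spike_trains={k: v.copy() for k, v in t.spike_trains.items()},
    ) for t in session.trials]
    return replace(session, trials=trials, neurons=list(session.neurons))
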