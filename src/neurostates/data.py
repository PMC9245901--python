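"""Domain types and on-disk formats for spike-train sessions.

A *session* is one recording: spike times for a handful of simultaneously
recorded neurons, a list of trials (each played in one role of the
hide-and-seek game), and human-tagged behavioral events inside each trial.
Events are either *points* (the game-phase markers: start, box open, jump
out, interaction, return transit, jump in, end) or *intervals* (free
behaviors such as darting).

On disk a session is a directory of UTF-8 CSV tables with header rows and
'.' decimals:

``spikes.csv``
    ``neuron_id,time_s``
``trials.csv``
    ``trial_id,role,start_s,end_s,failed``
``events.csv``
    ``trial_id,label,kind,start_s,end_s`` where ``kind`` is ``point`` or
    ``interval`` and ``end_s`` is empty for points.
``neurons.csv``
    ``neuron_id`` — written so silent neurons survive a round trip; on
    read it is optional and defaults to the neurons seen in ``spikes.csv``.

Times are seconds (float). Bins are 0-based and half-open,
``[t0 + i*w, t0 + (i+1)*w)``; a trailing partial bin is dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: Canonical order of the game-phase markers within a trial.
PHASE_ORDER = (
    "start",
    "box open",
    "jump out",
    "interaction",
    "return transit",
    "jump in",
    "end",
)

#: Phase markers expected for each role. "box open" exists only when the
#: recorded animal is seeking (the experimenter opens the start-box
#: remotely). Observing trials carry the phase markers of the observed game,
#: without "box open" (the observer has no closed start-box cue).
ROLE_PHASES: Mapping[str, Tuple[str, ...]] = {
    "seek": PHASE_ORDER,
    "hide": tuple(p for p in PHASE_ORDER if p != "box open"),
    "observing": tuple(p for p in PHASE_ORDER if p != "box open"),
}

ROLES = ("hide", "seek", "observing")


class FormatError(ValueError):
    """A session directory is missing a table or a table is malformed."""


class ValidationError(ValueError):
    """A domain-type invariant is violated."""


@dataclass
class Trial:
    """One trial of the game, with its role and tagged events.

    ``phase_points`` maps phase names to absolute times (seconds);
    ``behavior_intervals`` are ``(label, start_s, end_s)`` tuples for free
    behaviors. ``failed`` flags trials where the game broke down; it is
    carried through but ignored by all statistics.
    """

    trial_id: int
    role: str
    start_s: float
    end_s: float
    phase_points: Dict[str, float] = field(default_factory=dict)
    behavior_intervals: List[Tuple[str, float, float]] = field(default_factory=list)
    failed: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def validate(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"trial {self.trial_id}: unknown role {self.role!r}")
        if not (self.start_s < self.end_s):
            raise ValidationError(f"trial {self.trial_id}: start_s must precede end_s")
        for name, t in self.phase_points.items():
            if name not in PHASE_ORDER:
                raise ValidationError(f"trial {self.trial_id}: unknown phase {name!r}")
            if not (self.start_s <= t <= self.end_s):
                raise ValidationError(
                    f"trial {self.trial_id}: phase {name!r} at {t} outside trial"
                )
        if "box open" in self.phase_points and self.role != "seek":
            raise ValidationError(
                f"trial {self.trial_id}: 'box open' tagged in a {self.role} trial"
            )
        order = [self.phase_points[p] for p in PHASE_ORDER if p in self.phase_points]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValidationError(
                f"trial {self.trial_id}: phase points violate the game order"
            )
        for label, a, b in self.behavior_intervals:
            if not (self.start_s <= a <= b <= self.end_s):
                raise ValidationError(
                    f"trial {self.trial_id}: interval {label!r} [{a}, {b}] outside trial"
                )

    def phase_offsets(self) -> Dict[str, float]:
        """Phase times relative to trial start."""
        return {k: v - self.start_s for k, v in self.phase_points.items()}


@dataclass
class BinnedTrial:
    """Spike counts of one trial on a uniform bin grid (neurons x bins)."""

    trial_id: int
    counts: np.ndarray
    bin_width_s: float
    t0: float

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def bin_centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.n_bins) + 0.5) * self.bin_width_s

    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise ValidationError("counts must be 2-D (neurons x bins)")
        if np.any(self.counts < 0):
            raise ValidationError("negative spike count")


@dataclass
class SpikeSession:
    """All data of one recording session."""

    session_id: str
    neurons: List[int]
    spikes: List[Tuple[int, float]]
    trials: List[Trial]

    @property
    def role_set(self) -> set:
        return {t.role for t in self.trials}

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def trial(self, trial_id: int) -> Trial:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(f"no trial with id {trial_id}")

    def trials_of_role(self, role: str) -> List[Trial]:
        return [t for t in self.trials if t.role == role]

    def spike_times(self, neuron_id: int) -> np.ndarray:
        return np.array(
            sorted(t for n, t in self.spikes if n == neuron_id), dtype=float
        )

    def validate(self) -> None:
        neuron_set = set(self.neurons)
        for n, t in self.spikes:
            if not (math.isfinite(t) and t >= 0):
                raise ValidationError(f"spike time {t!r} not finite and non-negative")
            if n not in neuron_set:
                raise ValidationError(f"spike references unknown neuron {n!r}")
        prev_end = -math.inf
        for tr in sorted(self.trials, key=lambda t: t.start_s):
            tr.validate()
            if tr.start_s < prev_end:
                raise ValidationError(f"trial {tr.trial_id} overlaps the previous trial")
            prev_end = tr.end_s
        self.trials.sort(key=lambda t: t.start_s)


# ---------------------------------------------------------------------------
# Segmentations


@dataclass
class Segmentation:
    """Per-trial label vectors over time bins — the common currency of all
    correspondence statistics.

    ``labels`` maps trial_id -> 1-D array of hashable labels, one per bin.
    The run-length form (``segments``) and the vector form are mutually
    convertible without loss.
    """

    bin_width_s: float
    labels: Dict[int, np.ndarray]

    def trial_ids(self) -> List[int]:
        return list(self.labels.keys())

    def concatenated(self, trial_ids: Optional[Sequence[int]] = None) -> np.ndarray:
        ids = list(trial_ids) if trial_ids is not None else self.trial_ids()
        return np.concatenate([np.asarray(self.labels[i]) for i in ids])

    def segments(self) -> List[Tuple[int, Any, int, int]]:
        """Run-length encoding: (trial_id, label, first_bin, last_bin) with
        inclusive bin indices."""
        out = []
        for tid, vec in self.labels.items():
            for label, first, last in run_length_encode(vec):
                out.append((tid, label, first, last))
        return out

    @classmethod
    def from_segments(
        cls, segments: Iterable[Tuple[int, Any, int, int]], bin_width_s: float
    ) -> "Segmentation":
        per_trial: Dict[int, List[Tuple[Any, int, int]]] = {}
        for tid, label, first, last in segments:
            per_trial.setdefault(tid, []).append((label, first, last))
        labels = {}
        for tid, segs in per_trial.items():
            segs.sort(key=lambda s: s[1])
            n = segs[-1][2] + 1
            vec = np.empty(n, dtype=object)
            covered = 0
            for label, first, last in segs:
                if first != covered:
                    raise ValidationError(
                        f"trial {tid}: segments do not tile the bins (gap at {covered})"
                    )
                vec[first : last + 1] = label
                covered = last + 1
            try:  # collapse to a numeric dtype when possible
                vec = vec.astype(int)
            except (ValueError, TypeError):
                pass
            labels[tid] = vec
        return cls(bin_width_s=bin_width_s, labels=labels)


def run_length_encode(vec: Sequence[Any]) -> List[Tuple[Any, int, int]]:
    """(label, first, last) runs of a label vector, inclusive indices."""
    vec = np.asarray(vec)
    if vec.size == 0:
        return []
    change = np.flatnonzero(vec[1:] != vec[:-1])
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [vec.size - 1]])
    return [(vec[s], int(s), int(e)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# Session I/O


def write_session(session: SpikeSession, path: str | Path) -> None:
    """Write a session directory in the documented CSV dialect."""
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"neuron_id": session.neurons}
    ).to_csv(path / "neurons.csv", index=False)
    pd.DataFrame(
        session.spikes, columns=["neuron_id", "time_s"]
    ).to_csv(path / "spikes.csv", index=False, float_format="%.17g")
    pd.DataFrame(
        [
            {
                "trial_id": t.trial_id,
                "role": t.role,
                "start_s": t.start_s,
                "end_s": t.end_s,
                "failed": t.failed,
            }
            for t in session.trials
        ],
        columns=["trial_id", "role", "start_s", "end_s", "failed"],
    ).to_csv(path / "trials.csv", index=False, float_format="%.17g")
    rows = []
    for t in session.trials:
        for name in PHASE_ORDER:
            if name in t.phase_points:
                rows.append(
                    {
                        "trial_id": t.trial_id,
                        "label": name,
                        "kind": "point",
                        "start_s": t.phase_points[name],
                        "end_s": "",
                    }
                )
        for label, a, b in t.behavior_intervals:
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "label": label,
                    "kind": "interval",
                    "start_s": a,
                    "end_s": b,
                }
            )
    pd.DataFrame(
        rows, columns=["trial_id", "label", "kind", "start_s", "end_s"]
    ).to_csv(path / "events.csv", index=False, float_format="%.17g")


def read_session(path: str | Path) -> SpikeSession:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    for fname in ("spikes.csv", "trials.csv", "events.csv"):
        if not (path / fname).exists():
            raise FormatError(f"missing table {fname} in {path}")
    spikes_df = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
    trials_df = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    events_df = pd.read_csv(path / "events.csv", float_precision="round_trip")

    if (path / "neurons.csv").exists():
        neurons = pd.read_csv(path / "neurons.csv")["neuron_id"].astype(int).tolist()
    else:
        neurons = sorted(set(spikes_df["neuron_id"].astype(int)))

    spikes = list(
        zip(spikes_df["neuron_id"].astype(int), spikes_df["time_s"].astype(float))
    )

    trials: Dict[int, Trial] = {}
    for _, row in trials_df.iterrows():
        tid = int(row["trial_id"])
        trials[tid] = Trial(
            trial_id=tid,
            role=str(row["role"]),
            start_s=float(row["start_s"]),
            end_s=float(row["end_s"]),
            failed=bool(row["failed"]) if "failed" in row else False,
        )
    for _, row in events_df.iterrows():
        tid = int(row["trial_id"])
        if tid not in trials:
            raise ValidationError(f"event references unknown trial {tid}")
        tr = trials[tid]
        t0 = float(row["start_s"])
        if not (tr.start_s <= t0 <= tr.end_s):
            raise ValidationError(
                f"event {row['label']!r} at {t0} outside trial {tid}"
            )
        if str(row["kind"]) == "point":
            tr.phase_points[str(row["label"])] = t0
        else:
            tr.behavior_intervals.append(
                (str(row["label"]), t0, float(row["end_s"]))
            )

    session = SpikeSession(
        session_id=path.name,
        neurons=neurons,
        spikes=spikes,
        trials=sorted(trials.values(), key=lambda t: t.start_s),
    )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# Results I/O


def format_p_value(p: float, n_null: int) -> Dict[str, Any]:
    """Serialize a permutation p-value; zero counts become the bound 1/n
    with a ``below_resolution`` flag (matching 'p < 1/n' reporting)."""
    if p <= 0:
        return {"p": 1.0 / n_null, "below_resolution": True}
    return {"p": float(p), "below_resolution": False}


def write_results(
    segmentations: Mapping[str, Segmentation],
    statistics: Mapping[str, Any],
    path: str | Path,
) -> None:
    """Write segmentation tables and a structured JSON report.

    ``segmentations`` maps a name (e.g. "hmm", "behavior") to a
    Segmentation; each becomes ``segmentation_<name>.csv`` with columns
    (trial_id, bin_index, state). ``statistics`` must be JSON-serializable
    apart from numpy scalars/arrays, which are converted.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, seg in segmentations.items():
        rows = []
        for tid in seg.trial_ids():
            for i, lab in enumerate(seg.labels[tid]):
                rows.append({"trial_id": tid, "bin_index": i, "state": lab})
        fname = "segmentation.csv" if name == "hmm" else f"segmentation_{name}.csv"
        pd.DataFrame(rows, columns=["trial_id", "bin_index", "state"]).to_csv(
            path / fname, index=False
        )
    with open(path / "report.json", "w") as fh:
        json.dump(_jsonable(statistics), fh, indent=2)


def read_report(path: str | Path) -> Dict[str, Any]:
    with open(Path(path) / "report.json") as fh:
        return json.load(fh)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
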