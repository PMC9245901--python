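"""Correspondence statistics between neural-state and behavioral labelings.

The HMM segments each trial's bins by neural state; the human tags divide
the same bins into behavioral segments. Treating both as clusterings of
the same time points, their similarity is the plug-in mutual information
(MI, nats). Chance level is assessed with permutation nulls that respect
the temporal statistics of the segmentation:

* segment shuffle — per trial, permute the order of the run-length
  segments of the HMM labeling (segment labels and lengths preserved);
* cyclic rotation — rotate the concatenated HMM labels by every possible
  nonzero offset (preserves lengths *and* transition statistics);
* segment relabel — keep all segment boundaries but draw each segment's
  label uniformly (used for the binary playing/observing role test).

Conditional probabilities P(behavior|state) and P(state|behavior) are
tested cell-wise against the segment-shuffle ensemble with a
Holm-Bonferroni correction, considering only cells whose observed
probability exceeds a small floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .data import (
    ROLE_PHASES,
    Segmentation,
    SpikeSession,
    ValidationError,
    format_p_value,
    run_length_encode,
)


# ---------------------------------------------------------------------------
# Behavioral segmentation from tags


def behavioral_segmentation(
    session: SpikeSession,
    bin_width_s: float = 0.25,
    intervals_override: bool = True,
) -> Segmentation:
    """Label every bin of every trial from the human tags.

    Bins between a phase point and the next tagged boundary carry that
    phase's label; tagged behavior intervals override the phase label
    where they overlap (configurable).
    """
    labels: Dict[int, np.ndarray] = {}
    for trial in session.trials:
        n = int(math.floor(trial.duration_s / bin_width_s))
        centers = trial.start_s + (np.arange(n) + 0.5) * bin_width_s
        phases = [
            (name, trial.phase_points[name])
            for name in ROLE_PHASES[trial.role]
            if name in trial.phase_points
        ]
        vec = np.empty(n, dtype=object)
        vec[:] = phases[0][0] if phases else "untagged"
        for name, t in phases:
            vec[centers >= t] = name
        interval_mask = np.zeros(n, dtype=bool)
        for label, a, b in trial.behavior_intervals:
            sel = (centers >= a) & (centers < b)
            if intervals_override:
                vec[sel] = label
            else:
                vec[sel & ~interval_mask] = label
            interval_mask |= sel
        labels[trial.trial_id] = vec
    return Segmentation(bin_width_s=bin_width_s, labels=labels)


# ---------------------------------------------------------------------------
# Mutual information


def _encode(labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    uniq, codes = np.unique(np.asarray(labels), return_inverse=True)
    return uniq, codes


def mutual_information(labels_a: Sequence, labels_b: Sequence) -> float:
    """Plug-in MI (nats) of the joint empirical distribution; 0 log 0 = 0."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("label vectors must be 1-D and equally long")
    if a.size == 0:
        raise ValidationError("label vectors must be non-empty")
    _, ca = _encode(a)
    _, cb = _encode(b)
    return _mi_codes(ca, cb, ca.max() + 1, cb.max() + 1)


def _mi_codes(ca: np.ndarray, cb: np.ndarray, na: int, nb: int) -> float:
    n = ca.size
    joint = np.bincount(ca * nb + cb, minlength=na * nb).reshape(na, nb)
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    j = joint[nz].astype(float)
    outer = np.outer(pa, pb)[nz].astype(float)
    return float(np.sum(j / n * (np.log(j * n) - np.log(outer))))


def entropy(labels: Sequence) -> float:
    """Plug-in entropy (nats)."""
    _, codes = _encode(np.asarray(labels))
    p = np.bincount(codes).astype(float)
    p = p[p > 0] / p.sum()
    return float(-np.sum(p * np.log(p)))


# ---------------------------------------------------------------------------
# Permutation nulls


def _segments_per_trial(
    seg: Segmentation, trial_ids: Sequence[int]
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """(labels, lengths) of run-length segments for each trial, encoded."""
    out = []
    for tid in trial_ids:
        runs = run_length_encode(seg.labels[tid])
        labs = np.array([r[0] for r in runs])
        lens = np.array([r[2] - r[1] + 1 for r in runs])
        out.append((labs, lens))
    return out


def _shuffled_concat(
    per_trial: List[Tuple[np.ndarray, np.ndarray]], rng: np.random.Generator
) -> np.ndarray:
    parts = []
    for labs, lens in per_trial:
        perm = rng.permutation(len(labs))
        parts.append(np.repeat(labs[perm], lens[perm]))
    return np.concatenate(parts)


def mi_significance(
    hmm_seg: Segmentation,
    behavior_seg: Segmentation,
    null: str = "segment_shuffle",
    n_null: int = 10_000,
    seed: int = 0,
) -> Dict:
    """Observed MI, its permutation null, and the p-value.

    ``null`` is "segment_shuffle" (n_null random per-trial segment-order
    permutations of the HMM labeling) or "cyclic_rotation" (MI at every
    nonzero rotation of the concatenated HMM labels; n_null is ignored).
    p = (#null >= observed) / n_null, reported with a below-resolution
    flag when the count is zero.
    """
    ids = _common_ids(hmm_seg, behavior_seg)
    obs_labels = hmm_seg.concatenated(ids)
    beh_labels = behavior_seg.concatenated(ids)
    observed = mutual_information(obs_labels, beh_labels)
    _, cb = _encode(beh_labels)
    nb = cb.max() + 1
    uniq_h = np.unique(obs_labels)
    code_of = {l: i for i, l in enumerate(uniq_h)}
    na = len(uniq_h)

    if null == "segment_shuffle":
        if n_null < 1:
            raise ValidationError("n_null must be >= 1")
        rng = np.random.default_rng(seed)
        per_trial = _segments_per_trial(hmm_seg, ids)
        per_trial = [
            (np.array([code_of[l] for l in labs]), lens)
            for labs, lens in per_trial
        ]
        null_mi = np.empty(n_null)
        for i in range(n_null):
            fake = _shuffled_concat(per_trial, rng)
            null_mi[i] = _mi_codes(fake, cb, na, nb)
    elif null == "cyclic_rotation":
        ch = np.array([code_of[l] for l in obs_labels])
        n = len(ch)
        null_mi = np.empty(n - 1)
        for r in range(1, n):
            null_mi[r - 1] = _mi_codes(np.roll(ch, r), cb, na, nb)
    else:
        raise ValueError(f"unknown null {null!r}")

    k = int(np.sum(null_mi >= observed))
    p = k / len(null_mi)
    return {
        "observed_mi": observed,
        "null_mi": null_mi,
        "n_null": len(null_mi),
        "p_value": p,
        **format_p_value(p, len(null_mi)),
        "null_kind": null,
    }


def _common_ids(a: Segmentation, b: Segmentation) -> List[int]:
    ids = a.trial_ids()
    if set(ids) != set(b.trial_ids()):
        raise ValidationError("segmentations cover different trials")
    for tid in ids:
        if len(a.labels[tid]) != len(b.labels[tid]):
            raise ValidationError(f"trial {tid}: bin counts differ")
    return ids


# ---------------------------------------------------------------------------
# Conditional probabilities


@dataclass
class ConditionalMatrices:
    """Row-stochastic conditionals between the two labelings.

    ``p_beh_given_state[s, b]`` = P(behavior b | state s) and
    ``p_state_given_beh[b, s]`` = P(state s | behavior b). Rows with zero
    support are all-zero and flagged in the ``*_defined`` masks.
    """

    states: np.ndarray
    behaviors: np.ndarray
    p_beh_given_state: np.ndarray
    p_state_given_beh: np.ndarray
    state_defined: np.ndarray
    behavior_defined: np.ndarray
    joint_counts: np.ndarray


def conditional_prob_matrices(
    hmm_labels: Sequence,
    behavior_labels: Sequence,
    states: Optional[Sequence] = None,
    behaviors: Optional[Sequence] = None,
) -> ConditionalMatrices:
    a = np.asarray(hmm_labels)
    b = np.asarray(behavior_labels)
    if a.shape != b.shape:
        raise ValidationError("label vectors must be equally long")
    states = np.asarray(states if states is not None else np.unique(a))
    behaviors = np.asarray(behaviors if behaviors is not None else np.unique(b))
    s_idx = {s: i for i, s in enumerate(states)}
    b_idx = {x: i for i, x in enumerate(behaviors)}
    joint = np.zeros((len(states), len(behaviors)))
    ca = np.array([s_idx[x] for x in a])
    cb = np.array([b_idx[x] for x in b])
    np.add.at(joint, (ca, cb), 1.0)
    row = joint.sum(axis=1)
    col = joint.sum(axis=0)
    pbs = np.divide(joint, row[:, None], out=np.zeros_like(joint),
                    where=row[:, None] > 0)
    psb = np.divide(joint.T, col[:, None], out=np.zeros_like(joint.T),
                    where=col[:, None] > 0)
    return ConditionalMatrices(
        states=states,
        behaviors=behaviors,
        p_beh_given_state=pbs,
        p_state_given_beh=psb,
        state_defined=row > 0,
        behavior_defined=col > 0,
        joint_counts=joint,
    )


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm rejection mask at family-wise level alpha."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, i in enumerate(order):
        if p[i] <= alpha / (m - rank):
            reject[i] = True
        else:
            break
    return reject


def conditional_significance(
    hmm_seg: Segmentation,
    behavior_seg: Segmentation,
    n_null: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    min_prob: float = 0.001,
) -> Dict:
    """Cell-wise bootstrap significance of both conditional matrices.

    Null conditionals come from the same per-trial segment-shuffle
    ensemble as :func:`mi_significance` (identical seed gives identical
    draws); per-cell p = fraction of null values >= observed. Cells with
    observed probability <= ``min_prob`` are excluded, and the
    Holm-Bonferroni correction runs across all included cells of both
    matrices jointly.
    """
    ids = _common_ids(hmm_seg, behavior_seg)
    hmm_labels = hmm_seg.concatenated(ids)
    beh_labels = behavior_seg.concatenated(ids)
    obs = conditional_prob_matrices(hmm_labels, beh_labels)
    states, behaviors = obs.states, obs.behaviors
    ns, nb = len(states), len(behaviors)

    rng = np.random.default_rng(seed)
    per_trial = _segments_per_trial(hmm_seg, ids)
    code_of = {s: i for i, s in enumerate(states)}
    per_trial = [
        (np.array([code_of[l] for l in labs]), lens) for labs, lens in per_trial
    ]
    b_idx = {x: i for i, x in enumerate(behaviors)}
    cb = np.array([b_idx[x] for x in beh_labels])

    ge_bs = np.zeros((ns, nb))
    ge_sb = np.zeros((nb, ns))
    for _ in range(n_null):
        fake = _shuffled_concat(per_trial, rng)
        joint = np.bincount(fake * nb + cb, minlength=ns * nb).reshape(ns, nb)
        row = joint.sum(axis=1, keepdims=True)
        col = joint.sum(axis=0, keepdims=True)
        pbs = np.divide(joint, row, out=np.zeros((ns, nb)), where=row > 0)
        psb = np.divide(joint.T, col.T, out=np.zeros((nb, ns)), where=col.T > 0)
        ge_bs += pbs >= obs.p_beh_given_state
        ge_sb += psb >= obs.p_state_given_beh
    p_bs = ge_bs / n_null
    p_sb = ge_sb / n_null

    inc_bs = obs.p_beh_given_state > min_prob
    inc_sb = obs.p_state_given_beh > min_prob
    flat_p = np.concatenate([p_bs[inc_bs], p_sb[inc_sb]])
    if flat_p.size:
        rej = holm_bonferroni(flat_p, alpha)
    else:
        rej = np.zeros(0, dtype=bool)
    stars_bs = np.zeros((ns, nb), dtype=bool)
    stars_sb = np.zeros((nb, ns), dtype=bool)
    stars_bs[inc_bs] = rej[: inc_bs.sum()]
    stars_sb[inc_sb] = rej[inc_bs.sum():]
    return {
        "states": states,
        "behaviors": behaviors,
        "observed": obs,
        "p_beh_given_state": p_bs,
        "p_state_given_beh": p_sb,
        "stars_beh_given_state": stars_bs,
        "stars_state_given_beh": stars_sb,
        "included_beh_given_state": inc_bs,
        "included_state_given_beh": inc_sb,
        "alpha": alpha,
        "n_null": n_null,
    }


# ---------------------------------------------------------------------------
# State-probability timecourses around a behavior


def state_behavior_timecourse(
    gammas: Mapping[int, np.ndarray],
    session: SpikeSession,
    behavior: str,
    bin_width_s: float = 0.25,
    pad_s: float = 1.0,
) -> Optional[Dict]:
    """Average per-state probability profile across stretched event windows.

    Each tagged interval of ``behavior`` is expanded by ``pad_s`` on both
    sides, the per-bin state posteriors inside the window are warped so
    that (window start, event start, event end, window end) align across
    events — the event body is stretched to the median event duration —
    and profiles are averaged across events. Returns None when the
    behavior was never tagged.
    """
    from .preprocessing import ReferenceAnchors, stretch_series

    events = []  # (trial_id, start, end) absolute seconds
    for trial in session.trials:
        for label, a, b in trial.behavior_intervals:
            if label == behavior and b > a:
                events.append((trial, a, b))
    if not events:
        return None
    med_len = float(np.median([b - a for _, a, b in events]))
    ref = ReferenceAnchors(
        role="event",
        names=("window start", "event start", "event end", "window end"),
        times=np.array([0.0, pad_s, pad_s + med_len, med_len + 2 * pad_s]),
        bin_width_s=bin_width_s,
    )
    profiles = []
    for trial, a, b in events:
        g = gammas[trial.trial_id]  # (T, K)
        T = g.shape[0]
        centers = trial.start_s + (np.arange(T) + 0.5) * bin_width_s
        w0, w1 = a - pad_s, b + pad_s
        sel = (centers >= w0 - bin_width_s) & (centers <= w1 + bin_width_s)
        if sel.sum() < 2:
            continue
        t_local = centers[sel] - w0
        anchors = np.array([0.0, a - w0, b - w0, w1 - w0])
        anchors = np.maximum.accumulate(anchors)
        for i in range(1, 4):  # strictify
            if anchors[i] <= anchors[i - 1]:
                anchors[i] = anchors[i - 1] + 1e-6
        prof = stretch_series(g[sel].T, t_local, anchors, ref, mode="linear")
        profiles.append(prof)
    if not profiles:
        return None
    mean_profile = np.mean(profiles, axis=0)  # (K, ref bins)
    return {
        "behavior": behavior,
        "profile": mean_profile,
        "grid": ref.grid(),
        "event_span": (pad_s, pad_s + med_len),
        "n_events": len(profiles),
    }


# ---------------------------------------------------------------------------
# Playing vs observing separation


def role_state_separation(
    hmm_seg: Segmentation,
    trial_roles: Mapping[int, str],
    n_states: Optional[int] = None,
    n_null: int = 10_000,
    seed: int = 0,
    mixing_band: Tuple[float, float] = (0.3, 0.7),
) -> Dict:
    """How cleanly the states split playing from observing.

    Returns P(observing | state) per state, the share of total time spent
    in "mixed" states (conditional probability strictly inside
    ``mixing_band``), and the MI between state labels and the binary
    per-bin role with a segment-relabel null (segment boundaries kept,
    each segment's label redrawn uniformly from the K states).
    """
    ids = hmm_seg.trial_ids()
    roles = {trial_roles[tid] for tid in ids}
    if "observing" not in roles or not (roles - {"observing"}):
        raise ValidationError("need both observing and playing trials")
    labels = hmm_seg.concatenated(ids)
    is_obs = np.concatenate(
        [
            np.full(len(hmm_seg.labels[tid]),
                    trial_roles[tid] == "observing")
            for tid in ids
        ]
    )
    states = np.unique(labels)
    K = n_states if n_states is not None else (
        int(states.max()) + 1 if np.issubdtype(states.dtype, np.integer)
        else len(states)
    )
    code_of = {s: i for i, s in enumerate(states)}
    codes = np.array([code_of[l] for l in labels])

    counts_all = np.bincount(codes, minlength=len(states)).astype(float)
    counts_obs = np.bincount(codes[is_obs], minlength=len(states)).astype(float)
    p_obs = np.divide(counts_obs, counts_all, out=np.full(len(states), np.nan),
                      where=counts_all > 0)
    lo, hi = mixing_band
    mixed = (p_obs > lo) & (p_obs < hi)
    mixing_fraction = float(counts_all[mixed].sum() / counts_all.sum())

    observed_mi = mutual_information(codes, is_obs)
    rng = np.random.default_rng(seed)
    per_trial = _segments_per_trial(hmm_seg, ids)
    seg_lens = [lens for _, lens in per_trial]
    null_mi = np.empty(n_null)
    cb = is_obs.astype(int)
    for i in range(n_null):
        parts = [
            np.repeat(rng.integers(0, K, size=len(lens)), lens)
            for lens in seg_lens
        ]
        null_mi[i] = _mi_codes(np.concatenate(parts), cb, K, 2)
    k = int(np.sum(null_mi >= observed_mi))
    p = k / n_null
    return {
        "states": states,
        "p_observing_given_state": p_obs,
        "mixing_fraction": mixing_fraction,
        "role_mi": observed_mi,
        "null_mi": null_mi,
        "p_value": p,
        **format_p_value(p, n_null),
    }
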