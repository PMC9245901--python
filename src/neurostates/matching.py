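"""Matching HMM states across independently fitted sessions.

Different sessions record disjoint neuron sets, so each gets its own HMM
and state labels are arbitrary per session. States are paired across
sessions by (1) computing each state's probability of being active along
a stretched common timeline (per role, anchors taken as medians over
every trial of every session), (2) correlating these timecourses for
every pair of states between the two sessions — one correlation matrix
per role — and (3) running the Hungarian algorithm on the negative mean
of the role matrices. The reference session is the one with the highest
average matched correlation to all others; every other session's states
are then relabeled by their assignment to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .data import SpikeSession, ValidationError
from .preprocessing import ReferenceAnchors, median_anchors, stretch_series, \
    trial_anchor_times

logger = logging.getLogger(__name__)


def global_anchors(
    sessions: Sequence[SpikeSession], role: str, bin_width_s: float = 0.25
) -> ReferenceAnchors:
    """Median phase anchors across every trial of every session."""
    trials = [t for s in sessions for t in s.trials]
    return median_anchors(trials, role, bin_width_s)


def state_probability_timecourse(
    gammas: Mapping[int, np.ndarray],
    session: SpikeSession,
    role: str,
    anchors: ReferenceAnchors,
) -> Optional[np.ndarray]:
    """Trial-averaged stretched state posteriors, (K x reference bins).

    Every trial's gamma (T x K) is warped linearly onto the reference
    grid, then averaged across trials; column sums stay 1. Returns None
    when the session has no trial of the role.
    """
    trials = session.trials_of_role(role)
    if not trials:
        return None
    w = anchors.bin_width_s
    stretched = []
    for trial in trials:
        g = gammas[trial.trial_id]  # (T, K)
        T = g.shape[0]
        times = (np.arange(T) + 0.5) * w
        ta = trial_anchor_times(trial, anchors.names)
        ta = np.maximum.accumulate(ta)
        for i in range(1, len(ta)):  # strictify degenerate tag times
            if ta[i] <= ta[i - 1]:
                ta[i] = ta[i - 1] + 1e-6
        stretched.append(stretch_series(g.T, times, ta, anchors, mode="linear"))
    return np.mean(stretched, axis=0)


def hungarian_assignment(cost: np.ndarray) -> np.ndarray:
    """Minimum-cost perfect assignment; ``perm[i]`` is the column of row i.

    Among equally optimal assignments the lexicographically smallest
    permutation is returned (rows fixed greedily in order, trying columns
    in ascending order and re-solving the remainder).
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValidationError("cost matrix must be square")
    if not np.all(np.isfinite(cost)):
        raise ValidationError("cost matrix must be finite")
    K = cost.shape[0]
    rows, cols = linear_sum_assignment(cost)
    best_total = cost[rows, cols].sum()
    tol = 1e-9 * (1.0 + abs(best_total))

    perm = np.empty(K, dtype=int)
    free_cols = list(range(K))
    remaining = best_total
    sub = cost
    for i in range(K):
        for j in sorted(free_cols):
            jj = free_cols.index(j)
            rest = np.delete(sub[1:], jj, axis=1)
            if rest.size:
                r, c = linear_sum_assignment(rest)
                rest_cost = rest[r, c].sum()
            else:
                rest_cost = 0.0
            if sub[0, jj] + rest_cost <= remaining + tol:
                perm[i] = j
                remaining -= sub[0, jj]
                sub = np.delete(sub[1:], jj, axis=1)
                free_cols.remove(j)
                break
    return perm


def correlation_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlations between rows of A and rows of B.

    Rows with zero variance get correlation 0 (logged), since a constant
    occupancy timecourse carries no matching signal.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((Ac**2).sum(axis=1))
    sb = np.sqrt((Bc**2).sum(axis=1))
    if np.any(sa == 0) or np.any(sb == 0):
        logger.info("constant state timecourse: correlation set to 0")
    denom = np.outer(sa, sb)
    num = Ac @ Bc.T
    return np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)


@dataclass
class MatchResult:
    """Assignment of one session's states onto a reference session."""

    session_id: str
    reference_id: str
    corr_by_role: Dict[str, np.ndarray]   # K x K per role
    assignment: np.ndarray                # state k -> reference state
    total_correlation: float              # sum of mean-corr entries on the assignment

    def validate(self) -> None:
        K = len(self.assignment)
        if sorted(self.assignment) != list(range(K)):
            raise ValidationError("assignment must be a bijection")


def match_states(
    timecourses: Mapping[str, np.ndarray],
    reference_timecourses: Mapping[str, np.ndarray],
    session_id: str = "session",
    reference_id: str = "reference",
    roles: Sequence[str] = ("hide", "seek"),
    distance: str = "correlation",
) -> MatchResult:
    """Match one session's states to a reference via occupancy timecourses.

    ``timecourses`` maps role -> (K x reference-bins) occupancy matrices
    for the same roles in both sessions. Cost is the negative mean of the
    per-role correlation matrices ("correlation", default) or of cosine
    similarities ("cosine").
    """
    corr_by_role: Dict[str, np.ndarray] = {}
    for role in roles:
        A = timecourses.get(role)
        B = reference_timecourses.get(role)
        if A is None or B is None:
            continue
        if distance == "correlation":
            corr_by_role[role] = correlation_matrix(A, B)
        elif distance == "cosine":
            na = np.linalg.norm(A, axis=1, keepdims=True)
            nb = np.linalg.norm(B, axis=1, keepdims=True)
            corr_by_role[role] = (A / np.maximum(na, 1e-12)) @ (
                B / np.maximum(nb, 1e-12)
            ).T
        else:
            raise ValueError(f"unknown distance {distance!r}")
    if not corr_by_role:
        raise ValidationError("no shared role with timecourses on both sides")
    mean_corr = np.mean(list(corr_by_role.values()), axis=0)
    assignment = hungarian_assignment(-mean_corr)
    total = float(mean_corr[np.arange(len(assignment)), assignment].sum())
    res = MatchResult(
        session_id=session_id,
        reference_id=reference_id,
        corr_by_role=corr_by_role,
        assignment=assignment,
        total_correlation=total,
    )
    res.validate()
    return res


def select_reference(
    timecourses_by_session: Mapping[str, Mapping[str, np.ndarray]],
    roles: Sequence[str] = ("hide", "seek"),
) -> Tuple[str, Dict[str, MatchResult]]:
    """Pick the reference session and match everyone to it.

    The reference maximizes the mean matched total correlation over all
    partner sessions (ties break by session order). Returns the reference
    id and a MatchResult per non-reference session.
    """
    ids = list(timecourses_by_session.keys())
    if not ids:
        raise ValidationError("no sessions to match")
    if len(ids) == 1:
        return ids[0], {}
    mean_scores = {}
    for ref in ids:
        scores = [
            match_states(
                timecourses_by_session[s], timecourses_by_session[ref],
                session_id=s, reference_id=ref, roles=roles,
            ).total_correlation
            for s in ids
            if s != ref
        ]
        mean_scores[ref] = float(np.mean(scores))
    best = max(ids, key=lambda s: mean_scores[s])  # first max wins ties
    matches = {
        s: match_states(
            timecourses_by_session[s], timecourses_by_session[best],
            session_id=s, reference_id=best, roles=roles,
        )
        for s in ids
        if s != best
    }
    return best, matches


def relabel_states(labels: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Apply a match: state k becomes reference state assignment[k]."""
    return np.asarray(assignment)[np.asarray(labels, dtype=int)]


def brute_force_assignment(cost: np.ndarray) -> Tuple[np.ndarray, float]:
    """Exhaustive minimum-cost assignment (test oracle for small K)."""
    cost = np.asarray(cost, dtype=float)
    K = cost.shape[0]
    best_perm, best_total = None, np.inf
    for perm in permutations(range(K)):
        total = sum(cost[i, perm[i]] for i in range(K))
        if total < best_total - 1e-12:
            best_total, best_perm = total, perm
    return np.array(best_perm), float(best_total)
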