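"""Classical trial-averaged view: pooled stretched rates and time clusters.

Before any single-trial modeling, the population can be summarized the
traditional way: smooth each trial's rates, stretch trials onto the
role's reference timeline, average across trials per neuron, min-max
normalize per neuron, and pool neurons across sessions. K-means applied
to the *time points* (columns) of the pooled matrix then shows which
game stages share a population activity pattern; the number of clusters
is chosen by forward-chained time-series cross-validation plus the
kneedle knee of the held-out score curve.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.model_selection import TimeSeriesSplit

from .data import SpikeSession, ValidationError
from .preprocessing import (
    ReferenceAnchors,
    bin_spikes,
    median_anchors,
    normalize_per_neuron,
    smooth_rates,
    stretch_series,
    trial_anchor_times,
)


def pooled_average_matrix(
    sessions: Sequence[SpikeSession],
    role: str,
    bin_width_s: float = 0.25,
    anchors: Optional[ReferenceAnchors] = None,
    smoothing_halfwidth_s: float = 0.5,
) -> Tuple[np.ndarray, ReferenceAnchors]:
    """Stretched, trial-averaged, normalized rates pooled across sessions.

    Per session: smooth each trial of the role, warp it onto the
    reference grid, average across trials per neuron, then min-max scale
    each neuron to [0, 1]. Rows of all sessions are stacked. Anchors
    default to the global medians over all sessions' trials.
    """
    all_trials = [t for s in sessions for t in s.trials if t.role == role]
    if not all_trials:
        raise ValidationError(f"no session has trials of role {role!r}")
    if anchors is None:
        anchors = median_anchors(all_trials, role, bin_width_s)
    blocks = []
    for session in sessions:
        trials = session.trials_of_role(role)
        if not trials:
            continue
        stretched = []
        for trial in trials:
            binned = bin_spikes(session, trial.trial_id, bin_width_s)
            rates = smooth_rates(binned, smoothing_halfwidth_s)
            times = (np.arange(binned.n_bins) + 0.5) * bin_width_s
            ta = trial_anchor_times(trial, anchors.names)
            ta = np.maximum.accumulate(ta)
            for i in range(1, len(ta)):
                if ta[i] <= ta[i - 1]:
                    ta[i] = ta[i - 1] + 1e-6
            stretched.append(
                stretch_series(rates, times, ta, anchors, mode="linear")
            )
        mean_rates = np.mean(stretched, axis=0)
        blocks.append(normalize_per_neuron([mean_rates])[0])
    return np.concatenate(blocks, axis=0), anchors


def hierarchical_order(matrix: np.ndarray) -> np.ndarray:
    """Row permutation from average-linkage clustering on 1 - correlation.

    Constant rows have undefined correlation; they are pushed away from
    everything by assigning the metric's maximal distance (2).
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 rows to order")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    ok = norms > 0
    denom = np.outer(norms, norms)
    corr = np.divide(Xc @ Xc.T, denom, out=np.zeros((len(X), len(X))),
                     where=denom > 0)
    dist = 1.0 - corr
    dist[~ok, :] = 2.0
    dist[:, ~ok] = 2.0
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return np.asarray(leaves_list(Z))


def kneedle_knee(x: Sequence[float], y: Sequence[float]) -> Optional[int]:
    """Knee index of a concave-increasing curve (Kneedle).

    Both coordinates are min-max normalized; the knee is the point of
    maximum positive vertical distance between the curve and its
    end-to-end secant. Ties resolve to the smallest x; a curve that never
    rises above the secant (e.g. a straight line) has no knee -> None.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValidationError("need at least 3 points")
    if np.any(np.diff(x) <= 0):
        raise ValidationError("x must be strictly increasing")
    xn = (x - x[0]) / (x[-1] - x[0])
    span = y.max() - y.min()
    if span == 0:
        return None
    yn = (y - y.min()) / span
    secant = yn[0] + (yn[-1] - yn[0]) * xn
    dist = yn - secant
    best = int(np.argmax(dist))
    if dist[best] <= 1e-12:
        return None
    return best


def kmeans_time_clusters(
    matrix: np.ndarray,
    K: Optional[int] = None,
    candidate_Ks: Sequence[int] = tuple(range(2, 13)),
    cv_splits: int = 20,
    seed: int = 0,
    n_init: int = 10,
) -> Tuple[np.ndarray, int, Dict[int, float]]:
    """K-means over time points (columns) with cross-validated K.

    With ``K=None``, each candidate is scored by forward-chained
    time-series splits: fit on the past columns, score the next block by
    its mean squared distance to the nearest center (held-out inertia per
    point), and the knee of the (negated) mean score curve picks K; if
    the curve has no knee the best-scoring candidate wins. Returns
    (labels per time point, chosen K, per-candidate CV score).
    """
    X = np.asarray(matrix, dtype=float).T  # samples = time points
    n = X.shape[0]
    scores: Dict[int, float] = {}
    if K is None:
        cands = [k for k in candidate_Ks if k < n]
        if not cands:
            raise ValidationError("no candidate K fits the number of columns")
        tss = TimeSeriesSplit(n_splits=min(cv_splits, n - 1))
        for k in cands:
            fold_scores = []
            for train, test in tss.split(X):
                if len(train) < k:
                    continue
                km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
                km.fit(X[train])
                d = km.transform(X[test]).min(axis=1)
                fold_scores.append(float(np.mean(d**2)))
            scores[k] = float(np.mean(fold_scores))
        knee = kneedle_knee(cands, [-scores[k] for k in cands])
        K = cands[knee] if knee is not None else min(scores, key=scores.get)
    if K > n:
        raise ValidationError("K exceeds the number of time points")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return labels, int(K), scores
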