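"""Binning, rate smoothing, normalization, and time-stretching.

Trials of a free game differ wildly in duration, so cross-trial
comparisons align them by *stretching*: a shared set of reference anchor
times is built from the median phase-point offsets across trials, and each
trial's timeline is warped piecewise-linearly so its anchors land on the
reference anchors. Continuous signals are resampled by linear
interpolation; discrete labels take the value at the nearest original
time (ties break toward the earlier bin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .data import ROLE_PHASES, BinnedTrial, SpikeSession, Trial, ValidationError

GAUSSIAN_HALFWIDTH_S = 0.5  # half-width at half-maximum of the smoothing window


def bin_spikes(
    session: SpikeSession, trial_id: int, bin_width_s: float = 0.25
) -> BinnedTrial:
    """Count spikes of every neuron in half-open 250 ms (default) bins.

    Bin i covers [t0 + i*w, t0 + (i+1)*w) with t0 the trial start; a
    trailing partial bin is dropped. Spikes outside all trials never enter
    any binned matrix.
    """
    if bin_width_s <= 0:
        raise ValidationError("bin_width_s must be positive")
    trial = session.trial(trial_id)  # KeyError for unknown ids
    n_bins = int(math.floor((trial.end_s - trial.start_s) / bin_width_s))
    counts = np.zeros((session.n_neurons, n_bins), dtype=int)
    row = {nid: i for i, nid in enumerate(session.neurons)}
    t_hi = trial.start_s + n_bins * bin_width_s
    for nid, t in session.spikes:
        if trial.start_s <= t < t_hi:
            b = int((t - trial.start_s) / bin_width_s)
            if b < n_bins:  # guard float edge
                counts[row[nid], b] += 1
    return BinnedTrial(
        trial_id=trial_id, counts=counts, bin_width_s=bin_width_s, t0=trial.start_s
    )


def bin_all_trials(
    session: SpikeSession, bin_width_s: float = 0.25
) -> Dict[int, BinnedTrial]:
    return {t.trial_id: bin_spikes(session, t.trial_id, bin_width_s)
            for t in session.trials}


def gaussian_kernel(bin_width_s: float, halfwidth_s: float) -> np.ndarray:
    """Unit-sum Gaussian window sampled at bin offsets.

    ``halfwidth_s`` is the half-width at half-maximum, so
    sigma = halfwidth / sqrt(2 ln 2). Support is +-4 sigma.
    """
    if halfwidth_s <= 0:
        raise ValidationError("halfwidth_s must be positive")
    sigma = halfwidth_s / math.sqrt(2.0 * math.log(2.0))
    half_n = max(1, int(math.ceil(4.0 * sigma / bin_width_s)))
    offsets = np.arange(-half_n, half_n + 1) * bin_width_s
    k = np.exp(-(offsets**2) / (2.0 * sigma**2))
    return k / k.sum()


def smooth_rates(
    binned: BinnedTrial, halfwidth_s: float = GAUSSIAN_HALFWIDTH_S
) -> np.ndarray:
    """Gaussian-smoothed firing rates in spikes/s (neurons x bins).

    The kernel is renormalized at the edges (convolution with an all-ones
    vector in the denominator), so a constant count profile stays exactly
    constant and total spike mass is conserved in the interior.
    """
    k = gaussian_kernel(binned.bin_width_s, halfwidth_s)
    T = binned.n_bins
    denom = np.convolve(np.ones(T), k, mode="same")
    out = np.empty(binned.counts.shape, dtype=float)
    for i, row in enumerate(binned.counts):
        out[i] = np.convolve(row.astype(float), k, mode="same") / denom
    return out / binned.bin_width_s


def normalize_per_neuron(rates: Sequence[np.ndarray]) -> List[np.ndarray]:
    """Min-max scale each neuron to [0, 1] across a whole trial set.

    ``rates`` is a list of (neurons x bins) matrices sharing the neuron
    axis. Neurons with zero range map to all zeros.
    """
    rates = [np.asarray(r, dtype=float) for r in rates]
    if not rates or sum(r.shape[1] for r in rates) == 0:
        raise ValidationError("need at least one bin to normalize")
    cat = np.concatenate(rates, axis=1)
    lo = cat.min(axis=1, keepdims=True)
    span = cat.max(axis=1, keepdims=True) - lo
    safe = np.where(span > 0, span, 1.0)
    return [np.where(span > 0, (r - lo) / safe, 0.0) for r in rates]


# ---------------------------------------------------------------------------
# Stretching


@dataclass
class ReferenceAnchors:
    """Shared reference timeline for one role.

    ``times`` are strictly increasing anchor offsets (seconds from trial
    start on the reference timeline), one per phase name; the uniform
    reference grid spans [first, last] anchor at the analysis bin width.
    """

    role: str
    names: Tuple[str, ...]
    times: np.ndarray
    bin_width_s: float

    @property
    def n_bins(self) -> int:
        return int(math.floor((self.times[-1] - self.times[0]) / self.bin_width_s))

    def grid(self) -> np.ndarray:
        """Reference-grid bin centers."""
        return self.times[0] + (np.arange(self.n_bins) + 0.5) * self.bin_width_s

    def validate(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("anchor times must be strictly increasing")


def trial_anchor_times(trial: Trial, names: Sequence[str]) -> np.ndarray:
    """Phase-point offsets of one trial in anchor order."""
    offs = trial.phase_offsets()
    out = []
    for name in names:
        if name not in offs:
            raise ValidationError(
                f"trial {trial.trial_id} is missing phase {name!r}"
            )
        out.append(offs[name])
    return np.asarray(out, dtype=float)


def median_anchors(
    trials: Sequence[Trial], role: str, bin_width_s: float = 0.25
) -> ReferenceAnchors:
    """Median phase-point offsets across trials of a role.

    With few trials the raw medians can be non-monotone; they are then
    minimally corrected by isotonic regression and strictified by an
    epsilon so the warp has increasing knots.
    """
    names = ROLE_PHASES[role]
    sel = [t for t in trials if t.role == role]
    if not sel:
        raise ValidationError(f"no trials of role {role!r}")
    offsets = np.stack([trial_anchor_times(t, names) for t in sel])
    med = np.median(offsets, axis=0)
    if np.any(np.diff(med) <= 0):
        iso = IsotonicRegression()
        med = iso.fit_transform(np.arange(len(med)), med)
        for i in range(1, len(med)):
            if med[i] <= med[i - 1]:
                med[i] = med[i - 1] + 1e-6
    anchors = ReferenceAnchors(
        role=role, names=tuple(names), times=med, bin_width_s=bin_width_s
    )
    anchors.validate()
    return anchors


def stretch_series(
    series: np.ndarray,
    times: np.ndarray,
    trial_anchors: np.ndarray,
    reference: ReferenceAnchors,
    mode: str = "linear",
) -> np.ndarray:
    """Warp one trial's series onto the reference grid.

    ``series`` has time as its last axis with sample coordinates
    ``times`` (seconds from trial start); ``trial_anchors`` are the
    trial's anchor offsets in reference-anchor order. The piecewise-linear
    time map sends trial anchor k to reference anchor k; the series is
    resampled at the pre-image of each reference-grid point, linearly for
    continuous data, by nearest original sample (ties toward the earlier
    bin) for discrete labels. Reference-grid points outside the anchor
    span do not exist by construction.
    """
    trial_anchors = np.asarray(trial_anchors, dtype=float)
    if np.any(np.diff(trial_anchors) <= 0):
        raise ValidationError("trial anchors must be strictly increasing")
    if len(trial_anchors) != len(reference.times):
        raise ValidationError("anchor count mismatch with reference")
    grid = reference.grid()
    # inverse warp: reference time -> trial time
    src_t = np.interp(grid, reference.times, trial_anchors)
    series = np.asarray(series)
    times = np.asarray(times, dtype=float)
    if mode == "linear":
        if series.ndim == 1:
            return np.interp(src_t, times, series.astype(float))
        return np.stack([np.interp(src_t, times, row.astype(float))
                         for row in series])
    if mode == "nearest":
        idx = _nearest_indices(times, src_t)
        return series[..., idx]
    raise ValueError(f"unknown mode {mode!r}")


def _nearest_indices(times: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Index of the nearest sample for each query time; ties -> earlier."""
    if len(times) == 1:
        return np.zeros(len(query), dtype=int)
    pos = np.searchsorted(times, query)
    pos = np.clip(pos, 1, len(times) - 1)
    left, right = times[pos - 1], times[pos]
    choose_right = (query - left) > (right - query)  # strict: ties go left
    idx = np.where(choose_right, pos, pos - 1)
    # queries before the first / after the last sample clamp naturally
    idx[query <= times[0]] = 0
    idx[query >= times[-1]] = len(times) - 1
    return idx
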