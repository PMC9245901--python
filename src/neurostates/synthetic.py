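"""Generator for state-structured synthetic sessions with ground truth.

The generative model mirrors the assumed physiology: at each time bin the
population is in one of ``K_true`` discrete states that follow each other
with Markovian (sticky, left-to-right through the game phases) dynamics;
each state has a stereotypical vector of latent factors; latents plus
stationary Gaussian-process wander drive per-neuron firing rates through a
linear readout and a softplus link; spike counts are Poisson.

Human-style behavioral tags are derived from the true state boundaries by
adding Gaussian jitter to phase points and randomly mislabeling free
behavior intervals, so the behavioral segmentation is an imperfect
observation of the true state sequence — exactly the situation the
downstream statistics must cope with.

Trial lengths are dwell-driven: each phase segment's duration is geometric
with mean ``stickiness`` bins, so the expected self-transition probability
is ``1 - 1/stickiness`` and the mean trial duration emerges from the
number of segments. When ``stickiness`` is left ``None`` it is derived
from ``mean_trial_duration_s``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .data import ROLE_PHASES, SpikeSession, Trial, ValidationError


class ConfigurationError(ValueError):
    pass


def _default_phase_state_map() -> Dict[str, List[Tuple[str, int]]]:
    """Default mapping from game phases to latent states (K_true = 8).

    Each entry ``(phase, state)`` labels the segment that *begins* at that
    phase point; the trial's final phase point ("end") closes the last
    segment. States shared across roles (interaction=3, transit=4,
    in-box=5) emulate role-independent game stages; state 7 is reserved
    for the free "darting" behavior.
    """
    return {
        "seek": [
            ("start", 0),        # waiting in the closed start-box
            ("box open", 1),     # peeking out of the opened box
            ("jump out", 2),     # seeking / running
            ("interaction", 3),  # play with the experimenter
            ("return transit", 4),
            ("jump in", 5),      # back in the box
        ],
        "hide": [
            ("start", 0),
            ("jump out", 6),     # running to hide
            ("interaction", 3),
            ("return transit", 4),
            ("jump in", 5),
        ],
        "observing": [
            ("start", 0),
            ("jump out", 6),
            ("interaction", 3),
            ("return transit", 4),
            ("jump in", 5),
        ],
    }


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    Defaults emulate a well-powered play session: 8 latent states, 20
    neurons, 15 trials per role of ~60 s at 250 ms bins, GP timescale
    400 ms, tag jitter 500 ms, 5% interval mislabeling.
    """

    K_true: int = 8
    d_true: int = 3
    n_neurons: int = 20
    n_trials: int = 15            # per role
    roles: Tuple[str, ...] = ("hide", "seek")
    bin_width_s: float = 0.25
    mean_trial_duration_s: float = 60.0
    stickiness: Optional[float] = None   # expected state dwell, in bins
    state_means: Optional[np.ndarray] = None     # K_true x d_true
    state_mean_scale: float = 2.0
    loading: Optional[np.ndarray] = None         # n_neurons x d_true
    baseline_log_rate: Optional[np.ndarray] = None
    gp_timescale_s: float = 0.4
    gp_noise_sd: float = 0.25
    tag_jitter_s: float = 0.5
    tag_mislabel_rate: float = 0.05
    phase_state_map: Dict[str, List[Tuple[str, int]]] = field(
        default_factory=_default_phase_state_map
    )
    free_states: Dict[int, str] = field(default_factory=lambda: {7: "darting"})
    free_state_prob: float = 0.25
    inter_trial_gap_s: float = 10.0

    def validate(self) -> None:
        if self.K_true < 1:
            raise ConfigurationError("K_true must be >= 1")
        if self.d_true < 1:
            raise ConfigurationError("d_true must be >= 1")
        if self.gp_timescale_s <= 0:
            raise ConfigurationError("gp_timescale_s must be positive")
        if self.tag_jitter_s < 0:
            raise ConfigurationError("tag_jitter_s must be non-negative")
        if not (0.0 <= self.tag_mislabel_rate <= 1.0):
            raise ConfigurationError("tag_mislabel_rate must lie in [0, 1]")
        if self.stickiness is not None and self.stickiness < 1:
            raise ConfigurationError("stickiness must be >= 1 bin")
        for role in self.roles:
            seq = self.phase_state_map.get(role)
            if not seq:
                raise ConfigurationError(f"phase_state_map has no entry for {role!r}")
            for _, s in seq:
                if not (0 <= s < self.K_true):
                    raise ConfigurationError(f"phase state {s} outside [0, K_true)")

    def neuron_ids(self) -> List[int]:
        return list(range(self.n_neurons))

    def resolve_stickiness(self, role: str) -> float:
        if self.stickiness is not None:
            return float(self.stickiness)
        seq = self.phase_state_map[role]
        n_free = self.free_state_prob * len(seq) if self.free_states else 0.0
        mean_bins = self.mean_trial_duration_s / self.bin_width_s
        return max(1.0, mean_bins / (len(seq) + n_free))


@dataclass
class GroundTruth:
    """Per-trial latent truth of a generated session."""

    states: Dict[int, np.ndarray]          # trial_id -> (T,)
    latents: Dict[int, np.ndarray]         # trial_id -> (T, d_true)
    rates: Dict[int, np.ndarray]           # trial_id -> (n_neurons, T) in Hz
    transition_matrix: np.ndarray          # K x K, empirical, rows sum to 1
    phase_boundaries: Dict[int, Dict[str, float]]  # trial_id -> name -> time_s
    config: SyntheticConfig

    def validate(self) -> None:
        for tid in self.states:
            T = len(self.states[tid])
            if self.latents[tid].shape[0] != T or self.rates[tid].shape[1] != T:
                raise ValidationError(f"trial {tid}: ground-truth lengths disagree")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0):
            raise ValidationError("transition matrix rows must sum to 1")


# ---------------------------------------------------------------------------
# State sequences


def sample_state_sequence(
    config: SyntheticConfig,
    role: str,
    n_bins: Optional[int],
    rng: np.random.Generator,
    return_boundaries: bool = False,
):
    """Sample one trial's latent state sequence.

    Phase states appear in the order of ``phase_state_map[role]`` with
    geometric dwell (mean = stickiness, in bins); free states are inserted
    after each phase segment with probability ``free_state_prob``. With
    ``n_bins=None`` the trial length is the summed dwell; otherwise dwells
    are rescaled proportionally (minimum 1 bin each) to total ``n_bins``.

    Returns the label vector, plus ``(labels, boundaries)`` where
    ``boundaries`` maps phase names to first-bin indices when
    ``return_boundaries`` is true.
    """
    seq = config.phase_state_map.get(role)
    if not seq:
        raise ConfigurationError(f"phase_state_map has no entry for {role!r}")
    stick = config.resolve_stickiness(role)
    free_ids = list(config.free_states.keys())

    segments: List[Tuple[int, Optional[str]]] = []  # (state, phase name or None)
    for phase, state in seq:
        segments.append((state, phase))
        if free_ids and rng.random() < config.free_state_prob:
            segments.append((int(rng.choice(free_ids)), None))

    p = min(1.0, 1.0 / stick)
    dwells = rng.geometric(p, size=len(segments)).astype(int)
    if n_bins is not None:
        if n_bins < 1:
            raise ConfigurationError("n_bins must be >= 1")
        if n_bins < len(segments):  # cannot fit every segment: keep phases only
            segments = [s for s in segments if s[1] is not None][: max(1, n_bins)]
            dwells = dwells[: len(segments)]
        dwells = _rescale_dwells(dwells, n_bins)

    labels = np.repeat([s for s, _ in segments], dwells)
    if return_boundaries:
        starts = np.concatenate([[0], np.cumsum(dwells)[:-1]])
        bounds = {
            phase: int(b)
            for (state, phase), b in zip(segments, starts)
            if phase is not None
        }
        return labels, bounds
    return labels


def _rescale_dwells(dwells: np.ndarray, n_bins: int) -> np.ndarray:
    total = int(dwells.sum())
    scaled = np.maximum(1, np.floor(dwells * (n_bins / total)).astype(int))
    # distribute the remainder over the longest segments, keeping each >= 1
    diff = n_bins - int(scaled.sum())
    order = np.argsort(-dwells)
    i = 0
    while diff != 0:
        j = order[i % len(order)]
        if diff > 0:
            scaled[j] += 1
            diff -= 1
        elif scaled[j] > 1:
            scaled[j] -= 1
            diff += 1
        i += 1
    return scaled


# ---------------------------------------------------------------------------
# Activity


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _gp_cholesky(T: int, bin_width_s: float, tau_s: float, sd: float) -> np.ndarray:
    t = np.arange(T) * bin_width_s
    dt = t[:, None] - t[None, :]
    K = sd**2 * np.exp(-(dt**2) / (2.0 * tau_s**2))
    K[np.diag_indices_from(K)] += 1e-9 + 1e-6 * sd**2
    return np.linalg.cholesky(K)


def sample_activity(
    states: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
    state_means: Optional[np.ndarray] = None,
    loading: Optional[np.ndarray] = None,
    baseline: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent trajectories, firing rates and Poisson counts for one trial.

    Returns ``(x, rates_hz, counts)`` with shapes (T, d), (n, T), (n, T).
    """
    if config.gp_timescale_s <= 0:
        raise ConfigurationError("gp_timescale_s must be positive")
    state_means = config.state_means if state_means is None else state_means
    loading = config.loading if loading is None else loading
    baseline = config.baseline_log_rate if baseline is None else baseline
    if state_means is None or loading is None or baseline is None:
        raise ConfigurationError(
            "state_means, loading and baseline_log_rate must be set "
            "(generate_session fills them in when the config leaves them None)"
        )
    T = len(states)
    x = np.asarray(state_means, dtype=float)[states]  # (T, d)
    if config.gp_noise_sd > 0 and T > 0:
        L = _gp_cholesky(T, config.bin_width_s, config.gp_timescale_s,
                         config.gp_noise_sd)
        x = x + L @ rng.standard_normal((T, x.shape[1]))
    rates_hz = softplus(np.asarray(loading) @ x.T + np.asarray(baseline)[:, None])
    counts = rng.poisson(rates_hz * config.bin_width_s)
    return x, rates_hz, counts


# ---------------------------------------------------------------------------
# Behavioral tags


def derive_behavior_tags(
    states: np.ndarray,
    boundaries: Mapping[str, int],
    config: SyntheticConfig,
    role: str,
    trial_start_s: float,
    rng: np.random.Generator,
) -> Tuple[Dict[str, float], List[Tuple[str, float, float]]]:
    """Imperfect human-style tags from the true state sequence.

    Phase points are the true segment boundaries plus truncated Gaussian
    jitter (order-preserving); behavior intervals are the runs of free
    states, each independently mislabeled with ``tag_mislabel_rate``.
    Returns absolute-time ``(phase_points, behavior_intervals)``.
    """
    if config.tag_jitter_s < 0:
        raise ConfigurationError("tag_jitter_s must be non-negative")
    w = config.bin_width_s
    end_s = trial_start_s + len(states) * w
    phase_names = [p for p, _ in config.phase_state_map[role]] + ["end"]
    true_times = [trial_start_s + boundaries[p] * w for p, _ in
                  config.phase_state_map[role]] + [end_s]

    jittered = np.array(true_times, dtype=float)
    if config.tag_jitter_s > 0:
        jittered = jittered + rng.normal(0.0, config.tag_jitter_s, size=len(jittered))
    jittered = np.clip(jittered, trial_start_s, end_s)
    jittered = np.maximum.accumulate(jittered)  # order-preserving
    phase_points = dict(zip(phase_names, jittered))
    phase_points["start"] = trial_start_s  # trial onset is known exactly
    phase_points["end"] = end_s

    labels_vocab = sorted(set(config.free_states.values()))
    intervals: List[Tuple[str, float, float]] = []
    free_ids = set(config.free_states.keys())
    runs = _runs(states)
    for state, first, last in runs:
        if state in free_ids:
            label = config.free_states[state]
            if len(labels_vocab) > 1 and rng.random() < config.tag_mislabel_rate:
                others = [l for l in labels_vocab if l != label]
                label = str(rng.choice(others))
            intervals.append(
                (label, trial_start_s + first * w, trial_start_s + (last + 1) * w)
            )
    return phase_points, intervals


def _runs(vec: np.ndarray) -> List[Tuple[int, int, int]]:
    vec = np.asarray(vec)
    if vec.size == 0:
        return []
    change = np.flatnonzero(vec[1:] != vec[:-1])
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [vec.size - 1]])
    return [(int(vec[s]), int(s), int(e)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# Full sessions


def _default_parameters(
    config: SyntheticConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw unspecified model parameters (state means, loading, baselines)."""
    if config.state_means is not None:
        means = np.asarray(config.state_means, dtype=float)
    else:
        means = rng.standard_normal((config.K_true, config.d_true))
        norms = np.linalg.norm(means, axis=1, keepdims=True)
        means = config.state_mean_scale * means / np.maximum(norms, 1e-12)
    if config.loading is not None:
        loading = np.asarray(config.loading, dtype=float)
    else:
        loading = rng.standard_normal(
            (config.n_neurons, config.d_true)
        ) / math.sqrt(config.d_true)
    if config.baseline_log_rate is not None:
        baseline = np.asarray(config.baseline_log_rate, dtype=float)
    else:
        # softplus(b) in roughly [2, 10] spikes/s
        baseline = rng.uniform(2.0, 10.0, size=config.n_neurons)
    return means, loading, baseline


def generate_session(
    config: SyntheticConfig, seed: int, session_id: Optional[str] = None
) -> Tuple[SpikeSession, GroundTruth]:
    """Generate one full session. Deterministic given (config, seed)."""
    config = copy.deepcopy(config)
    config.validate()
    rng = np.random.default_rng(seed)
    means, loading, baseline = _default_parameters(config, rng)
    config.state_means, config.loading, config.baseline_log_rate = (
        means, loading, baseline,
    )

    # round-robin over roles
    order: List[str] = []
    for i in range(config.n_trials):
        order.extend(config.roles)

    trials: List[Trial] = []
    spikes: List[Tuple[int, float]] = []
    gt_states, gt_latents, gt_rates, gt_bounds = {}, {}, {}, {}
    t_cursor = 0.0
    w = config.bin_width_s
    trans_counts = np.zeros((config.K_true, config.K_true))

    for tid, role in enumerate(order):
        states, bounds = sample_state_sequence(
            config, role, None, rng, return_boundaries=True
        )
        x, rates_hz, counts = sample_activity(
            states, config, rng, means, loading, baseline
        )
        start_s = t_cursor
        end_s = start_s + len(states) * w
        # spike times uniform within their bin
        for n in range(config.n_neurons):
            for b in np.flatnonzero(counts[n]):
                ts = start_s + (b + rng.random(counts[n, b])) * w
                spikes.extend((config.neuron_ids()[n], float(t)) for t in ts)
        phase_points, intervals = derive_behavior_tags(
            states, bounds, config, role, start_s, rng
        )
        trials.append(
            Trial(
                trial_id=tid,
                role=role,
                start_s=start_s,
                end_s=end_s,
                phase_points=phase_points,
                behavior_intervals=intervals,
            )
        )
        gt_states[tid] = states
        gt_latents[tid] = x
        gt_rates[tid] = rates_hz
        gt_bounds[tid] = {p: start_s + b * w for p, b in bounds.items()}
        gt_bounds[tid]["end"] = end_s
        np.add.at(trans_counts, (states[:-1], states[1:]), 1)
        t_cursor = end_s + config.inter_trial_gap_s

    spikes.sort(key=lambda s: s[1])
    row_tot = trans_counts.sum(axis=1, keepdims=True)
    A = np.where(
        row_tot > 0, trans_counts / np.maximum(row_tot, 1), 1.0 / config.K_true
    )
    session = SpikeSession(
        session_id=session_id or f"synthetic-{seed}",
        neurons=config.neuron_ids(),
        spikes=spikes,
        trials=trials,
    )
    session.validate()
    truth = GroundTruth(
        states=gt_states,
        latents=gt_latents,
        rates=gt_rates,
        transition_matrix=A,
        phase_boundaries=gt_bounds,
        config=config,
    )
    truth.validate()
    return session, truth
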