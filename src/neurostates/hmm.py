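"""Sticky Gaussian-observation hidden Markov model, fitted by MAP-EM.

States s_t follow a Markov chain with initial distribution pi0 and
transition matrix A; given the state, the observation (a latent-factor
vector from GPFA) is Gaussian with state-specific mean and covariance.
The transition rows carry a sticky Dirichlet prior: concentration alpha
on every entry plus an extra kappa on the diagonal, which discourages
rapid state switching. The MAP M-step for row i is therefore

    A_ij  propto  E[n_ij] + alpha - 1 + kappa * delta_ij

(floored at a small positive value before normalization). Fitting runs
EM from ``n_restarts`` random initializations (K-means on the pooled
latents) and keeps the restart with the highest final MAP objective
(data log-likelihood plus the transition log-prior).

All trials of a session are treated as independent sequences sharing one
model; the forward-backward recursions are batched across trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from .data import ValidationError

LOG2PI = math.log(2.0 * math.pi)
_ROW_FLOOR = 1e-8


@dataclass
class StickyHMMModel:
    """K-state Gaussian HMM parameters."""

    pi0: np.ndarray           # (K,)
    A: np.ndarray             # (K, K), row-stochastic
    means: np.ndarray         # (K, d)
    covs: np.ndarray          # (K, d, d)

    @property
    def K(self) -> int:
        return len(self.pi0)

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def validate(self) -> None:
        if not np.allclose(self.pi0.sum(), 1.0, atol=1e-10):
            raise ValidationError("pi0 must sum to 1")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-10):
            raise ValidationError("transition rows must sum to 1")
        for k in range(self.K):
            np.linalg.cholesky(self.covs[k])  # raises if not SPD


@dataclass
class HMMFitConfig:
    """Fitting knobs: sticky prior, restarts, EM stopping."""

    alpha: float = 1.0
    kappa: float = 100.0
    n_restarts: int = 40
    base_seed: int = 0
    tol: float = 1e-7
    max_iter: int = 200
    cov_ridge: float = 1e-6

    def validate(self) -> None:
        if self.alpha < 0 or self.kappa < 0:
            raise ValidationError("alpha and kappa must be non-negative")
        if self.n_restarts < 1:
            raise ValidationError("need at least one restart")


# ---------------------------------------------------------------------------
# Emission log-densities


def _emission_loglik(model: StickyHMMModel, X: np.ndarray) -> np.ndarray:
    """log N(x_t; mu_k, Sigma_k) for all t, k. X is (T, d) -> (T, K)."""
    from scipy.linalg import solve_triangular

    if not np.all(np.isfinite(X)):
        raise ValidationError("latents contain non-finite values")
    T, d = X.shape
    out = np.empty((T, model.K))
    for k in range(model.K):
        L = np.linalg.cholesky(model.covs[k])
        z = solve_triangular(L, (X - model.means[k]).T, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, k] = -0.5 * (d * LOG2PI + logdet + np.sum(z * z, axis=0))
    return out


# ---------------------------------------------------------------------------
# Forward-backward / Viterbi (single sequence)


def forward_backward(
    model: StickyHMMModel, X: np.ndarray
) -> Tuple[float, np.ndarray]:
    """Scaled forward-backward for one sequence.

    Returns (log-likelihood, gamma) with gamma (T, K) the per-bin
    posterior state probabilities (rows sum to 1).
    """
    if X.ndim != 2 or X.shape[1] != model.d:
        raise ValidationError("latent dimension mismatch with model")
    logB = _emission_loglik(model, X)
    T, K = logB.shape
    m = logB.max(axis=1)
    B = np.exp(logB - m[:, None])

    alpha = np.empty((T, K))
    c = np.empty(T)
    a = model.pi0 * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ model.A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    loglik = float(np.sum(np.log(c)) + np.sum(m))

    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (model.A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return loglik, gamma


def viterbi_path(model: StickyHMMModel, X: np.ndarray) -> np.ndarray:
    """Most likely state sequence; ties break toward the lower index."""
    logB = _emission_loglik(model, X)
    T, K = logB.shape
    logA = np.log(np.maximum(model.A, 1e-300))
    delta = np.log(np.maximum(model.pi0, 1e-300)) + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA  # (from, to)
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def path_log_score(model: StickyHMMModel, X: np.ndarray, path: Sequence[int]) -> float:
    """Joint log p(path, X) under the model (for optimality checks)."""
    logB = _emission_loglik(model, X)
    path = np.asarray(path, dtype=int)
    s = math.log(max(model.pi0[path[0]], 1e-300)) + logB[0, path[0]]
    for t in range(1, len(path)):
        s += math.log(max(model.A[path[t - 1], path[t]], 1e-300))
        s += logB[t, path[t]]
    return float(s)


# ---------------------------------------------------------------------------
# Batched E-step over trials


def _batched_e_step(model: StickyHMMModel, trials: List[np.ndarray]):
    """Forward-backward over all trials at once (padded to max length).

    Returns (total loglik, gammas per trial, summed transition counts,
    summed initial-state posteriors).
    """
    n = len(trials)
    K = model.K
    lengths = np.array([len(X) for X in trials])
    Tmax = int(lengths.max())
    logB = np.full((n, Tmax, K), -np.inf)
    for i, X in enumerate(trials):
        logB[i, : len(X)] = _emission_loglik(model, X)
    m = np.where(
        np.arange(Tmax)[None, :] < lengths[:, None],
        logB.max(axis=2),
        0.0,
    )
    B = np.exp(logB - m[:, :, None])
    B[~np.isfinite(B)] = 0.0

    alpha = np.zeros((n, Tmax, K))
    c = np.ones((n, Tmax))
    a = model.pi0[None, :] * B[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / c[:, 0, None]
    for t in range(1, Tmax):
        act = lengths > t
        a = (alpha[act, t - 1, :] @ model.A) * B[act, t, :]
        s = a.sum(axis=1)
        c[act, t] = s
        alpha[act, t, :] = a / s[:, None]
    loglik = float(np.sum(np.log(c)) + np.sum(m))

    beta = np.zeros((n, Tmax, K))
    beta[np.arange(n), lengths - 1, :] = 1.0
    trans = np.zeros((K, K))
    for t in range(Tmax - 2, -1, -1):
        act = lengths > t + 1
        bb = B[act, t + 1, :] * beta[act, t + 1, :]
        beta[act, t, :] = (bb @ model.A.T) / c[act, t + 1, None]
        xi = alpha[act, t, :, None] * model.A[None, :, :] * bb[:, None, :]
        xi_sum = xi.sum(axis=(1, 2), keepdims=True)
        trans += (xi / np.maximum(xi_sum, 1e-300)).sum(axis=0)

    gammas = []
    for i, X in enumerate(trials):
        g = alpha[i, : len(X)] * beta[i, : len(X)]
        g /= g.sum(axis=1, keepdims=True)
        gammas.append(g)
    init = np.sum([g[0] for g in gammas], axis=0)
    return loglik, gammas, trans, init


def _transition_log_prior(model: StickyHMMModel, cfg: HMMFitConfig) -> float:
    K = model.K
    W = np.full((K, K), cfg.alpha - 1.0) + cfg.kappa * np.eye(K)
    return float(np.sum(W * np.log(np.maximum(model.A, 1e-300))))


def map_objective(
    model: StickyHMMModel, trials: List[np.ndarray], cfg: HMMFitConfig
) -> float:
    ll = sum(forward_backward(model, X)[0] for X in trials)
    return ll + _transition_log_prior(model, cfg)


def _init_model(
    trials: List[np.ndarray], K: int, cfg: HMMFitConfig, seed: int
) -> StickyHMMModel:
    X = np.concatenate(trials, axis=0)
    d = X.shape[1]
    if K == 1:
        labels = np.zeros(len(X), dtype=int)
        centers = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(X)
        labels, centers = km.labels_, km.cluster_centers_
    covs = np.empty((K, d, d))
    global_cov = np.cov(X.T).reshape(d, d) + cfg.cov_ridge * np.eye(d)
    for k in range(K):
        sel = X[labels == k]
        if len(sel) > d:
            covs[k] = np.cov(sel.T).reshape(d, d) + cfg.cov_ridge * np.eye(d)
        else:
            covs[k] = global_cov
    diag = (cfg.alpha + cfg.kappa) / (K * cfg.alpha + cfg.kappa + 1e-12)
    diag = min(max(diag, 1.0 / K), 1.0 - 1e-6) if K > 1 else 1.0
    A = np.full((K, K), (1.0 - diag) / max(K - 1, 1))
    np.fill_diagonal(A, diag)
    A /= A.sum(axis=1, keepdims=True)
    return StickyHMMModel(
        pi0=np.full(K, 1.0 / K), A=A, means=centers, covs=covs
    )


def _em(
    trials: List[np.ndarray], model: StickyHMMModel, cfg: HMMFitConfig
) -> Tuple[StickyHMMModel, List[float]]:
    K = model.K
    prior_w = np.full((K, K), cfg.alpha - 1.0) + cfg.kappa * np.eye(K)
    history: List[float] = []
    prev = -np.inf
    for _ in range(cfg.max_iter):
        ll, gammas, trans, init = _batched_e_step(model, trials)
        obj = ll + _transition_log_prior(model, cfg)
        history.append(obj)
        if np.isfinite(prev) and obj - prev < cfg.tol * (abs(prev) + 1.0):
            break
        prev = obj

        # M-step
        pi0 = np.maximum(init, _ROW_FLOOR)
        model.pi0 = pi0 / pi0.sum()
        rows = np.maximum(trans + prior_w, _ROW_FLOOR)
        model.A = rows / rows.sum(axis=1, keepdims=True)
        G = np.concatenate(gammas, axis=0)          # (Ttot, K)
        X = np.concatenate(trials, axis=0)          # (Ttot, d)
        w = G.sum(axis=0)                           # (K,)
        d = X.shape[1]
        for k in range(K):
            wk = max(w[k], 1e-12)
            mu = (G[:, k] @ X) / wk
            diff = X - mu
            cov = (diff.T * G[:, k]) @ diff / wk + cfg.cov_ridge * np.eye(d)
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                cov += 1e-3 * np.trace(cov) / d * np.eye(d)
            model.means[k] = mu
            model.covs[k] = cov
    return model, history


def fit_sticky_hmm(
    trial_latents: Mapping[int, np.ndarray] | Sequence[np.ndarray],
    K: int,
    config: Optional[HMMFitConfig] = None,
) -> Tuple[StickyHMMModel, Dict]:
    """MAP-EM fit with random restarts; returns the best model.

    ``trial_latents`` maps trial ids to (T, d) latent matrices (or is a
    plain sequence). Restart r uses seed ``base_seed + r``; the model
    with the highest final MAP objective wins. Diagnostics report every
    restart's final objective and the winner's objective history.
    """
    cfg = config or HMMFitConfig()
    cfg.validate()
    if isinstance(trial_latents, Mapping):
        trials = [np.asarray(v, dtype=float) for v in trial_latents.values()]
    else:
        trials = [np.asarray(v, dtype=float) for v in trial_latents]
    trials = [X for X in trials if len(X) >= 2]
    if not trials:
        raise ValidationError("need at least one trial with >= 2 bins")
    total_bins = sum(len(X) for X in trials)
    if K > total_bins:
        raise ValidationError("K exceeds the total number of bins")

    best = None
    finals = []
    for r in range(cfg.n_restarts):
        model = _init_model(trials, K, cfg, seed=cfg.base_seed + r)
        model, history = _em(trials, model, cfg)
        finals.append(history[-1])
        if best is None or history[-1] > best[1][-1]:
            best = (model, history, r)
    model, history, r_best = best
    model.validate()
    diagnostics = {
        "restart_objectives": finals,
        "best_restart": r_best,
        "objective_history": history,
    }
    return model, diagnostics


def select_num_states(
    trial_latents: Mapping[int, np.ndarray],
    candidate_Ks: Sequence[int],
    folds: int = 10,
    config: Optional[HMMFitConfig] = None,
) -> Tuple[int, Dict[int, float]]:
    """Cross-validated choice of the number of states.

    Trials are partitioned into ``folds`` groups; for each K an HMM is
    fitted on the training trials and scored by the summed held-out
    log-likelihood normalized by the number of held-out time points. The
    chosen K maximizes the mean normalized score across folds.
    """
    if not list(candidate_Ks):
        raise ValidationError("candidate_Ks must be non-empty")
    cfg = config or HMMFitConfig()
    ids = list(trial_latents.keys())
    if len(ids) < folds:
        raise ValidationError("need at least as many trials as folds")
    rng = np.random.default_rng(cfg.base_seed)
    order = rng.permutation(len(ids))
    fold_ids = [list(np.array(ids)[order[f::folds]]) for f in range(folds)]

    scores: Dict[int, float] = {}
    for K in candidate_Ks:
        per_fold = []
        for f in range(folds):
            test = fold_ids[f]
            train = {i: trial_latents[i] for i in ids if i not in test}
            model, _ = fit_sticky_hmm(train, K, cfg)
            ll = 0.0
            nbins = 0
            for i in test:
                X = np.asarray(trial_latents[i], dtype=float)
                ll += forward_backward(model, X)[0]
                nbins += len(X)
            per_fold.append(ll / nbins)
        scores[K] = float(np.mean(per_fold))
    chosen = max(scores, key=scores.get)
    return chosen, scores


def decode_segmentation(
    model: StickyHMMModel,
    trial_latents: Mapping[int, np.ndarray],
    method: str = "viterbi",
) -> Dict[int, np.ndarray]:
    """Per-trial state labels: Viterbi (default) or per-bin argmax-gamma."""
    out = {}
    for tid, X in trial_latents.items():
        X = np.asarray(X, dtype=float)
        if method == "viterbi":
            out[tid] = viterbi_path(model, X)
        elif method == "gamma":
            out[tid] = np.argmax(forward_backward(model, X)[1], axis=1)
        else:
            raise ValueError(f"unknown decode method {method!r}")
    return out


def state_posteriors(
    model: StickyHMMModel, trial_latents: Mapping[int, np.ndarray]
) -> Dict[int, np.ndarray]:
    """Per-trial gamma matrices (T, K)."""
    return {
        tid: forward_backward(model, np.asarray(X, dtype=float))[1]
        for tid, X in trial_latents.items()
    }
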