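"""Latent-factor extraction: FA dimensionality selection and GPFA.

The number of latent dimensions of a session is chosen with a two-step
procedure: (1) factor-analysis models of increasing dimensionality are
compared by cross-validated log-likelihood on the session's binned rates;
(2) the dimensionality is reduced to the smallest number of eigenvalues
of the winning model's shared covariance that capture 95% of its
variance.

Gaussian-process factor analysis (GPFA) then extracts smooth latent
trajectories x_t from binned spike counts y_t:

    y_t = C x_t + d + eps,  eps ~ N(0, R) (R diagonal),
    x_i  ~ GP(0, k_i),  k_i(dt) = (1 - sigma_n^2) exp(-dt^2 / (2 tau_i^2))
                                  + sigma_n^2 delta(dt)

with a fixed small GP noise floor sigma_n^2 and one squared-exponential
timescale tau_i per latent. Fitting is EM: the E-step is exact Gaussian
conditioning on the full trial (posterior over all latents at all bins at
once), the M-step updates C, d, R in closed form and each tau_i by
bounded 1-D search. Spike counts are fed in untransformed by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from sklearn.decomposition import FactorAnalysis
from sklearn.model_selection import KFold

from .data import BinnedTrial, ValidationError

LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Factor analysis


@dataclass
class FAModel:
    """Fitted factor-analysis model y ~ N(d_vec, C C^T + Psi)."""

    C: np.ndarray          # neurons x d
    d_vec: np.ndarray      # per-neuron offsets
    Psi: np.ndarray        # diagonal noise variances
    loglike_curve: List[float]  # training log-likelihood per EM iteration
    _sk: FactorAnalysis = field(repr=False, default=None)

    @property
    def d(self) -> int:
        return self.C.shape[1]

    def score(self, X: np.ndarray) -> float:
        """Average log-likelihood per sample."""
        return float(self._sk.score(X))

    def shared_covariance_eigs(self) -> np.ndarray:
        """Descending eigenvalues of the shared covariance C^T C.

        C^T C (d x d) has the same nonzero spectrum as C C^T, so the
        variance fractions are identical either way.
        """
        vals = np.linalg.eigvalsh(self.C.T @ self.C)
        return vals[::-1]


def fit_factor_analysis(
    X: np.ndarray,
    d: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> FAModel:
    """Fit FA with ``d`` latent dimensions to ``X`` (samples x neurons)."""
    X = np.asarray(X, dtype=float)
    if d < 1:
        raise ValidationError("d must be >= 1")
    if X.shape[0] <= d:
        raise ValidationError("need more samples than latent dimensions")
    var = X.var(axis=0)
    if np.any(var == 0):
        # ridge a dead channel so the noise variance stays positive
        X = X.copy()
        dead = np.flatnonzero(var == 0)
        bump = 1e-6 * np.where(np.arange(X.shape[0]) % 2 == 0, 1.0, -1.0)
        for j in dead:
            X[:, j] = X[:, j] + bump
    fa = FactorAnalysis(
        n_components=d, max_iter=max_iter, tol=tol, random_state=seed
    )
    fa.fit(X)
    return FAModel(
        C=fa.components_.T.copy(),
        d_vec=fa.mean_.copy(),
        Psi=fa.noise_variance_.copy(),
        loglike_curve=list(fa.loglike_),
        _sk=fa,
    )


def select_dimensionality(
    X: np.ndarray,
    candidate_dims: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    variance_fraction: float = 0.95,
) -> Tuple[int, Dict[int, float]]:
    """Two-step latent-dimensionality selection.

    Step 1: cross-validated FA log-likelihood picks d*. Step 2: the
    smallest dimensionality capturing ``variance_fraction`` of the d*
    model's shared covariance is returned. Also returns the per-candidate
    CV scores.
    """
    if not list(candidate_dims):
        raise ValidationError("candidate_dims must be non-empty")
    if folds < 2:
        raise ValidationError("need at least 2 folds")
    X = np.asarray(X, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores: Dict[int, float] = {}
    for d in candidate_dims:
        fold_scores = []
        for train, test in kf.split(X):
            model = fit_factor_analysis(X[train], d, seed=seed)
            fold_scores.append(model.score(X[test]))
        scores[d] = float(np.mean(fold_scores))
    d_star = max(scores, key=scores.get)
    eigs = fit_factor_analysis(X, d_star, seed=seed).shared_covariance_eigs()
    eigs = np.maximum(eigs, 0.0)
    total = eigs.sum()
    if total <= 0:  # no shared variance at all: floor at one dimension
        return 1, scores
    frac = np.cumsum(eigs) / total
    chosen = int(np.searchsorted(frac, variance_fraction) + 1)
    return min(chosen, d_star), scores


# ---------------------------------------------------------------------------
# GPFA


@dataclass
class GPFAModel:
    """Fitted GPFA model (see module docstring for the generative form)."""

    C: np.ndarray            # neurons x d
    d_vec: np.ndarray        # per-neuron offsets
    R: np.ndarray            # diagonal observation noise variances
    taus: np.ndarray         # per-latent SE timescales, seconds
    sigma_n2: float          # fixed GP noise-floor variance
    bin_width_s: float
    loglik_history: List[float] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.C.shape[0]

    @property
    def d(self) -> int:
        return self.C.shape[1]


def _se_kernel(T: int, bin_width_s: float, tau: float, sigma_n2: float) -> np.ndarray:
    t = np.arange(T) * bin_width_s
    dt = t[:, None] - t[None, :]
    K = (1.0 - sigma_n2) * np.exp(-(dt**2) / (2.0 * tau**2))
    K[np.diag_indices_from(K)] += sigma_n2 + 1e-9
    return K


class _TrialPosterior:
    """Exact Gaussian posterior of all latents of one trial."""

    __slots__ = ("mean", "cov", "loglik", "T", "d")

    def __init__(self, mean, cov, loglik, T, d):
        self.mean, self.cov, self.loglik = mean, cov, loglik
        self.T, self.d = T, d

    def traj(self) -> np.ndarray:
        """Posterior-mean latent trajectory, (T, d)."""
        return self.mean.reshape(self.d, self.T).T

    def time_blocks(self) -> Tuple[np.ndarray, np.ndarray]:
        """(E[x_t], E[x_t x_t^T]) as ((T, d), (T, d, d)) arrays."""
        mu = self.mean.reshape(self.d, self.T)
        cov = self.cov.reshape(self.d, self.T, self.d, self.T)
        Exx = cov[:, np.arange(self.T), :, np.arange(self.T)]  # (T, d, d)
        Exx = Exx + mu.T[:, :, None] * mu.T[:, None, :]
        return mu.T, Exx

    def latent_second_moment(self, i: int) -> np.ndarray:
        """E[x_i x_i^T] over time for latent i, (T, T)."""
        mu = self.mean.reshape(self.d, self.T)
        cov = self.cov.reshape(self.d, self.T, self.d, self.T)
        return cov[i, :, i, :] + np.outer(mu[i], mu[i])


def _precision_pieces(model: GPFAModel, T: int):
    """Per-length cached quantities: posterior covariance and GP logdets."""
    d = model.d
    Kinvs, logdetK = [], 0.0
    for i in range(d):
        K = _se_kernel(T, model.bin_width_s, model.taus[i], model.sigma_n2)
        c, low = cho_factor(K, lower=True)
        logdetK += 2.0 * np.sum(np.log(np.diag(c)))
        Kinvs.append(cho_solve((c, low), np.eye(T)))
    M = model.C.T @ (model.C / model.R[:, None])  # C^T R^-1 C
    P = np.kron(M, np.eye(T))
    for i in range(d):
        P[i * T : (i + 1) * T, i * T : (i + 1) * T] += Kinvs[i]
    cP, lowP = cho_factor(P, lower=True)
    logdetP = 2.0 * np.sum(np.log(np.diag(cP)))
    Sigma = cho_solve((cP, lowP), np.eye(d * T))
    return Sigma, logdetP, logdetK


def _e_step_trial(
    model: GPFAModel, Y: np.ndarray, cache: Dict[int, tuple]
) -> _TrialPosterior:
    q, T = Y.shape
    d = model.d
    if T not in cache:
        cache[T] = _precision_pieces(model, T)
    Sigma, logdetP, logdetK = cache[T]
    Yc = Y - model.d_vec[:, None]
    B = (model.C / model.R[:, None]).T @ Yc  # (d, T)
    b = B.reshape(d * T)
    mu = Sigma @ b
    quad = float(np.sum(Yc * Yc / model.R[:, None]) - b @ mu)
    logdetS = logdetP + logdetK + T * float(np.sum(np.log(model.R)))
    loglik = -0.5 * (q * T * LOG2PI + logdetS + quad)
    return _TrialPosterior(mu, Sigma, loglik, T, d)


def fit_gpfa(
    binned: Mapping[int, BinnedTrial] | Sequence[BinnedTrial],
    d: int,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-6,
    sigma_n2: float = 1e-3,
    tau_init_s: float = 0.5,
    tau_bounds_s: Tuple[float, float] = (0.05, 10.0),
    tau_update_every: int = 3,
) -> Tuple[GPFAModel, Dict[int, np.ndarray]]:
    """Fit GPFA by EM and return the model plus posterior-mean latents.

    ``binned`` maps trial ids to BinnedTrial (or is a sequence of them).
    Trials with fewer than 2 bins are skipped with a warning. Returns
    ``(model, latents)`` with ``latents[trial_id]`` of shape (T, d).
    """
    if isinstance(binned, Mapping):
        items = list(binned.items())
    else:
        items = [(bt.trial_id, bt) for bt in binned]
    items = [(tid, bt) for tid, bt in items if bt.n_bins >= 2]
    if not items:
        raise ValidationError("no trial with at least 2 bins")
    if d < 1:
        raise ValidationError("d must be >= 1")
    bin_width = items[0][1].bin_width_s
    Ys = {tid: bt.counts.astype(float) for tid, bt in items}

    # initialize from plain FA on the pooled bins
    stacked = np.concatenate([Y.T for Y in Ys.values()], axis=0)
    fa = fit_factor_analysis(stacked, d, seed=seed, max_iter=200)
    model = GPFAModel(
        C=fa.C.copy(),
        d_vec=fa.d_vec.copy(),
        R=np.maximum(fa.Psi.copy(), 1e-6),
        taus=np.full(d, tau_init_s, dtype=float),
        sigma_n2=sigma_n2,
        bin_width_s=bin_width,
    )

    prev_ll = -np.inf
    for it in range(max_iter):
        cache: Dict[int, tuple] = {}
        posts = {tid: _e_step_trial(model, Ys[tid], cache) for tid in Ys}
        ll = float(sum(p.loglik for p in posts.values()))
        model.loglik_history.append(ll)

        # --- M-step: C, d, R (closed form over all trials)
        q = model.n_neurons
        S_yx = np.zeros((q, d + 1))
        S_xx = np.zeros((d + 1, d + 1))
        total_T = 0
        RSS = np.zeros(q)
        for tid, p in posts.items():
            Y = Ys[tid]
            Ex, Exx = p.time_blocks()
            S_yx[:, :d] += Y @ Ex
            S_yx[:, d] += Y.sum(axis=1)
            S_xx[:d, :d] += Exx.sum(axis=0)
            S_xx[:d, d] += Ex.sum(axis=0)
            S_xx[d, :d] += Ex.sum(axis=0)
            S_xx[d, d] += p.T
            total_T += p.T
        Cd = np.linalg.solve(S_xx + 1e-10 * np.eye(d + 1), S_yx.T).T
        model.C = Cd[:, :d]
        model.d_vec = Cd[:, d]
        # R update: R_j = mean_t E[(y - C x - d)^2_j]
        RSS = np.zeros(q)
        for tid, p in posts.items():
            Y = Ys[tid]
            Ex, Exx = p.time_blocks()
            Yc = Y - model.d_vec[:, None]
            cross = (Yc * (model.C @ Ex.T)).sum(axis=1)
            quad = np.einsum("ij,tjk,ik->i", model.C, Exx, model.C)
            RSS += (Yc * Yc).sum(axis=1) - 2.0 * cross + quad
        model.R = np.maximum(RSS / total_T, 1e-6)

        # --- M-step: per-latent timescales by bounded 1-D search
        # (every few iterations; the search re-solves a T x T system per
        # candidate tau, which dominates runtime if run every iteration)
        update_tau = (it % tau_update_every == tau_update_every - 1)
        for i in range(d if update_tau else 0):
            Ss = [p.latent_second_moment(i) for p in posts.values()]

            def neg_obj(tau: float) -> float:
                val = 0.0
                ks: Dict[int, tuple] = {}
                for S in Ss:
                    T = S.shape[0]
                    if T not in ks:
                        K = _se_kernel(T, model.bin_width_s, tau, model.sigma_n2)
                        c, low = cho_factor(K, lower=True)
                        ks[T] = (c, low, 2.0 * np.sum(np.log(np.diag(c))))
                    c, low, ld = ks[T]
                    val += ld + np.trace(cho_solve((c, low), S))
                return 0.5 * val

            res = minimize_scalar(
                neg_obj,
                bounds=tau_bounds_s,
                method="bounded",
                options={"xatol": 1e-3, "maxiter": 25},
            )
            if res.fun <= neg_obj(model.taus[i]):
                model.taus[i] = float(res.x)

        if ll - prev_ll < tol * abs(prev_ll) and np.isfinite(prev_ll):
            break
        prev_ll = ll

    cache = {}
    latents = {
        tid: _e_step_trial(model, Ys[tid], cache).traj() for tid in Ys
    }
    return model, latents


def infer_latents(model: GPFAModel, binned: BinnedTrial) -> np.ndarray:
    """Posterior-mean latent trajectory (T, d) for one trial."""
    if binned.counts.shape[0] != model.n_neurons:
        raise ValidationError(
            f"trial has {binned.counts.shape[0]} neurons, model expects "
            f"{model.n_neurons}"
        )
    post = _e_step_trial(model, binned.counts.astype(float), {})
    return post.traj()


def log_likelihood(model: GPFAModel, binned: BinnedTrial) -> float:
    """Marginal log-likelihood of one trial under the model."""
    return _e_step_trial(model, binned.counts.astype(float), {}).loglik


def principal_angle_deg(A: np.ndarray, B: np.ndarray) -> float:
    """Largest principal angle (degrees) between the column spans of A, B."""
    Qa, _ = np.linalg.qr(np.asarray(A, dtype=float))
    Qb, _ = np.linalg.qr(np.asarray(B, dtype=float))
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    s = np.clip(s, -1.0, 1.0)
    return float(np.degrees(np.arccos(s.min())))
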