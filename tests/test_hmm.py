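import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from neurostates.data import ValidationError
from neurostates.hmm import (
    HMMFitConfig,
    StickyHMMModel,
    decode_segmentation,
    fit_sticky_hmm,
    forward_backward,
    path_log_score,
    select_num_states,
    viterbi_path,
)
from neurostates.synthetic import SyntheticConfig, sample_activity, \
    sample_state_sequence


def _random_model(rng, K, d):
    pi0 = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    means = rng.normal(size=(K, d)) * 2
    covs = np.empty((K, d, d))
    for k in range(K):
        M = rng.normal(size=(d, d))
        covs[k] = M @ M.T + 0.5 * np.eye(d)
    return StickyHMMModel(pi0=pi0, A=A, means=means, covs=covs)


def _enumeration_loglik(model, X):
    """Sum over all K^T paths — the exact-inference oracle."""
    T = len(X)
    K = model.K
    logB = np.array(
        [
            [multivariate_normal.logpdf(X[t], model.means[k], model.covs[k])
             for k in range(K)]
            for t in range(T)
        ]
    )
    scores = []
    for path in itertools.product(range(K), repeat=T):
        s = np.log(model.pi0[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            s += np.log(model.A[path[t - 1], path[t]]) + logB[t, path[t]]
        scores.append(s)
    return logsumexp(scores), scores


class TestExactInference:
    @pytest.mark.parametrize("T,K,d,seed", [
        (4, 2, 1, 0), (5, 2, 2, 1), (6, 3, 2, 2), (4, 3, 3, 3),
    ])
    def test_forward_matches_path_enumeration(self, T, K, d, seed):
        rng = np.random.default_rng(seed)
        model = _random_model(rng, K, d)
        X = rng.normal(size=(T, d))
        expected, _ = _enumeration_loglik(model, X)
        loglik, gamma = forward_backward(model, X)
        assert loglik == pytest.approx(expected, abs=1e-10)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)

    @pytest.mark.parametrize("T,K,d,seed", [(5, 2, 2, 4), (6, 3, 2, 5)])
    def test_viterbi_matches_brute_force(self, T, K, d, seed):
        rng = np.random.default_rng(seed)
        model = _random_model(rng, K, d)
        X = rng.normal(size=(T, d))
        _, scores = _enumeration_loglik(model, X)
        paths = list(itertools.product(range(K), repeat=T))
        best = paths[int(np.argmax(scores))]
        vit = viterbi_path(model, X)
        assert path_log_score(model, X, vit) == pytest.approx(
            max(scores), abs=1e-10
        )
        assert tuple(vit) == best

    def test_single_state_gives_iid_gaussian(self):
        rng = np.random.default_rng(6)
        model = _random_model(rng, 1, 2)
        X = rng.normal(size=(10, 2))
        loglik, gamma = forward_backward(model, X)
        iid = sum(
            multivariate_normal.logpdf(x, model.means[0], model.covs[0])
            for x in X
        )
        assert loglik == pytest.approx(iid, abs=1e-10)
        np.testing.assert_array_equal(gamma, 1.0)
        np.testing.assert_array_equal(viterbi_path(model, X), 0)

    def test_viterbi_beats_argmax_gamma_sequence(self):
        rng = np.random.default_rng(7)
        model = _random_model(rng, 3, 2)
        X = rng.normal(size=(12, 2))
        vit = viterbi_path(model, X)
        _, gamma = forward_backward(model, X)
        greedy = np.argmax(gamma, axis=1)
        assert path_log_score(model, X, vit) >= path_log_score(
            model, X, greedy
        ) - 1e-12

    def test_label_permutation_leaves_loglik_unchanged(self):
        rng = np.random.default_rng(8)
        model = _random_model(rng, 3, 2)
        X = rng.normal(size=(20, 2))
        ll, _ = forward_backward(model, X)
        perm = np.array([2, 0, 1])
        inv = np.argsort(perm)
        permuted = StickyHMMModel(
            pi0=model.pi0[perm], A=model.A[np.ix_(perm, perm)],
            means=model.means[perm], covs=model.covs[perm],
        )
        ll2, _ = forward_backward(permuted, X)
        assert ll2 == pytest.approx(ll, abs=1e-10)

    def test_non_finite_input_rejected(self):
        model = _random_model(np.random.default_rng(9), 2, 2)
        X = np.full((5, 2), np.nan)
        with pytest.raises(ValidationError):
            forward_backward(model, X)


def _latents_from_generator(seed, K_true=3, scale=3.0, n_trials=8, d=2,
                            gp_noise=0.25, gp_timescale=0.1):
    """Trial latents straight from the generative model, with truth.

    The default wander timescale (0.1 s) is below the 0.25 s bin, so the
    within-state noise is effectively white and the HMM's emission model
    is well-specified — the right regime for recovery checks.
    """
    # phase map: walk through the states in order (cycling when K < 5)
    phases = ["start", "jump out", "interaction", "return transit", "jump in"]
    cfg = SyntheticConfig(
        K_true=K_true, d_true=d, n_neurons=5, stickiness=10.0,
        gp_noise_sd=gp_noise, gp_timescale_s=gp_timescale,
        state_mean_scale=scale,
        phase_state_map={
            "hide": [(p, k % K_true) for k, p in enumerate(phases)]
        },
        roles=("hide",), free_states={},
    )
    rng = np.random.default_rng(seed)
    # equally spaced directions guarantee the means really are separated
    angles = 2 * np.pi * np.arange(K_true) / K_true
    means = np.zeros((K_true, d))
    means[:, 0] = scale * np.cos(angles)
    means[:, 1 % d] = scale * np.sin(angles)
    latents, states = {}, {}
    for tid in range(n_trials):
        s = sample_state_sequence(cfg, "hide", None, rng)
        x, _, _ = sample_activity(
            s, cfg, rng, state_means=means,
            loading=np.zeros((5, d)), baseline=np.zeros(5),
        )
        latents[tid], states[tid] = x, s
    return latents, states


def matched_accuracy(pred, true, K):
    from scipy.optimize import linear_sum_assignment

    conf = np.zeros((K, K))
    np.add.at(conf, (pred, true), 1)
    r, c = linear_sum_assignment(-conf)
    return conf[r, c].sum() / len(true)


class TestFitting:
    def test_single_state_fit_is_global_gaussian(self):
        rng = np.random.default_rng(0)
        trials = [rng.normal(size=(30, 2)) for _ in range(3)]
        cfg = HMMFitConfig(n_restarts=1, base_seed=0)
        model, diag = fit_sticky_hmm(trials, 1, cfg)
        X = np.concatenate(trials)
        np.testing.assert_allclose(model.means[0], X.mean(axis=0), atol=1e-6)
        # objective = iid Gaussian log-likelihood (transition prior adds
        # kappa * log 1 = 0 for the 1-state chain)
        iid = sum(
            multivariate_normal.logpdf(x, model.means[0], model.covs[0])
            for x in X
        )
        assert diag["objective_history"][-1] == pytest.approx(iid, rel=1e-6)

    def test_huge_kappa_forces_identity_transitions(self):
        latents, _ = _latents_from_generator(1)
        cfg = HMMFitConfig(kappa=1e6, n_restarts=2, base_seed=0)
        model, _ = fit_sticky_hmm(latents, 3, cfg)
        off_diag = model.A - np.diag(np.diag(model.A))
        assert off_diag.sum() < 1e-3 * model.K

    def test_objective_monotone_on_every_restart(self):
        latents, _ = _latents_from_generator(2, n_trials=4)
        for r in range(3):
            cfg = HMMFitConfig(n_restarts=1, base_seed=r)
            _, diag = fit_sticky_hmm(latents, 3, cfg)
            h = np.array(diag["objective_history"])
            assert np.all(np.diff(h) > -1e-8 * (np.abs(h[:-1]) + 1))

    def test_ground_truth_recovery(self):
        latents, states = _latents_from_generator(3, n_trials=10)
        cfg = HMMFitConfig(n_restarts=5, base_seed=0)
        model, _ = fit_sticky_hmm(latents, 3, cfg)
        seg = decode_segmentation(model, latents)
        pred = np.concatenate([seg[t] for t in sorted(latents)])
        true = np.concatenate([states[t] for t in sorted(latents)])
        assert matched_accuracy(pred, true, 3) >= 0.95

    def test_accuracy_increases_with_separation(self):
        accs = []
        for scale in (0.3, 1.0, 3.0):
            latents, states = _latents_from_generator(
                4, scale=scale, gp_noise=0.6
            )
            cfg = HMMFitConfig(n_restarts=3, base_seed=0)
            model, _ = fit_sticky_hmm(latents, 3, cfg)
            seg = decode_segmentation(model, latents)
            pred = np.concatenate([seg[t] for t in sorted(latents)])
            true = np.concatenate([states[t] for t in sorted(latents)])
            accs.append(matched_accuracy(pred, true, 3))
        assert accs[0] <= accs[1] <= accs[2] and accs[0] < accs[2]

    def test_restart_reproducibility(self):
        latents, _ = _latents_from_generator(5, n_trials=4)
        cfg = HMMFitConfig(n_restarts=3, base_seed=7)
        m1, d1 = fit_sticky_hmm(latents, 3, cfg)
        m2, d2 = fit_sticky_hmm(latents, 3, cfg)
        assert d1["restart_objectives"] == d2["restart_objectives"]
        np.testing.assert_array_equal(m1.means, m2.means)

    def test_k_larger_than_bins_rejected(self):
        with pytest.raises(ValidationError):
            fit_sticky_hmm([np.zeros((3, 1))], 10,
                           HMMFitConfig(n_restarts=1))


class TestModelSelection:
    def test_singleton_candidate_returned(self):
        latents, _ = _latents_from_generator(6, n_trials=10)
        cfg = HMMFitConfig(n_restarts=1, base_seed=0)
        K, scores = select_num_states(latents, [4], folds=5, config=cfg)
        assert K == 4 and set(scores) == {4}

    def test_scores_finite_and_k_recovered_nearby(self):
        latents, _ = _latents_from_generator(7, n_trials=12)
        cfg = HMMFitConfig(n_restarts=2, base_seed=0, max_iter=100)
        K, scores = select_num_states(
            latents, [2, 3, 4, 5], folds=6, config=cfg
        )
        assert all(np.isfinite(v) for v in scores.values())
        assert K in (2, 3, 4)  # K_true = 3 plus/minus one

    def test_empty_candidates_rejected(self):
        latents, _ = _latents_from_generator(8, n_trials=4)
        with pytest.raises(ValidationError):
            select_num_states(latents, [], folds=2)
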