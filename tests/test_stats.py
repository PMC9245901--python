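import math

import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

from neurostates.data import Segmentation, ValidationError, run_length_encode
from neurostates.stats import (
    _segments_per_trial,
    _shuffled_concat,
    behavioral_segmentation,
    conditional_prob_matrices,
    conditional_significance,
    entropy,
    holm_bonferroni,
    mi_significance,
    mutual_information,
    role_state_separation,
    state_behavior_timecourse,
)


class TestMutualInformation:
    def test_perfect_balanced_dependence(self):
        assert mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(
            math.log(2)
        )

    def test_independence_is_zero(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_matches_contingency_oracle_on_random_labels(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 4, size=200)
            b = rng.integers(0, 3, size=200)
            assert mutual_information(a, b) == pytest.approx(
                mutual_info_score(a, b), abs=1e-12
            )

    def test_self_mi_is_entropy(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 5, size=300)
        assert mutual_information(a, a) == pytest.approx(entropy(a), abs=1e-12)

    def test_invariant_to_label_permutation(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, size=150)
        b = rng.integers(0, 4, size=150)
        assert mutual_information(a, b) == pytest.approx(
            mutual_information(3 - a, b), abs=1e-12
        )
        assert mutual_information(a, b) >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mutual_information([0, 1], [0, 1, 2])


def _seg(labels_by_trial, w=0.25):
    return Segmentation(
        bin_width_s=w,
        labels={tid: np.asarray(v) for tid, v in labels_by_trial.items()},
    )


def _sticky_random(rng, n, K, mean_run=5):
    out = []
    while len(out) < n:
        out.extend([int(rng.integers(K))] * int(rng.geometric(1 / mean_run)))
    return np.array(out[:n])


class TestMISignificance:
    def test_single_segment_per_trial_gives_p_one(self):
        hmm = _seg({0: [1] * 10, 1: [2] * 8})
        beh = _seg({0: [0] * 5 + [1] * 5, 1: [0] * 4 + [1] * 4})
        res = mi_significance(hmm, beh, n_null=200, seed=0)
        assert res["p_value"] == 1.0

    def test_identical_many_segment_labeling_is_significant(self):
        rng = np.random.default_rng(3)
        labels = {t: _sticky_random(rng, 120, 5) for t in range(5)}
        hmm = _seg(labels)
        beh = _seg({t: v.copy() for t, v in labels.items()})
        res = mi_significance(hmm, beh, n_null=2000, seed=1)
        assert res["p"] < 0.001 and res["below_resolution"]

    def test_shuffle_preserves_segment_multiset(self):
        rng = np.random.default_rng(4)
        labels = _sticky_random(rng, 100, 4)
        seg = _seg({0: labels})
        per_trial = _segments_per_trial(seg, [0])
        for _ in range(20):
            fake = _shuffled_concat(per_trial, rng)
            orig = sorted(
                (l, last - first + 1) for l, first, last in
                run_length_encode(labels)
            )
            # merging of adjacent equal labels can only coarsen runs, so
            # compare the drawn segment multiset before concatenation
            labs, lens = per_trial[0]
            assert sorted(zip(labs, lens)) == orig
            assert len(fake) == len(labels)
            assert np.array_equal(np.sort(np.unique(fake)),
                                  np.sort(np.unique(labels)))

    def test_cyclic_null_size_and_rotation_zero(self):
        rng = np.random.default_rng(5)
        labels = {0: _sticky_random(rng, 40, 3), 1: _sticky_random(rng, 25, 3)}
        hmm = _seg(labels)
        beh = _seg({0: _sticky_random(rng, 40, 2),
                    1: _sticky_random(rng, 25, 2)})
        res = mi_significance(hmm, beh, null="cyclic_rotation")
        assert res["n_null"] == 65 - 1
        obs = mutual_information(hmm.concatenated(), beh.concatenated())
        assert res["observed_mi"] == pytest.approx(obs, abs=1e-12)

    def test_rejection_rate_calibrated_under_independence(self):
        # under a null generator the p-value should be near-uniform:
        # rejection at alpha=0.05 within [0.02, 0.10] over 200 datasets
        rng = np.random.default_rng(6)
        rejections = 0
        n_sets = 200
        for i in range(n_sets):
            labels = {t: _sticky_random(rng, 60, 4) for t in range(4)}
            beh = {t: _sticky_random(rng, 60, 3) for t in range(4)}
            res = mi_significance(
                _seg(labels), _seg(beh), n_null=400, seed=1000 + i
            )
            rejections += res["p_value"] <= 0.05
        assert 0.02 <= rejections / n_sets <= 0.10


class TestConditionals:
    def test_toy_joint_counts(self):
        hmm = [0, 0, 0, 1, 1]
        beh = ["a", "a", "a", "a", "b"]
        res = conditional_prob_matrices(hmm, beh)
        np.testing.assert_allclose(res.p_beh_given_state,
                                   [[1.0, 0.0], [0.5, 0.5]])
        np.testing.assert_allclose(
            res.p_state_given_beh, [[0.75, 0.25], [0.0, 1.0]]
        )

    def test_defined_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 4, 100)
        b = rng.integers(0, 3, 100)
        res = conditional_prob_matrices(a, b)
        np.testing.assert_allclose(
            res.p_beh_given_state[res.state_defined].sum(axis=1), 1.0
        )

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 3, 200)
        b = rng.integers(0, 2, 200)
        res = conditional_prob_matrices(a, b)
        for s in range(3):
            for v in range(2):
                expected = np.mean(b[a == s] == v)
                assert res.p_beh_given_state[s, v] == pytest.approx(expected)

    def test_identity_labeling_has_significant_diagonal(self):
        rng = np.random.default_rng(9)
        labels = {t: _sticky_random(rng, 100, 3) for t in range(4)}
        hmm = _seg(labels)
        beh = _seg({t: v.copy() for t, v in labels.items()})
        res = conditional_significance(hmm, beh, n_null=500, seed=0)
        diag = np.diag(res["stars_beh_given_state"])
        assert diag.all()

    def test_tiny_observed_probability_excluded(self):
        hmm = _seg({0: [0] * 999 + [1]})
        beh = _seg({0: ["a"] * 999 + ["b"]})
        res = conditional_significance(hmm, beh, n_null=50, seed=0,
                                       min_prob=0.01)
        # P(b | state 0) = 0.0... below the floor -> never starred
        assert not res["included_beh_given_state"][0, 1]
        assert not res["stars_beh_given_state"][0, 1]
        n_stars = (res["stars_beh_given_state"].sum()
                   + res["stars_state_given_beh"].sum())
        n_included = (res["included_beh_given_state"].sum()
                      + res["included_state_given_beh"].sum())
        assert n_stars <= n_included


class TestHolmBonferroni:
    def test_hand_worked_example(self):
        # 0.01 <= 0.05/3, 0.02 <= 0.05/2, 0.04 <= 0.05/1 -> all rejected
        np.testing.assert_array_equal(
            holm_bonferroni([0.01, 0.02, 0.04], alpha=0.05),
            [True, True, True],
        )

    def test_all_ones_reject_nothing(self):
        assert not holm_bonferroni([1.0, 1.0, 1.0]).any()

    def test_stops_at_first_failure(self):
        # 0.001 rejected; 0.03 > 0.05/2 stops the procedure
        np.testing.assert_array_equal(
            holm_bonferroni([0.001, 0.03, 0.04]), [True, False, False]
        )

    def test_dominates_plain_bonferroni(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.uniform(0, 0.2, size=8)
            holm = holm_bonferroni(p, 0.05)
            bonf = p <= 0.05 / len(p)
            assert np.all(holm[bonf])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.uniform(0, 1, size=10)
            expected = multipletests(p, alpha=0.05, method="holm")[0]
            np.testing.assert_array_equal(holm_bonferroni(p, 0.05), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_bonferroni([0.5, 1.5])


def _session_with_intervals(intervals_by_trial, n_bins=40, w=0.25):
    from neurostates.data import SpikeSession, Trial

    trials = []
    for tid, intervals in intervals_by_trial.items():
        start = tid * (n_bins * w + 5)
        trials.append(
            Trial(
                tid, "hide", start, start + n_bins * w,
                behavior_intervals=[
                    (lab, start + a, start + b) for lab, a, b in intervals
                ],
            )
        )
    return SpikeSession(session_id="tc", neurons=[], spikes=[], trials=trials)


class TestTimecourse:
    def test_single_event_single_state_is_flat_one(self):
        session = _session_with_intervals({0: [("darting", 3.0, 5.0)]})
        gammas = {0: np.ones((40, 1))}
        res = state_behavior_timecourse(gammas, session, "darting")
        np.testing.assert_allclose(res["profile"], 1.0)

    def test_one_hot_gamma_inside_events(self):
        session = _session_with_intervals({0: [("darting", 3.0, 5.0)]})
        g = np.zeros((40, 2))
        g[:, 0] = 1.0
        sel = slice(12, 20)  # bins covering 3-5 s
        g[sel, 0] = 0.0
        g[sel, 1] = 1.0
        gammas = {0: g}
        res = state_behavior_timecourse(gammas, session, "darting")
        lo, hi = res["event_span"]
        grid = res["grid"]
        inside = (grid > lo + 0.25) & (grid < hi - 0.25)
        np.testing.assert_allclose(res["profile"][1, inside], 1.0, atol=1e-6)

    def test_absent_behavior_returns_none(self):
        session = _session_with_intervals({0: []})
        assert state_behavior_timecourse({0: np.ones((40, 1))}, session,
                                         "darting") is None

    def test_two_events_match_resampling_oracle(self):
        from neurostates.preprocessing import ReferenceAnchors, stretch_series

        session = _session_with_intervals(
            {0: [("darting", 3.0, 5.0)], 1: [("darting", 2.0, 6.0)]}
        )
        rng = np.random.default_rng(12)
        gammas = {t: rng.dirichlet(np.ones(3), size=40) for t in (0, 1)}
        res = state_behavior_timecourse(gammas, session, "darting", pad_s=1.0)
        med = 3.0  # median event length of {2, 4}
        ref = ReferenceAnchors(
            "event", ("a", "b", "c", "d"),
            np.array([0.0, 1.0, 1.0 + med, 2.0 + med]), 0.25,
        )
        profiles = []
        for trial, (a, b) in zip(session.trials, [(3.0, 5.0), (2.0, 6.0)]):
            g = gammas[trial.trial_id]
            centers = trial.start_s + (np.arange(40) + 0.5) * 0.25
            w0, w1 = a + trial.start_s - 1.0, b + trial.start_s + 1.0
            # recompute window-relative warp independently
            sel = (centers >= w0 - 0.25) & (centers <= w1 + 0.25)
            anchors = np.array([0.0, 1.0, 1.0 + (b - a), (b - a) + 2.0])
            profiles.append(
                stretch_series(g[sel].T, centers[sel] - w0, anchors, ref,
                               "linear")
            )
        np.testing.assert_allclose(res["profile"], np.mean(profiles, axis=0),
                                   atol=1e-10)


class TestRoleSeparation:
    def _seg_roles(self, labels_by_trial, roles):
        return _seg(labels_by_trial), roles

    def test_pure_observing_state(self):
        seg, roles = self._seg_roles(
            {0: [0] * 10, 1: [1] * 10},
            {0: "seek", 1: "observing"},
        )
        res = role_state_separation(seg, roles, n_states=2, n_null=100, seed=0)
        assert res["p_observing_given_state"][1] == 1.0
        assert res["p_observing_given_state"][0] == 0.0

    def test_perfect_partition_significant_with_zero_mixing(self):
        rng = np.random.default_rng(13)
        play = {t: _sticky_random(rng, 80, 3) for t in range(3)}
        obs = {t + 3: _sticky_random(rng, 80, 3) + 3 for t in range(3)}
        seg = _seg({**play, **obs})
        roles = {t: "seek" for t in play} | {t: "observing" for t in obs}
        res = role_state_separation(seg, roles, n_states=6, n_null=2000, seed=1)
        assert res["mixing_fraction"] == 0.0
        assert res["below_resolution"]

    def test_uniform_spread_fully_mixed(self):
        labels = {0: np.tile([0, 1], 50), 1: np.tile([0, 1], 50)}
        seg, roles = self._seg_roles(labels, {0: "seek", 1: "observing"})
        res = role_state_separation(seg, roles, n_states=2, n_null=100, seed=2)
        np.testing.assert_allclose(res["p_observing_given_state"], 0.5)
        assert res["mixing_fraction"] == 1.0

    def test_missing_role_rejected(self):
        seg, roles = self._seg_roles({0: [0] * 10}, {0: "seek"})
        with pytest.raises(ValidationError):
            role_state_separation(seg, roles)


class TestBehavioralSegmentation:
    def test_intervals_override_phase_labels(self):
        from neurostates.data import SpikeSession, Trial

        trial = Trial(
            0, "hide", 0.0, 10.0,
            phase_points={"start": 0.0, "jump out": 4.0},
            behavior_intervals=[("darting", 5.0, 6.0)],
        )
        s = SpikeSession("b", [], [], [trial])
        seg = behavioral_segmentation(s, 0.25)
        vec = seg.labels[0]
        assert vec[0] == "start"
        assert vec[17] == "jump out"
        assert all(v == "darting" for v in vec[20:24])
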