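"""Arena simulation, adaptive sampling, evidence accrual and inverse MDS."""

import numpy as np
import pytest

from actionrsa import (
    ArrangementSession,
    ArrangementTrial,
    InverseMDS,
    euclidean_rdm,
    inverse_mds_estimate,
    kendall_tau_a,
    lift_the_weakest,
    loo_reliability,
    make_rdm,
    run_session,
    simulate_arranger,
    update_evidence,
)
from actionrsa.arrangement import (SessionComplete, exclude_arrangers,
                                   read_session, write_session)


def planar_truth(n, rng):
    """A 2-D-embeddable ground truth (points in the plane)."""
    return euclidean_rdm(rng.normal(size=(n, 2)))


class TestSimulateArranger:
    def test_equilateral_triangle(self):
        truth = make_rdm([1.0, 1.0, 1.0], 3)
        trial = simulate_arranger(truth, [0, 1, 2], placement_noise=0.0)
        from scipy.spatial.distance import pdist

        d = pdist(trial.coords)
        assert np.allclose(d, d[0], atol=1e-9)

    def test_noiseless_preserves_rank_order(self, rng):
        truth = planar_truth(8, rng)
        trial = simulate_arranger(truth, np.arange(8), placement_noise=0.0)
        from scipy.spatial.distance import pdist

        assert kendall_tau_a(pdist(trial.coords), truth.values).tau_a == 1.0

    def test_heavy_noise_destroys_structure(self, rng):
        truth = planar_truth(8, rng)
        taus = []
        for s in range(40):
            trial = simulate_arranger(truth, np.arange(8),
                                      placement_noise=50.0, seed=s)
            from scipy.spatial.distance import pdist

            taus.append(kendall_tau_a(pdist(trial.coords), truth.values).tau_a)
        assert abs(np.mean(taus)) < 0.2

    def test_degenerate_subrdm_warns(self):
        truth = make_rdm([0.0, 0.0, 0.0], 3)
        with pytest.warns(UserWarning, match="degenerate"):
            trial = simulate_arranger(truth, [0, 1, 2], placement_noise=0.0)
        assert np.allclose(trial.coords, 0.0)

    def test_coords_inside_disk(self, rng):
        truth = planar_truth(8, rng)
        trial = simulate_arranger(truth, np.arange(8), placement_noise=0.3,
                                  seed=3)
        assert np.all(np.hypot(*trial.coords.T) <= 1 + 1e-9)


class TestUpdateEvidence:
    def test_opposite_rim_points_saturate(self):
        sess = ArrangementSession(3)
        trial = ArrangementTrial([0, 1, 2],
                                 [[-1.0, 0.0], [1.0, 0.0], [0.0, 0.0]])
        update_evidence(trial, sess)
        assert sess.evidence[0] == pytest.approx(1.0)  # pair (0,1), d=2

    def test_coincident_points_add_nothing(self):
        sess = ArrangementSession(3)
        trial = ArrangementTrial([0, 1, 2],
                                 [[0.3, 0.3], [0.3, 0.3], [-0.5, 0.0]])
        update_evidence(trial, sess)
        assert sess.evidence[0] == 0.0

    def test_multiplicative_accumulation(self):
        # w = 0.3 per trial requires distance 2*sqrt(0.3)
        d = 2 * np.sqrt(0.3)
        sess = ArrangementSession(3)
        trial = ArrangementTrial([0, 1, 2],
                                 [[-d / 2, 0.0], [d / 2, 0.0], [0.0, 0.9]])
        update_evidence(trial, sess)
        update_evidence(trial, sess)
        assert sess.evidence[0] == pytest.approx(1 - 0.7**2)
        assert sess.evidence[0] >= 0.5  # reaches the criterion

    def test_evidence_monotone_over_trials(self, rng):
        truth = planar_truth(10, rng)
        sess = ArrangementSession(10, max_trial_size=5, max_trials=50)
        prev = sess.evidence.copy()
        while not sess.complete:
            subset = lift_the_weakest(sess, seed=rng)
            update_evidence(simulate_arranger(truth, subset, 0.05, rng), sess)
            assert np.all(sess.evidence >= prev - 1e-15)
            prev = sess.evidence.copy()


class TestLiftTheWeakest:
    def test_initial_subsets_cover_all_items(self, rng):
        truth = planar_truth(20, rng)
        sess = ArrangementSession(20, max_trial_size=5, max_trials=100)
        seen_counts = np.zeros(20)
        while seen_counts.min() == 0:
            subset = lift_the_weakest(sess, seed=rng)
            # no item repeats before every item has appeared once
            assert seen_counts[subset].max() <= seen_counts.min() + 1
            seen_counts[subset] += 1
            update_evidence(simulate_arranger(truth, subset, 0.02, rng), sess)

    def test_weakest_pair_included(self, rng):
        from actionrsa import condensed_index

        sess = ArrangementSession(8, max_trial_size=4, max_trials=100)
        sess.evidence[:] = 0.9
        sess.evidence[condensed_index(2, 6, 8)] = 0.1  # unique weakest pair
        subset = lift_the_weakest(sess, seed=rng)
        assert 2 in subset and 6 in subset

    def test_complete_session_raises(self, rng):
        sess = ArrangementSession(4, max_trial_size=4)
        sess.evidence[:] = 0.9
        with pytest.raises(SessionComplete):
            lift_the_weakest(sess, seed=rng)


class TestInverseMDS:
    def test_single_full_trial_perfect_recovery(self, rng):
        truth = planar_truth(9, rng)
        sess = ArrangementSession(9, max_trial_size=9)
        update_evidence(simulate_arranger(truth, np.arange(9), 0.0, rng), sess)
        est = inverse_mds_estimate(sess)
        assert kendall_tau_a(est.values, truth.values).tau_a == 1.0

    def test_scale_invariance_of_trials(self, rng):
        truth = planar_truth(7, rng)
        trial = simulate_arranger(truth, np.arange(7), 0.0, rng)
        shrunk = ArrangementTrial(trial.items, trial.coords * 0.5)
        s1 = ArrangementSession(7)
        update_evidence(trial, s1)
        s2 = ArrangementSession(7)
        update_evidence(trial, s2)
        update_evidence(shrunk, s2)
        a = inverse_mds_estimate(s1)
        b = inverse_mds_estimate(s2)
        assert np.allclose(a.values, b.values, atol=1e-6)

    def test_rotation_reflection_invariance(self, rng):
        truth = planar_truth(7, rng)
        trial = simulate_arranger(truth, np.arange(7), 0.0, rng)
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        R = R @ np.diag([1, -1])
        s1, s2 = ArrangementSession(7), ArrangementSession(7)
        update_evidence(trial, s1)
        update_evidence(ArrangementTrial(trial.items, trial.coords @ R.T), s2)
        assert np.allclose(inverse_mds_estimate(s1).values,
                           inverse_mds_estimate(s2).values, atol=1e-9)

    def test_unit_rms_normalization(self, rng):
        truth = planar_truth(10, rng)
        sess = run_session(truth, placement_noise=0.02, max_trial_size=6,
                           seed=rng)
        est = inverse_mds_estimate(sess)
        assert np.sqrt(np.mean(est.values**2)) == pytest.approx(1.0)

    def test_adaptive_session_recovery(self, rng):
        truth = planar_truth(20, rng)
        sess = run_session(truth, placement_noise=0.02, max_trial_size=8,
                           seed=99)
        est = inverse_mds_estimate(sess)
        assert kendall_tau_a(est.values, truth.values).tau_a >= 0.9

    def test_missing_pair_raises(self):
        sess = ArrangementSession(5)
        trial = ArrangementTrial([0, 1, 2],
                                 [[0.0, 0.5], [0.5, -0.5], [-0.5, -0.5]])
        update_evidence(trial, sess)
        with pytest.raises(ValueError, match="co-presented"):
            inverse_mds_estimate(sess)


class TestLooReliability:
    def test_identical_subjects_one(self, rng):
        r = euclidean_rdm(rng.normal(size=(10, 3)))
        assert np.allclose(loo_reliability([r] * 5), 1.0)

    def test_independent_subjects_near_zero(self, rng):
        rdms = [euclidean_rdm(rng.normal(size=(50, 3))) for _ in range(20)]
        assert abs(np.nanmean(loo_reliability(rdms))) < 0.05

    def test_reliability_decreases_with_noise(self, rng):
        base = rng.normal(size=(15, 3))
        means = []
        for sd in (0.1, 0.5, 1.5, 4.0):
            rdms = [euclidean_rdm(base + rng.normal(0, sd, base.shape))
                    for _ in range(6)]
            means.append(np.nanmean(loo_reliability(rdms)))
        assert np.all(np.diff(means) < 0)

    def test_too_few_subjects(self, rng):
        r = euclidean_rdm(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            loo_reliability([r, r])


class TestExcludeArrangers:
    def test_outlier_subject_dropped(self, rng):
        base = rng.normal(size=(8, 2))
        rdms = [euclidean_rdm(base + rng.normal(0, 0.05, base.shape))
                for _ in range(10)]
        rdms.append(euclidean_rdm(rng.normal(size=(8, 2))))  # unrelated
        keep, corr = exclude_arrangers(rdms)
        assert not keep[-1] and keep[:-1].all()

    def test_catch_failure_dropped(self, rng):
        base = rng.normal(size=(8, 2))
        rdms = [euclidean_rdm(base + rng.normal(0, 0.05, base.shape))
                for _ in range(6)]
        catch = np.array([True] * 5 + [False])
        keep, _ = exclude_arrangers(rdms, catch)
        assert not keep[-1]


class TestSessionIO:
    def test_roundtrip(self, rng, tmp_path):
        truth = planar_truth(8, rng)
        sess = run_session(truth, placement_noise=0.05, max_trial_size=5,
                           max_trials=60, seed=5)
        p = tmp_path / "session_000.txt"
        write_session(sess, p)
        back = read_session(p)
        assert back.n_items == sess.n_items
        assert len(back.trials) == len(sess.trials)
        assert np.allclose(back.evidence, sess.evidence, atol=1e-12)
        assert np.allclose(inverse_mds_estimate(back).values,
                           inverse_mds_estimate(sess).values, atol=1e-12)

    def test_degenerate_two_item_trial_preserved(self, tmp_path):
        sess = ArrangementSession(3)
        with pytest.warns(UserWarning, match="degenerate"):
            t = ArrangementTrial([0, 1], [[0.0, 0.5], [0.0, -0.5]])
        update_evidence(t, sess)
        p = tmp_path / "session_deg.txt"
        write_session(sess, p)
        back = read_session(p)
        assert len(back.trials) == 1
        assert back.trials[0].items.size == 2

    def test_missing_metadata_named(self, tmp_path):
        p = tmp_path / "session_bad.txt"
        p.write_text("trial,item,x,y\n0,0,0.1,0.2\n")
        with pytest.raises(ValueError, match="n_items"):
            read_session(p)
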