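"""MSM estimation, validation and kinetics against exact oracles."""

import numpy as np
import pytest

from idpdissect import msm, synthetic
from idpdissect.msm import (MicrostateAssignment, bootstrap_populations,
                            ck_test, cluster_microstates,
                            estimate_transition_matrix, implied_timescales,
                            mfpt, mfpt_matrix, pcca_coarse_grain, select_lag,
                            select_n_macrostates,
                            timescales_from_eigenvalues, vamp2_score)


def _assignment(labels, k, boundaries=(0,)):
    return MicrostateAssignment(np.asarray(labels), np.zeros((k, 1)), k, 0,
                                np.asarray(boundaries))


class TestClustering:
    def test_two_separated_clouds_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(100, 2)) * 0.1
        b = rng.normal(size=(100, 2)) * 0.1 + 5.0
        x = np.vstack([a, b])
        truth = np.repeat([0, 1], 100)
        assign = cluster_microstates(x, 2, seed=1)
        same = (assign.labels == truth).mean()
        assert same in (0.0, 1.0)  # equal up to label permutation

    def test_identical_points_dedup_guard(self):
        assign = cluster_microstates(np.ones((50, 2)), 5, seed=0)
        assert assign.k == 1
        assert np.all(assign.labels == 0)

    def test_k_exceeding_frames_raises(self):
        with pytest.raises(ValueError):
            cluster_microstates(np.zeros((3, 2)), 5, seed=0)

    def test_inertia_equals_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(60, 2))
        assign = cluster_microstates(x, 4, seed=2)
        brute = sum(np.sum((x[i] - assign.centers[assign.labels[i]]) ** 2)
                    for i in range(60))
        assert assign.inertia == pytest.approx(brute, rel=1e-9)


class TestTransitionEstimation:
    def test_hand_counted_sliding_pairs(self):
        counts = msm.count_transitions([np.array([0, 0, 1, 1])], 2, 1)
        assert counts.tolist() == [[1.0, 1.0], [0.0, 1.0]]

    def test_deterministic_cycle(self):
        labels = np.tile([0, 1], 50)
        model = estimate_transition_matrix(_assignment(labels, 2), 1,
                                           mode="counts")
        assert np.allclose(model.transition_matrix, [[0, 1], [1, 0]])

    def test_no_cross_boundary_counting(self):
        # two trajectories; the 1->0 junction must not be counted
        labels = np.array([0, 0, 1, 1, 0, 0, 0, 0])
        counts = msm.count_transitions(
            _assignment(labels, 2, boundaries=(0, 4)).split_labels(), 2, 1)
        assert counts[1, 0] == 0

    def test_reversible_satisfies_detailed_balance(self):
        rng = np.random.default_rng(2)
        t_true = np.array([[0.9, 0.08, 0.02], [0.05, 0.9, 0.05],
                           [0.02, 0.08, 0.9]])
        labels = synthetic.sample_markov_chain(t_true, 30_000, rng)
        model = estimate_transition_matrix(_assignment(labels, 3), 1)
        flux = model.stationary[:, None] * model.transition_matrix
        assert np.abs(flux - flux.T).max() < 1e-8
        assert np.allclose(model.transition_matrix.sum(axis=1), 1.0,
                           atol=1e-10)

    def test_spectral_sanity(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 4, 10_000)
        model = estimate_transition_matrix(_assignment(labels, 4), 1)
        assert model.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.abs(model.eigenvalues) <= 1.0 + 1e-10)
        assert np.all(model.stationary >= 0)
        assert model.stationary.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(model.stationary @ model.transition_matrix,
                           model.stationary, atol=1e-8)


class TestImpliedTimescales:
    def test_closed_form(self):
        assert timescales_from_eigenvalues(np.array([0.8]), 1)[0] == \
            pytest.approx(4.48142011, abs=1e-6)

    def test_reducible_flagged_infinite(self):
        assert timescales_from_eigenvalues(np.array([1.0]), 1)[0] == np.inf

    def test_symmetric_two_state_eigenvalue(self):
        rng = np.random.default_rng(4)
        t = np.array([[0.9, 0.1], [0.1, 0.9]])
        labels = synthetic.sample_markov_chain(t, 200_000, rng)
        model = estimate_transition_matrix(_assignment(labels, 2), 1)
        assert model.eigenvalues[1] == pytest.approx(0.8, abs=0.01)

    def test_select_lag_levels_off(self):
        table = msm.ImpliedTimescalesTable(
            lags=np.array([1, 2, 4, 8]),
            timescales=np.array([[10.0], [40.0], [43.0], [45.0]]),
            resolved=np.ones((4, 1), dtype=bool))
        assert select_lag(table) == 2

    def test_select_n_macrostates_gap(self):
        # three slow processes then a big drop: 4 macrostates
        assert select_n_macrostates(np.array([100.0, 90.0, 80.0, 2.0])) == 4


class TestVamp2:
    def test_iid_labels_score_one(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 5, 100_000)
        assert vamp2_score(labels, 1) == pytest.approx(1.0, abs=0.01)

    def test_two_block_metastable_score_two(self):
        rng = np.random.default_rng(6)
        t = np.array([[0.999, 0.001], [0.001, 0.999]])
        labels = synthetic.sample_markov_chain(t, 200_000, rng)
        assert vamp2_score(labels, 1) == pytest.approx(2.0, abs=0.05)

    def test_monotone_in_n_processes(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 6, 5_000)
        scores = [vamp2_score(labels, 1, n_processes=n) for n in (1, 2, 4, 6)]
        assert all(a <= b + 1e-12 for a, b in zip(scores[:-1], scores[1:]))

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            vamp2_score(np.array([0, 1]), 5)


class TestPcca:
    def _block_model(self, coupling=0.005):
        rng = np.random.default_rng(8)
        c = coupling
        t = np.array([[0.89 - c, 0.1, c / 2, c / 2],
                      [0.1, 0.89 - c, c / 2, c / 2],
                      [c / 2, c / 2, 0.89 - c, 0.1],
                      [c / 2, c / 2, 0.1, 0.89 - c]])
        t /= t.sum(axis=1)[:, None]
        labels = synthetic.sample_markov_chain(t, 100_000, rng)
        return estimate_transition_matrix(_assignment(labels, 4), 1)

    def test_blocks_recovered_exactly(self):
        macro = pcca_coarse_grain(self._block_model(), 2)
        assert macro.crisp_map[0] == macro.crisp_map[1]
        assert macro.crisp_map[2] == macro.crisp_map[3]
        assert macro.crisp_map[0] != macro.crisp_map[2]

    def test_membership_rows_sum_to_one(self):
        macro = pcca_coarse_grain(self._block_model(), 2)
        assert np.allclose(macro.memberships.sum(axis=1), 1.0, atol=1e-10)
        assert macro.populations.sum() == pytest.approx(1.0, abs=1e-6)

    def test_identity_coarse_graining(self):
        model = self._block_model()
        macro = pcca_coarse_grain(model, model.transition_matrix.shape[0])
        assert np.array_equal(macro.memberships,
                              np.eye(model.transition_matrix.shape[0]))

    def test_non_reversible_input_rejected(self):
        rng = np.random.default_rng(9)
        labels = synthetic.sample_markov_chain(
            np.array([[0.9, 0.1], [0.2, 0.8]]), 5_000, rng)
        model = estimate_transition_matrix(_assignment(labels, 2), 1,
                                           mode="counts")
        with pytest.raises(ValueError, match="reversible"):
            pcca_coarse_grain(model, 2)


class TestCkTest:
    def test_multiple_one_has_zero_deviation(self):
        rng = np.random.default_rng(10)
        t = np.array([[0.95, 0.05], [0.05, 0.95]])
        labels = synthetic.sample_markov_chain(t, 50_000, rng)
        res = ck_test(_assignment(labels, 2), 1, [1, 2], 2)
        assert np.allclose(res["deviation"][0], 0.0, atol=1e-12)

    def test_exact_markov_chain_consistent(self):
        rng = np.random.default_rng(11)
        t = np.array([[0.98, 0.02], [0.02, 0.98]])
        labels = synthetic.sample_markov_chain(t, 200_000, rng)
        res = ck_test(_assignment(labels, 2), 1, [1, 2, 5, 10], 2)
        assert np.nanmax(res["deviation"]) < 0.02

    def test_semi_markov_deviation_detected(self):
        # deterministic dwell of 20 frames: strongly non-exponential
        labels = np.tile(np.repeat([0, 1], 20), 2_000)
        res = ck_test(_assignment(labels, 2), 1, [1, 10], 2)
        assert np.nanmax(res["deviation"][1]) > 0.05


class TestMfpt:
    def _model(self, t):
        t = np.asarray(t, dtype=float)
        pi = synthetic.stationary_distribution(t)
        return msm.TransitionModel(1, t, t, np.arange(t.shape[0]),
                                   np.linalg.eigvals(t), pi, True)

    def test_source_equals_target_is_zero(self):
        model = self._model([[0.9, 0.1], [0.1, 0.9]])
        assert mfpt(model, [0], [0]) == 0.0

    def test_two_state_geometric_oracle(self):
        model = self._model([[0.9, 0.1], [0.0, 1.0]])
        assert mfpt(model, [0], [1]) == pytest.approx(10.0, abs=1e-9)

    def test_three_state_matches_monte_carlo(self):
        rng = np.random.default_rng(12)
        t = rng.dirichlet(np.ones(3) * 2, size=3)
        model = self._model(t)
        analytic = mfpt(model, [0], [2])
        cum = np.cumsum(t, axis=1)
        times = []
        for _ in range(100_000):
            s, n = 0, 0
            while s != 2:
                s = int(np.searchsorted(cum[s], rng.random()))
                n += 1
            times.append(n)
        assert analytic == pytest.approx(np.mean(times), rel=0.02)

    def test_unreachable_target_is_infinite(self):
        t = np.array([[1.0, 0.0], [0.5, 0.5]])
        model = msm.TransitionModel(1, t, t, np.arange(2),
                                    np.linalg.eigvals(t),
                                    np.array([1.0, 0.0]), False)
        assert mfpt(model, [0], [1]) == np.inf


class TestBootstrap:
    def _trajs(self, rng, n=4, length=20_000, identical=False):
        t = np.array([[0.97, 0.02, 0.01], [0.02, 0.97, 0.01],
                      [0.01, 0.01, 0.98]])
        if identical:
            one = synthetic.sample_markov_chain(t, length, rng)
            return [one.copy() for _ in range(n)], t
        return [synthetic.sample_markov_chain(t, length, rng)
                for _ in range(n)], t

    def test_identical_trajectories_zero_std(self):
        rng = np.random.default_rng(13)
        trajs, _ = self._trajs(rng, identical=True)
        boot = bootstrap_populations(trajs, 3, 1, 3, n_iter=10, seed=0)
        assert np.allclose(boot.population_std, 0.0, atol=1e-12)

    def test_populations_normalised_and_close_to_truth(self):
        rng = np.random.default_rng(14)
        trajs, t = self._trajs(rng)
        boot = bootstrap_populations(trajs, 3, 1, 3, n_iter=10, seed=0)
        assert boot.populations.sum() == pytest.approx(1.0, abs=1e-6)
        pi = synthetic.stationary_distribution(t)
        # identity coarse-graining: macrostates are the microstates
        perm = boot.crisp_map
        assert np.abs(boot.populations[perm] - pi).max() < 0.05

    def test_single_trajectory_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_populations([np.zeros(10, dtype=int)], 1, 1, 1)


def test_mfpt_matrix_macrostates():
    t = np.array([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]])
    pi = synthetic.stationary_distribution(t)
    model = msm.TransitionModel(1, t, t, np.arange(3), np.linalg.eigvals(t),
                                pi, True)
    mat = mfpt_matrix(model, np.array([0, 0, 1]), 2)
    assert mat[0, 0] == 0.0
    assert mat[0, 1] > 0 and mat[1, 0] > 0
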