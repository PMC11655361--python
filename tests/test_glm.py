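import numpy as np
import pytest

from smbuffers.glm import (GlmTaskData, build_neuron_design, fit_and_test,
                           trajectory_glm, cross_structure_glm,
                           _next_place_labels)
from smbuffers.maze import MazeGraph, generate_task_set
from smbuffers.synthetic import (AgentPolicy, simulate_behaviour,
                                 simulate_rate_spikes)
from smbuffers.task_space import bin_session, normalize_activity


def make_task_data(behaviours, binned, rate_fn, seed0):
    data = []
    for i, (beh, bs) in enumerate(zip(behaviours, binned)):
        spk = simulate_rate_spikes(beh, rate_fn, seed=seed0 + i)
        st = spk["time_s"].to_numpy()
        act = normalize_activity(st, beh.trials, task_id=str(i))
        data.append(GlmTaskData(act, bs, st, beh.trials))
    return data


PLACE = lambda ang, gp, node: 0.5 + 12.0 * (node == 6)
GP = lambda ang, gp, node: 0.5 + 12.0 * np.exp(
    3 * (np.cos(np.radians(gp - 300)) - 1))
FLAT = lambda ang, gp, node: 4.0 + 0 * ang


class TestVerdicts:
    def test_place_cell(self, behaviours3, binned3):
        res = fit_and_test(make_task_data(behaviours3, binned3, PLACE, 100),
                           n_perm=100, seed=0)
        assert res["place"].tuned
        assert not res["goal_progress"].tuned

    def test_gp_cell(self, behaviours3, binned3):
        res = fit_and_test(make_task_data(behaviours3, binned3, GP, 200),
                           n_perm=100, seed=0)
        assert res["goal_progress"].tuned
        assert not res["place"].tuned

    def test_flat_cell_untuned(self, behaviours3, binned3):
        res = fit_and_test(make_task_data(behaviours3, binned3, FLAT, 300),
                           n_perm=100, seed=0)
        assert not res["place"].tuned
        assert not res["goal_progress"].tuned

    def test_single_task_rejected(self, behaviours3, binned3):
        data = make_task_data(behaviours3[:1], binned3[:1], FLAT, 1)
        with pytest.raises(ValueError):
            fit_and_test(data)


class TestDesign:
    def test_no_leakage_between_folds(self, behaviours3, binned3):
        """Zeroing the held-out period's activity leaves every training mean
        unchanged."""
        from smbuffers.glm import _fold_level_means
        data = make_task_data(behaviours3, binned3, PLACE, 100)
        d = build_neuron_design(data)
        L = 9
        lv = d.labels["place"]
        codes = d.fold * L + lv
        means = _fold_level_means(d.y[None, :], codes, d.n_folds * L,
                                  d.n_folds, L)
        y2 = d.y.copy()
        y2[d.fold == 3] = 0.0
        means2 = _fold_level_means(y2[None, :], codes, d.n_folds * L,
                                   d.n_folds, L)
        assert np.allclose(means[0, 3], means2[0, 3])

    def test_fold_row_count(self, behaviours3, binned3):
        data = make_task_data(behaviours3, binned3, FLAT, 2)
        d = build_neuron_design(data)
        act = data[1].act
        rows = np.sum(d.fold == 4 + 1)  # task 1, state B
        assert rows == act.n_trials * act.cfg.bins_per_state

    def test_next_place_labels(self, maze):
        nodes = np.array([1, 1, 2, 2, 2, 5, 5, 4])
        labels = _next_place_labels(nodes, maze)
        from smbuffers.glm import _edge_codes
        codes = _edge_codes(maze)
        assert labels[0] == codes[(1, 2)]
        assert labels[2] == codes[(2, 5)]
        assert labels[5] == codes[(5, 4)]
        assert labels[-1] == -1  # tail has no next step


class TestTrajectory:
    def test_trajectory_cell_flagged(self, maze, behaviours3, binned3):
        """A cell firing only on 5 -> 6 steps passes the trajectory screen."""
        data = []
        for i, (beh, bs) in enumerate(zip(behaviours3, binned3)):
            labels = _next_place_labels(bs.flat("node"), maze)
            from smbuffers.glm import _edge_codes
            code = _edge_codes(maze)[(5, 6)]
            on = (labels == code).reshape(bs.n_trials, bs.n_bins)
            # inject spikes directly at the flagged bins plus sparse noise
            rng = np.random.default_rng(50 + i)
            bt = bs.flat("bin_time")[on.reshape(-1)]
            spikes = np.sort(np.concatenate(
                [bt + rng.random(len(bt)) * 0.05,
                 rng.uniform(bt.min(), bt.max(), 200)]))
            act = normalize_activity(spikes, beh.trials, task_id=str(i))
            data.append(GlmTaskData(act, bs, spikes, beh.trials))
        v = trajectory_glm(data, n_perm=100, seed=1)
        assert v.tuned

    def test_gp_cell_not_flagged(self, behaviours3, binned3):
        data = make_task_data(behaviours3, binned3, GP, 400)
        v = trajectory_glm(data, n_perm=100, seed=2)
        assert not v.tuned


@pytest.fixture(scope="module")
def structures(maze):
    t4 = generate_task_set(maze, 2, seed=21)
    t5 = generate_task_set(maze, 2, seed=22, structure="ABCDE")
    b4 = [simulate_behaviour(maze, t, AgentPolicy(epsilon=0.9), 12,
                             seed=60 + i) for i, t in enumerate(t4)]
    b5 = [simulate_behaviour(maze, t, AgentPolicy(epsilon=0.9), 12,
                             seed=80 + i) for i, t in enumerate(t5)]
    s4 = [bin_session(b.trials, b.positions, maze) for b in b4]
    s5 = [bin_session(b.trials, b.positions, maze) for b in b5]
    return (b4, s4), (b5, s5)


class TestCrossStructure:
    def test_gp_invariant_neuron_generalizes(self, structures):
        (b4, s4), (b5, s5) = structures
        test_d = make_task_data(b4, s4, GP, 500)
        train_d = make_task_data(b5, s5, GP, 600)
        res = cross_structure_glm(train_d, test_d, n_perm=100, seed=3)
        assert res["goal_progress"].tuned

    def test_structure_specific_neuron_fails(self, structures):
        """A neuron whose goal-progress phase differs between structures does
        not generalize across them."""
        (b4, s4), (b5, s5) = structures
        GP2 = lambda ang, gp, node: 0.5 + 12.0 * np.exp(
            3 * (np.cos(np.radians(gp - 120)) - 1))
        test_d = make_task_data(b4, s4, GP, 700)
        train_d = make_task_data(b5, s5, GP2, 800)
        res = cross_structure_glm(train_d, test_d, n_perm=100, seed=4)
        assert not res["goal_progress"].tuned

    def test_flat_neuron_fails(self, structures):
        (b4, s4), (b5, s5) = structures
        res = cross_structure_glm(make_task_data(b5, s5, FLAT, 900),
                                  make_task_data(b4, s4, FLAT, 950),
                                  n_perm=100, seed=5)
        assert not res["goal_progress"].tuned
        assert not res["place"].tuned
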