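import numpy as np
import pandas as pd
import pytest

from smbuffers.maze import TaskConfig
from smbuffers.synthetic import (AgentPolicy, OfflineGeneratorSpec,
                                 OfflineModule, SyntheticNeuronSpec,
                                 anchor_visit_times, simulate_behaviour,
                                 simulate_offline, simulate_spikes,
                                 unwrapped_angle)
from smbuffers.task_space import normalize_activity


@pytest.fixture(scope="module")
def behaviour(maze):
    task = TaskConfig((1, 9, 5, 7))
    return simulate_behaviour(maze, task, AgentPolicy(epsilon=1.0), 20, seed=2)


class TestBehaviourGenerator:
    def test_deterministic_under_seed(self, maze):
        task = TaskConfig((3, 5, 8, 1))
        a = simulate_behaviour(maze, task, AgentPolicy(), 5, seed=7)
        b = simulate_behaviour(maze, task, AgentPolicy(), 5, seed=7)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_rewards_follow_task_logic(self, behaviour):
        rew = behaviour.events[behaviour.events["event"] == "reward"]
        locs = rew["location"].to_numpy()
        start = np.flatnonzero(locs == 1)[0]
        expected = np.tile([1, 9, 5, 7], len(locs))[:len(locs) - start]
        assert np.array_equal(locs[start:], expected)

    def test_tone_at_every_reward_a(self, behaviour):
        tones = behaviour.events[behaviour.events["event"] == "tone"]
        rew_a = behaviour.events[(behaviour.events["event"] == "reward")
                                 & (behaviour.events["location"] == 1)]
        assert len(tones) == len(rew_a)

    def test_reward_count_per_trial_equals_periodicity(self, behaviour):
        tab = behaviour.trials.table
        assert (tab.groupby("trial").size() == 4).all()


class TestSpikeGenerator:
    def test_delta_bump_zero_lag_spikes_at_anchor(self, maze, behaviour):
        """A near-delta bump with zero lag fires only around anchor visits."""
        spec = SyntheticNeuronSpec(neuron_id=0, anchor_gp=0, anchor_loc=9,
                                   lag_deg=0.0, kappa_task=200.0,
                                   kappa_gp=0.0, baseline_rate=0.0)
        spikes = simulate_spikes(behaviour, [spec], seed=3)
        visits = anchor_visit_times(behaviour, 0, 9)
        angles = unwrapped_angle(spikes["time_s"].to_numpy(), behaviour.trials)
        visit_angles = unwrapped_angle(visits, behaviour.trials)
        dist = np.min(np.abs(angles[:, None] - visit_angles[None, :]), axis=1)
        assert np.quantile(dist, 0.95) < 30.0

    def test_lagged_neuron_peaks_one_state_after_anchor(self, maze, behaviour):
        """lag = 90 deg: peak firing one full state after each anchor visit
        (anchor at the state-B reward => task peak near 180 deg)."""
        spec = SyntheticNeuronSpec(neuron_id=0, anchor_gp=0, anchor_loc=9,
                                   lag_deg=90.0, kappa_task=20.0, kappa_gp=0.5)
        spikes = simulate_spikes(behaviour, [spec], seed=4)
        act = normalize_activity(spikes["time_s"].to_numpy(), behaviour.trials)
        peak = np.argmax(act.mean_curve())
        assert min(abs(peak - 180), 360 - abs(peak - 180)) <= 25

    def test_rate_recovery_matches_intensity(self, maze):
        """Binned empirical rate reproduces the intended intensity profile
        within Poisson error at high trial count."""
        task = TaskConfig((1, 9, 5, 7))
        beh = simulate_behaviour(maze, task, AgentPolicy(epsilon=1.0), 60,
                                 seed=5)
        spec = SyntheticNeuronSpec(neuron_id=0, anchor_gp=0, anchor_loc=1,
                                   lag_deg=180.0, kappa_task=10.0,
                                   kappa_gp=0.5, peak_rate=25.0,
                                   baseline_rate=0.5)
        spikes = simulate_spikes(beh, [spec], seed=6)
        act = normalize_activity(spikes["time_s"].to_numpy(), beh.trials)
        curve = act.mean_curve()
        # anchor = reward a (trial start), so the bump sits near 180 deg
        peak = int(np.argmax(curve))
        assert min(abs(peak - 180), 360 - abs(peak - 180)) <= 20
        assert curve.max() > 10.0
        trough = np.roll(curve, 180 - peak)[:60].mean()
        assert trough < 3.0

    def test_never_visited_anchor_warns_baseline_only(self, maze, behaviour):
        unvisited = [(g, loc) for g in range(3) for loc in maze.nodes
                     if len(anchor_visit_times(behaviour, g, loc)) == 0]
        assert unvisited, "stereotyped agent should leave some steps unvisited"
        g, loc = unvisited[0]
        spec = SyntheticNeuronSpec(neuron_id=0, anchor_gp=g, anchor_loc=loc,
                                   lag_deg=0.0, baseline_rate=5.0)
        with pytest.warns(UserWarning, match="never"):
            spikes = simulate_spikes(behaviour, [spec], seed=7)
        assert len(spikes) > 0  # baseline spikes remain

    def test_interval_gain_scales_bump(self, maze, behaviour):
        spec = SyntheticNeuronSpec(neuron_id=0, anchor_gp=0, anchor_loc=9,
                                   lag_deg=90.0, baseline_rate=0.0)
        t0 = behaviour.trials.state_edges()[0]
        t1 = behaviour.trials.state_edges()[-1]
        lo = simulate_spikes(behaviour, [spec], seed=8,
                             interval_gain={0: (np.array([t0]), np.array([0.2]))})
        hi = simulate_spikes(behaviour, [spec], seed=8,
                             interval_gain={0: (np.array([t0]), np.array([2.0]))})
        assert len(hi) > 3 * len(lo)


class TestOfflineGenerator:
    def _coactivity(self, lags, topology, seed):
        from smbuffers.offline import pair_metadata, sleep_crosscorr
        spec = OfflineGeneratorSpec(
            topology=topology,
            modules=[OfflineModule(list(range(len(lags))), list(lags))])
        spk = simulate_offline(spec, duration_s=240, seed=seed)
        meta = pair_metadata({i: l for i, l in enumerate(lags)})
        return meta.merge(sleep_crosscorr(spk), on=["neuron_i", "neuron_j"])

    def test_identical_lags_most_coactive(self):
        pairs = self._coactivity([40.0, 41.0, 200.0], "ring", seed=9)
        best = pairs.sort_values("corr").iloc[-1]
        assert {best["neuron_i"], best["neuron_j"]} == {0, 1}

    def test_ring_wraps_circular_proximity(self):
        """Lags 10 vs 350 (circularly close) are more coactive than 10 vs 180
        on a ring."""
        pairs = self._coactivity([10.0, 350.0, 180.0], "ring", seed=10)
        c = {frozenset((r.neuron_i, r.neuron_j)): r.corr
             for r in pairs.itertuples()}
        assert c[frozenset((0, 1))] > c[frozenset((0, 2))]

    def test_module_size_validated(self):
        with pytest.raises(ValueError):
            OfflineGeneratorSpec(topology="ring",
                                 modules=[OfflineModule([0], [0.0])])
        with pytest.raises(ValueError):
            OfflineGeneratorSpec(topology="moebius", modules=[])
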