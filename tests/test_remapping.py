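import numpy as np
import pytest

from smbuffers.remapping import (best_rotation, cluster_day,
                                 coherence_analysis, coherence_clustering,
                                 generalization_histogram, peak_to_peak_angle,
                                 rotation_angles_batch, state_tuning)
from smbuffers.synthetic import (AgentPolicy, SyntheticNeuronSpec,
                                 simulate_behaviour, simulate_rate_spikes,
                                 simulate_spikes)
from smbuffers.task_space import normalize_activity
from smbuffers.maze import TaskConfig


def bump_curve(center_deg, kappa=2.5, n_bins=360, noise=0.0, rng=None):
    th = np.arange(n_bins) * 360.0 / n_bins - center_deg
    c = np.exp(kappa * (np.cos(np.radians(th)) - 1.0))
    if noise and rng is not None:
        c = c + noise * rng.random(n_bins)
    return c


class TestStateTuning:
    def test_state_b_neuron(self, maze):
        beh = simulate_behaviour(maze, TaskConfig((1, 9, 5, 7)),
                                 AgentPolicy(epsilon=1.0), 15, seed=1)
        fn = lambda ang, gp, node: 0.3 + 10.0 * ((np.mod(ang, 360) >= 90)
                                                 & (np.mod(ang, 360) < 180))
        spk = simulate_rate_spikes(beh, fn, seed=2)
        act = normalize_activity(spk["time_s"].to_numpy(), beh.trials)
        res = state_tuning(act)
        assert res.preferred_state == 1
        assert res.p_value < 1e-4 and res.tuned_05 and res.tuned_01

    def test_structureless_null_rate(self, maze):
        """Around 5% of flat Poisson neurons come out state tuned."""
        beh = simulate_behaviour(maze, TaskConfig((1, 9, 5, 7)),
                                 AgentPolicy(epsilon=1.0), 20, seed=3)
        flags = []
        for i in range(120):
            spk = simulate_rate_spikes(
                beh, lambda ang, gp, node: 4.0 + 0 * ang, seed=100 + i)
            act = normalize_activity(spk["time_s"].to_numpy(), beh.trials)
            flags.append(state_tuning(act).tuned_05)
        rate = np.mean(flags)
        assert rate < 0.12  # 5% plus binomial slack at n=120

    def test_too_few_trials_rejected(self, maze):
        beh = simulate_behaviour(maze, TaskConfig((1, 9, 5, 7)),
                                 AgentPolicy(epsilon=1.0), 3, seed=4)
        spk = simulate_rate_spikes(beh, lambda a, g, n: 5.0 + 0 * a, seed=5)
        act = normalize_activity(spk["time_s"].to_numpy(), beh.trials)
        with pytest.raises(ValueError):
            state_tuning(act)


class TestBestRotation:
    def test_identity_and_roll(self, rng):
        curve = bump_curve(140.0)
        assert best_rotation(curve, curve).angle_deg == 0.0
        rolled = np.roll(curve, -90)
        assert best_rotation(curve, rolled).angle_deg == 90.0

    def test_matches_brute_force_oracle(self, rng):
        """Grid-search equals explicit roll-and-correlate on random curves."""
        for _ in range(300):
            ref, oth = rng.random(360), rng.random(360)
            res = best_rotation(ref, oth)
            brute = [(np.corrcoef(ref, np.roll(oth, r))[0, 1], r)
                     for r in range(0, 360, 10)]
            best_corr = max(b[0] for b in brute)
            assert res.correlation == pytest.approx(best_corr)

    def test_zero_variance_undefined(self):
        res = best_rotation(np.ones(360), np.arange(360.0))
        assert np.isnan(res.angle_deg)

    def test_peak_to_peak(self):
        c = bump_curve(40.0)
        assert peak_to_peak_angle(c, np.roll(c, 90)) == pytest.approx(90.0)


class TestGeneralization:
    def test_non_remapping_population(self, rng):
        curves = np.stack([
            np.stack([bump_curve(a, noise=0.2, rng=rng)] * 3)
            for a in rng.uniform(0, 360, 40)])
        g = generalization_histogram(curves)
        assert g.proportion > 0.95

    def test_same_data_zero_angles(self, rng):
        c = bump_curve(77.0, noise=0.1, rng=rng)
        curves = np.stack([np.stack([c, c.copy()])])
        g = generalization_histogram(curves)
        assert np.allclose(g.angles, 0.0)

    def test_quantized_remapping_matches_analytic_chance(self, rng):
        """Random whole-state remapping over two comparisons converges to
        1/16 (3 s.e. at n = 4000)."""
        n = 4000
        base = rng.uniform(0, 360, n)
        curves = np.empty((n, 3, 360))
        for k in range(3):
            rot = np.where(k == 0, 0.0, rng.integers(0, 4, n) * 90.0)
            for i in range(n):
                curves[i, k] = bump_curve(base[i] + rot[i], noise=0.3, rng=rng)
        g = generalization_histogram(curves)
        se = np.sqrt(g.chance * (1 - g.chance) / n)
        assert g.chance == pytest.approx(1 / 16)
        assert abs(g.proportion - g.chance) < 3 * se


class TestCoherence:
    def _module_curves(self, rng, n_modules=3, per_module=6, noise=0.25):
        """Modular population: within a module all neurons co-rotate."""
        curves, module = [], []
        for m in range(n_modules):
            rots = rng.integers(0, 4, 2) * 90.0
            for _ in range(per_module):
                base = rng.uniform(0, 360)
                curves.append(np.stack(
                    [bump_curve(base, noise=noise, rng=rng),
                     bump_curve(base + rots[0], noise=noise, rng=rng),
                     bump_curve(base + rots[1], noise=noise, rng=rng)]))
                module.append(m)
        return np.stack(curves), np.array(module)

    def test_corotating_pairs_coherent(self, rng):
        curves, module = self._module_curves(rng, n_modules=1)
        summ = coherence_analysis(curves)
        assert summ.proportion > 0.9

    def test_modular_population(self, rng):
        curves, module = self._module_curves(rng)
        summ = coherence_analysis(curves)
        same = module[summ.pair_index[:, 0]] == module[summ.pair_index[:, 1]]
        within = summ.coherent[same].mean()
        between = summ.coherent[~same].mean()
        assert within > 0.8
        assert between < within - 0.3

    def test_independent_remapping_near_chance(self, rng):
        n = 60
        curves = np.empty((n, 3, 360))
        for i in range(n):
            base = rng.uniform(0, 360)
            rots = rng.integers(0, 4, 2) * 90.0
            curves[i] = np.stack([bump_curve(base, noise=0.25, rng=rng),
                                  bump_curve(base + rots[0], noise=0.25, rng=rng),
                                  bump_curve(base + rots[1], noise=0.25, rng=rng)])
        summ = coherence_analysis(curves)
        assert summ.proportion < 0.25  # chance is 1/16; allow noise headroom


class TestClustering:
    def test_modular_day_beats_permuted(self, rng):
        curves, _ = TestCoherence()._module_curves(rng, n_modules=4,
                                                   per_module=5)
        real, null = coherence_clustering(curves, seed=0,
                                          distance_threshold=60.0)
        assert real.n_clusters >= 2
        assert real.silhouette > null.silhouette

    def test_identical_neurons_single_cluster_sentinel(self, rng):
        c = bump_curve(120.0)
        curves = np.stack([np.stack([c, c, c])] * 12)
        q = cluster_day(curves + 1e-9 * rng.random(curves.shape), seed=1,
                        distance_threshold=60.0)
        if q.n_clusters < 2:
            assert np.isnan(q.silhouette)

    def test_too_few_neurons_rejected(self, rng):
        curves = rng.random((5, 3, 360))
        with pytest.raises(ValueError):
            cluster_day(curves)


class TestConcordanceFilter:
    def test_filter_never_raises_generalizing_proportion(self):
        """On a coherent (non-remapping) population, restricting to neurons
        with concordant best-rotation and peak-to-peak angles does not
        increase the generalizing proportion."""
        from smbuffers.remapping import concordant_remapping
        rng = np.random.default_rng(42)
        curves = np.stack([
            np.stack([bump_curve(a, noise=0.4, rng=rng) for _ in range(3)])
            for a in rng.uniform(0, 360, 80)])
        full = generalization_histogram(curves)
        keep = concordant_remapping(curves)
        assert keep.sum() >= 10
        sub = generalization_histogram(curves[keep])
        assert sub.proportion <= full.proportion + 1e-12
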