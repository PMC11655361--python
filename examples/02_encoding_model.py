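"""Classify simulated neurons as goal-progress- or place-tuned.

Builds three tasks, simulates a pure place cell and a pure goal-progress
cell, and runs the cross-validated encoding model with its circular-shift
permutation null.
"""
import numpy as np

from smbuffers import AgentPolicy, MazeGraph, generate_task_set, \
    simulate_behaviour
from smbuffers.glm import GlmTaskData, fit_and_test
from smbuffers.synthetic import simulate_rate_spikes
from smbuffers.task_space import bin_session, normalize_activity

maze = MazeGraph.grid()
tasks = generate_task_set(maze, 3, seed=5)
behs = [simulate_behaviour(maze, t, AgentPolicy(epsilon=0.9), 15, seed=10 + i)
        for i, t in enumerate(tasks)]
bss = [bin_session(b.trials, b.positions, maze) for b in behs]

neurons = {
    "place cell (node 6)": lambda a, g, n: 0.5 + 12.0 * (n == 6),
    "goal-progress cell (late)": lambda a, g, n: 0.5 + 12.0 * np.exp(
        3 * (np.cos(np.radians(g - 300)) - 1)),
}
for name, fn in neurons.items():
    data = []
    for i, (beh, bs) in enumerate(zip(behs, bss)):
        spk = simulate_rate_spikes(beh, fn, seed=100 + i)
        st = spk["time_s"].to_numpy()
        data.append(GlmTaskData(normalize_activity(st, beh.trials,
                                                   task_id=str(i)),
                                bs, st, beh.trials))
    res = fit_and_test(data, n_perm=100, seed=0)
    print(f"{name}:")
    for var, v in res.items():
        print(f"  {var:14s} beta={v.mean_beta:+.3f} "
              f"(permutation 95th pct {v.perm_threshold:+.3f}), "
              f"cross-task map p={v.xcorr_p:.4f} -> tuned={v.tuned}")
print("A neuron is tuned when its coefficient beats the shifted-spike null "
      "AND its per-level rate maps correlate across tasks.")
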