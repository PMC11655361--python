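"""Score a simulated session of the four-goal loop task.

Simulates a near-optimal agent on one task, then prints the fraction of
shortest-path transitions, per-trial relative path distance, the route
entropy of one transition and the analytic chance of a direct return home.
"""
import numpy as np

from smbuffers import (AgentPolicy, ChanceModel, MazeGraph, TaskConfig,
                       chance_probability, path_entropy, score_transitions,
                       simulate_behaviour)

maze = MazeGraph.grid()
task = TaskConfig((1, 9, 5, 7))
beh = simulate_behaviour(maze, task, AgentPolicy(epsilon=0.9), n_trials=30,
                         seed=0)
recs = score_transitions(beh.trials, beh.positions, maze)

print(f"trials: {beh.trials.n_trials}")
print(f"shortest-path transitions: {100 * recs['is_shortest'].mean():.1f}%"
      "  (100% would be a perfectly optimal agent)")
print(f"mean relative path distance: "
      f"{recs['relative_path_distance'].mean():.2f}"
      "  (taken steps / shortest steps; 1.0 = optimal)")

h = path_entropy(recs, (1, 9), maze)
print(f"route entropy 1->9: {h:.2f}"
      "  (1 = no route bias across the six shortest routes, 0 = stereotyped)")

chance = ChanceModel.analytic(maze)
p = chance_probability(chance, task.rewards[3], task.rewards[0], maze=maze)
print(f"analytic chance of a direct d->a return: {p:.3f}"
      "  (a diffusing walker's first-passage probability)")
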