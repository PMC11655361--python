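"""Trial structure and behavioural scoring on the grid maze.

A *trial* runs from one reward at location a to the next reward at a; each
trial is tiled by one interval per *state* (A = a->b, B = b->c, ...). All
scoring operates on a TrialTable (state intervals) plus a positions log of
timestamped node entries.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .maze import MazeGraph, TaskConfig, ChanceModel, shortest_paths, STATE_LABELS


@dataclass
class TrialTable:
    """State intervals of a session.

    ``table`` columns: trial (int, 0-based), state (str A..E), state_idx,
    t_start, t_end, src_loc (reward just obtained), dst_loc (current goal).
    Intervals tile [first reward a, last reward a] without overlap.
    """

    table: pd.DataFrame
    task: TaskConfig

    @property
    def n_trials(self) -> int:
        return int(self.table["trial"].max()) + 1 if len(self.table) else 0

    def trial_bounds(self) -> np.ndarray:
        """(n_trials + 1,) trial-start times (reward-a events)."""
        starts = self.table[self.table["state_idx"] == 0]["t_start"].to_numpy()
        last_end = self.table["t_end"].iloc[-1]
        return np.append(starts, last_end)

    def state_edges(self) -> np.ndarray:
        """All state-boundary times (reward events), length n_states + 1."""
        return np.append(self.table["t_start"].to_numpy(),
                         self.table["t_end"].iloc[-1])


def trial_table_from_events(events: pd.DataFrame, task: TaskConfig) -> TrialTable:
    """Build the TrialTable from a behaviour event log.

    Only complete trials (reward a -> next reward a) are retained. Reward
    events must appear in task order; the event log's ``state`` column is not
    required (states are derived from reward locations).
    """
    rew = events[events["event"] == "reward"].sort_values("time_s")
    if len(rew) == 0:
        raise ValueError("no reward events in log")
    locs = rew["location"].astype(int).to_numpy()
    times = rew["time_s"].to_numpy()
    a = task.rewards[0]
    first_a = np.flatnonzero(locs == a)
    if len(first_a) < 2:
        raise ValueError("need at least one complete trial (two rewards at a)")
    start = first_a[0]
    p = task.periodicity
    rows = []
    i = start
    trial = 0
    while i + p < len(locs):
        block = locs[i:i + p + 1]
        expected = np.array(list(task.rewards) + [a])
        if not np.array_equal(block, expected):
            raise ValueError(
                f"reward sequence violates task order at reward index {i}")
        for s in range(p):
            rows.append(dict(trial=trial, state=STATE_LABELS[s], state_idx=s,
                             t_start=times[i + s], t_end=times[i + s + 1],
                             src_loc=int(task.rewards[s]),
                             dst_loc=int(task.goal_after(s))))
        i += p
        trial += 1
    if not rows:
        raise ValueError("zero complete trials")
    return TrialTable(table=pd.DataFrame(rows), task=task)


def _nodes_in_interval(positions: pd.DataFrame, t0: float, t1: float,
                       entry_node: int) -> list[int]:
    """Node sequence occupied during [t0, t1], starting from entry_node."""
    t = positions["time_s"].to_numpy()
    loc = positions["location"].to_numpy()
    mask = (t > t0) & (t <= t1)
    seq = [int(entry_node)] + [int(x) for x in loc[mask]]
    # collapse repeats (re-registrations of the same node)
    out = [seq[0]]
    for n in seq[1:]:
        if n != out[-1]:
            out.append(n)
    return out


def score_transitions(trials: TrialTable, positions: pd.DataFrame,
                      maze: MazeGraph) -> pd.DataFrame:
    """Per state interval: taken path, shortest length and relative path
    distance (taken steps / shortest steps, >= 1 when the log is clean).

    Intervals whose position log contains a non-adjacent jump (a gap) are
    flagged rather than dropped.
    """
    recs = []
    for row in trials.table.itertuples():
        path = _nodes_in_interval(positions, row.t_start, row.t_end, row.src_loc)
        if path[-1] != row.dst_loc:
            path = path + [row.dst_loc]
        flagged = any(maze.manhattan(a, b) != 1
                      for a, b in zip(path[:-1], path[1:]))
        n_steps = len(path) - 1
        shortest = maze.manhattan(row.src_loc, row.dst_loc)
        rpd = n_steps / shortest if shortest > 0 else np.nan
        recs.append(dict(trial=row.trial, state=row.state, src=row.src_loc,
                         dst=row.dst_loc, path=tuple(path), n_steps=n_steps,
                         shortest_length=shortest,
                         relative_path_distance=rpd,
                         is_shortest=bool(n_steps == shortest),
                         flagged=flagged))
    return pd.DataFrame(recs)


def path_entropy(records: pd.DataFrame, transition: tuple[int, int],
                 maze: MazeGraph) -> float | None:
    """Entropy of shortest-route choice for one transition, in [0, 1].

    Computed as ``-sum pk log_x pk`` with the logarithmic base x equal to the
    number of available shortest routes, over the shortest paths actually
    taken; 1 means no route bias, 0 means a single stereotyped route.
    Returns None (undefined) when only one shortest route exists.
    """
    src, dst = transition
    routes = shortest_paths(maze, src, dst)
    x = len(routes)
    if x < 2:
        return None
    sub = records[(records["src"] == src) & (records["dst"] == dst)
                  & records["is_shortest"]]
    if len(sub) == 0:
        return None
    counts = sub["path"].value_counts()
    pk = counts.to_numpy(dtype=float) / counts.sum()
    return float(-(pk * (np.log(pk) / np.log(x))).sum())


def _reached_directly(path: list[int], src: int, dst: int, maze: MazeGraph) -> bool:
    """Did the path reach dst from src in exactly the shortest step count?"""
    if dst not in path:
        return False
    k = path.index(dst)
    return k == maze.manhattan(src, dst)


def zero_shot_stats(first_trial_records: dict, maze: MazeGraph) -> pd.DataFrame:
    """Zero-shot inference statistics over tasks.

    ``first_trial_records`` maps task_id -> first-trial transition records
    (the score_transitions rows for trial 0). For each task we score whether
    the animal took a direct path d->a (the inference transition) and, as
    controls, whether it returned directly to a prematurely from b (during
    state B) or from c (during state C). A premature return requires a to be
    a detour: merely passing through a on a shortest route to the current
    goal does not count. Returns one row per task with boolean columns
    d_to_a, c_to_a, b_to_a.
    """
    rows = []
    for task_id, recs in first_trial_records.items():
        recs = recs[recs["trial"] == recs["trial"].min()]
        by_state = {r.state: r for r in recs.itertuples()}
        p = len(by_state)
        last = STATE_LABELS[p - 1]  # D or E: the return-home transition
        out = {"task_id": task_id}
        r = by_state[last]
        out["d_to_a"] = bool(r.is_shortest)
        a = r.dst
        for label, key in (("B", "b_to_a"), ("C", "c_to_a")):
            rb = by_state[label]
            on_route = (maze.manhattan(rb.src, a) + maze.manhattan(a, rb.dst)
                        == maze.manhattan(rb.src, rb.dst))
            out[key] = (not on_route
                        and _reached_directly(list(rb.path), rb.src, a, maze))
        rows.append(out)
    return pd.DataFrame(rows)


def bias_performance_correlation(records: pd.DataFrame,
                                 baseline: ChanceModel) -> float:
    """Pearson r between per-trial relative path distance and the mean
    baseline step probability of the steps actually taken.

    NaN when fewer than 3 trials or when either quantity is constant
    (e.g. an all-optimal session).
    """
    per_trial = []
    for trial, sub in records.groupby("trial"):
        steps = []
        for path in sub["path"]:
            steps += [baseline.step_probability(a, b)
                      for a, b in zip(path[:-1], path[1:])]
        rpd = sub["n_steps"].sum() / sub["shortest_length"].sum()
        per_trial.append((rpd, float(np.mean(steps))))
    arr = np.asarray(per_trial)
    if len(arr) < 3 or arr[:, 0].std() == 0 or arr[:, 1].std() == 0:
        return float("nan")
    return float(stats.pearsonr(arr[:, 0], arr[:, 1])[0])
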