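"""The 3x3 grid maze, task configurations and diffusion chance models.

Nodes are labelled 1-9 row-major::

    1 2 3
    4 5 6
    7 8 9

so node 1 is adjacent to exactly {2, 4} and the centre node 5 has degree 4.
Edges run along cardinal directions only. A task is an ordered loop of 4
(ABCD) or 5 (ABCDE) distinct rewarded nodes; after the last reward the first
becomes available again.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

STATE_LABELS = "ABCDE"


def _node_coords(node: int) -> tuple[int, int]:
    return (node - 1) // 3, (node - 1) % 3


@dataclass(frozen=True)
class MazeGraph:
    """3x3 grid maze with cardinal-direction edges."""

    graph: nx.Graph = field(repr=False)

    @classmethod
    def grid(cls) -> "MazeGraph":
        g = nx.Graph()
        g.add_nodes_from(range(1, 10))
        for n in range(1, 10):
            r, c = _node_coords(n)
            if c < 2:
                g.add_edge(n, n + 1)
            if r < 2:
                g.add_edge(n, n + 3)
        return cls(graph=g)

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def neighbors(self, node: int) -> list[int]:
        self._check(node)
        return sorted(self.graph.neighbors(node))

    def manhattan(self, a: int, b: int) -> int:
        self._check(a)
        self._check(b)
        (ra, ca), (rb, cb) = _node_coords(a), _node_coords(b)
        return abs(ra - rb) + abs(ca - cb)

    def _check(self, node) -> None:
        if node not in self.graph:
            raise ValueError(f"unknown node label: {node!r}")


def shortest_paths(maze: MazeGraph, src: int, dst: int) -> list[tuple[int, ...]]:
    """All minimal-length node sequences from src to dst.

    On the grid the shortest length equals the Manhattan distance. The
    identity path ``(src,)`` is returned for ``src == dst``.
    """
    maze._check(src)
    maze._check(dst)
    return sorted(tuple(p) for p in nx.all_shortest_paths(maze.graph, src, dst))


@dataclass(frozen=True)
class TaskConfig:
    """An ordered loop of rewarded nodes (e.g. 1-9-5-7)."""

    rewards: tuple[int, ...]

    def __post_init__(self):
        if len(self.rewards) not in (4, 5):
            raise ValueError("a task has 4 (ABCD) or 5 (ABCDE) rewards")
        if len(set(self.rewards)) != len(self.rewards):
            raise ValueError("reward locations must be distinct")

    @property
    def structure(self) -> str:
        return "ABCD" if len(self.rewards) == 4 else "ABCDE"

    @property
    def periodicity(self) -> int:
        return len(self.rewards)

    @property
    def state_span_deg(self) -> float:
        return 360.0 / self.periodicity

    def goal_after(self, state_idx: int) -> int:
        """Reward node that terminates state ``state_idx`` (the current goal)."""
        return self.rewards[(state_idx + 1) % self.periodicity]

    def transitions(self) -> list[tuple[int, int]]:
        """Ordered (src, dst) reward pairs, including the wrap d->a."""
        p = self.periodicity
        return [(self.rewards[i], self.rewards[(i + 1) % p]) for i in range(p)]

    def to_json(self) -> str:
        return json.dumps({"structure": self.structure, "rewards": list(self.rewards)})

    @classmethod
    def from_json(cls, text: str) -> "TaskConfig":
        d = json.loads(text)
        cfg = cls(rewards=tuple(d["rewards"]))
        if d.get("structure") and d["structure"] != cfg.structure:
            raise ValueError("structure field inconsistent with reward count")
        return cfg


@dataclass
class ChanceModel:
    """Row-stochastic node-to-node transition model for chance levels.

    ``analytic`` mode assigns equal probability to all graph neighbours
    (a randomly diffusing animal); ``empirical`` mode uses the observed
    transition matrix from a pre-task exploration session.
    """

    mode: str
    transition_matrix: np.ndarray  # (9, 9), rows = from-node (1..9 -> 0..8)

    def __post_init__(self):
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (9, 9):
            raise ValueError("transition matrix must be 9x9")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")
        self.transition_matrix = tm

    @classmethod
    def analytic(cls, maze: MazeGraph) -> "ChanceModel":
        tm = np.zeros((9, 9))
        for n in maze.nodes:
            nbrs = maze.neighbors(n)
            for m in nbrs:
                tm[n - 1, m - 1] = 1.0 / len(nbrs)
        return cls(mode="analytic", transition_matrix=tm)

    @classmethod
    def empirical(cls, node_sequence, maze: MazeGraph,
                  smoothing: float = 1e-9) -> "ChanceModel":
        """Transition matrix from an observed node sequence (exploration)."""
        seq = [int(n) for n in node_sequence]
        counts = np.zeros((9, 9))
        for a, b in zip(seq[:-1], seq[1:]):
            counts[a - 1, b - 1] += 1
        # only allow steps along maze edges; smooth so rows are stochastic
        adj = nx.to_numpy_array(maze.graph, nodelist=maze.nodes)
        counts = counts * adj + smoothing * adj
        tm = counts / counts.sum(axis=1, keepdims=True)
        return cls(mode="empirical", transition_matrix=tm)

    def step_probability(self, src: int, dst: int) -> float:
        return float(self.transition_matrix[src - 1, dst - 1])

    def path_probability(self, path) -> float:
        """Product of step probabilities along a node path."""
        p = 1.0
        for a, b in zip(path[:-1], path[1:]):
            p *= self.step_probability(a, b)
        return p


def chance_probability(chance: ChanceModel, src: int, dst: int,
                       n_steps: int | None = None, maze: MazeGraph | None = None,
                       mode: str = "exact") -> float:
    """Probability a random walker starting at src first reaches dst in the
    shortest possible number of steps.

    ``mode="exact"`` (default): first passage at exactly ``n_steps`` (the
    Manhattan distance unless given). ``mode="within"``: first passage at or
    before ``n_steps``.
    """
    maze = maze or MazeGraph.grid()
    if n_steps is None:
        n_steps = maze.manhattan(src, dst)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    tm = chance.transition_matrix.copy()
    # make dst absorbing
    tm[dst - 1, :] = 0.0
    tm[dst - 1, dst - 1] = 1.0
    state = np.zeros(9)
    state[src - 1] = 1.0
    absorbed_prev = 1.0 if src == dst else 0.0
    within = 0.0
    exact = 0.0
    for _ in range(n_steps):
        state = state @ tm
        absorbed = state[dst - 1]
        exact = absorbed - absorbed_prev
        absorbed_prev = absorbed
        within = absorbed
    if src == dst:
        within -= 1.0  # the walker started absorbed; exclude trivial mass
    return float(exact if mode == "exact" else within)


# ---------------------------------------------------------------------------
# task-set generation with the training constraints
# ---------------------------------------------------------------------------

_RING_ORDER = (1, 2, 3, 6, 9, 8, 7, 4)  # outer ring, clockwise


def _rotate_node(node: int, quarter_turns: int) -> int:
    r, c = _node_coords(node)
    for _ in range(quarter_turns % 4):
        r, c = c, 2 - r
    return r * 3 + c + 1


def _is_rotation_of(a: TaskConfig, b: TaskConfig) -> bool:
    """True if b equals a under some maze rotation plus cyclic shift."""
    if a.periodicity != b.periodicity:
        return False
    p = a.periodicity
    for q in range(4):
        rot = tuple(_rotate_node(n, q) for n in a.rewards)
        for s in range(p):
            if tuple(rot[(i + s) % p] for i in range(p)) == b.rewards:
                return True
    return False


def _solvable_by_circling(task: TaskConfig) -> bool:
    """True when all rewards lie on the outer ring in ring order (either
    direction), so that steady circling visits them in sequence."""
    if any(n == 5 for n in task.rewards):
        return False
    pos = {n: i for i, n in enumerate(_RING_ORDER)}
    idx = [pos[n] for n in task.rewards]
    for direction in (1, -1):
        gaps = [(direction * (idx[(k + 1) % len(idx)] - idx[k])) % 8
                for k in range(len(idx))]
        if sum(gaps) == 8:
            return True
    return False


def _task_space_correlation(task: TaskConfig, maze: MazeGraph) -> float:
    """Correlation between task distance and spatial distance over all
    ordered reward pairs."""
    p = task.periodicity
    td, sd = [], []
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            td.append((j - i) % p)
            sd.append(maze.manhattan(task.rewards[i], task.rewards[j]))
    td, sd = np.asarray(td, float), np.asarray(sd, float)
    if td.std() == 0 or sd.std() == 0:
        return 0.0
    return float(np.corrcoef(td, sd)[0, 1])


def _chance_spread(task: TaskConfig, chance: ChanceModel, maze: MazeGraph) -> float:
    """Max-min spread of analytic chance over task and control transitions."""
    a = task.rewards[0]
    pairs = task.transitions() + [(task.rewards[1], a), (task.rewards[2], a)]
    probs = [chance_probability(chance, s, d, maze=maze) for s, d in pairs]
    return float(max(probs) - min(probs))


@dataclass
class TaskSetConstraints:
    """Checkable constraints on a pseudo-random task set."""

    max_task_space_corr: float = 0.6
    no_shared_transition: bool = True
    no_circling: bool = True
    no_spatial_rotation: bool = True
    max_chance_spread: float = 0.15


def check_task_constraints(tasks: list[TaskConfig], constraints: TaskSetConstraints,
                           maze: MazeGraph | None = None) -> bool:
    """Independent brute-force check that a task list satisfies all criteria."""
    maze = maze or MazeGraph.grid()
    chance = ChanceModel.analytic(maze)
    for i, t in enumerate(tasks):
        if abs(_task_space_correlation(t, maze)) > constraints.max_task_space_corr:
            return False
        if constraints.no_circling and _solvable_by_circling(t):
            return False
        if _chance_spread(t, chance, maze) > constraints.max_chance_spread:
            return False
        if constraints.no_shared_transition and i > 0:
            if set(t.transitions()) & set(tasks[i - 1].transitions()):
                return False
        if constraints.no_spatial_rotation:
            for prev in tasks[:i]:
                if _is_rotation_of(prev, t):
                    return False
    return True


def generate_task_set(maze: MazeGraph, n_tasks: int, seed: int,
                      structure: str = "ABCD",
                      constraints: TaskSetConstraints | None = None,
                      max_attempts: int = 100_000) -> list[TaskConfig]:
    """Rejection-sample ``n_tasks`` task configurations satisfying the
    training constraints; deterministic under ``seed``.

    Raises RuntimeError if the constraint set proves infeasible within
    ``max_attempts`` candidate draws.
    """
    constraints = constraints or TaskSetConstraints()
    p = 4 if structure == "ABCD" else 5
    rng = np.random.default_rng(seed)
    chance = ChanceModel.analytic(maze)
    tasks: list[TaskConfig] = []
    attempts = 0
    while len(tasks) < n_tasks:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"task-set constraints infeasible: {len(tasks)}/{n_tasks} tasks "
                f"after {max_attempts} attempts")
        attempts += 1
        cand = TaskConfig(tuple(int(n) for n in
                                rng.choice(maze.nodes, size=p, replace=False)))
        if abs(_task_space_correlation(cand, maze)) > constraints.max_task_space_corr:
            continue
        if constraints.no_circling and _solvable_by_circling(cand):
            continue
        if _chance_spread(cand, chance, maze) > constraints.max_chance_spread:
            continue
        if constraints.no_shared_transition and tasks:
            if set(cand.transitions()) & set(tasks[-1].transitions()):
                continue
        if constraints.no_spatial_rotation and any(
                _is_rotation_of(t, cand) for t in tasks):
            continue
        tasks.append(cand)
    return tasks
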