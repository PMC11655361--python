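import warnings

import numpy as np
import pytest

from smbuffers.maze import MazeGraph, TaskConfig, generate_task_set
from smbuffers.synthetic import AgentPolicy, simulate_behaviour
from smbuffers.task_space import bin_session

warnings.filterwarnings("ignore", message=".*Maximum Likelihood optimization.*")
warnings.filterwarnings("ignore", message=".*Perfect separation.*")
warnings.filterwarnings("ignore", message="Mean of empty slice")


@pytest.fixture(scope="session")
def maze():
    return MazeGraph.grid()


@pytest.fixture(scope="session")
def tasks3(maze):
    return generate_task_set(maze, 3, seed=5)


@pytest.fixture(scope="session")
def behaviours3(maze, tasks3):
    """Three simulated sessions from a near-optimal agent (shared by the
    encoding-model and task-space tests)."""
    return [simulate_behaviour(maze, t, AgentPolicy(epsilon=0.9), 12,
                               seed=40 + i)
            for i, t in enumerate(tasks3)]


@pytest.fixture(scope="session")
def binned3(maze, behaviours3):
    return [bin_session(b.trials, b.positions, maze) for b in behaviours3]


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent draws)."""
    return np.random.default_rng(0)
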