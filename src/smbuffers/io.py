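"""Readers/writers for the plain-text interchange formats and run
configuration.

All tables are tab-separated text. Times are seconds (float), angles degrees,
bin indices 0-based, states labelled A-E, nodes 1-9 (edges as "n-m").
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .maze import MazeGraph

EVENT_TYPES = {"poke", "reward", "tone", "position"}
EVENT_COLUMNS = ["session_id", "time_s", "event", "location", "trial_idx",
                 "state"]


@dataclass
class RunConfig:
    """Thresholds and seeds of an analysis run; serialized with every output
    so a run is reproducible from its config alone."""

    structure: str = "ABCD"
    bins_per_state: int = 90
    gp_bins: int = 3
    smoothing_sigma_deg: float = 10.0
    n_permutations: int = 100
    rotation_window_deg: float = 45.0
    nonzero_lag_deg: float = 30.0
    distal_lag_deg: float = 90.0
    robustness_fraction: float = 1.0 / 3.0
    alpha: float = 0.05
    alpha_strict: float = 0.01
    seeds: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "RunConfig":
        p = Path(text_or_path)
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls(**json.loads(text))


def _validate_location(loc, maze: MazeGraph, row: int) -> None:
    s = str(loc)
    if "-" in s:
        a, b = s.split("-")
        if not (a.strip().isdigit() and b.strip().isdigit()
                and int(a) in maze.nodes and int(b) in maze.nodes
                and maze.manhattan(int(a), int(b)) == 1):
            raise ValueError(f"row {row}: unknown edge code {loc!r}")
    else:
        try:
            node = int(float(s))
        except ValueError:
            raise ValueError(f"row {row}: unknown location code {loc!r}")
        if node not in maze.nodes:
            raise ValueError(f"row {row}: unknown location code {loc!r}")


def _check_monotone(times: pd.Series, what: str) -> None:
    t = times.to_numpy()
    bad = np.flatnonzero(np.diff(t) < 0)
    if len(bad):
        raise ValueError(f"{what}: non-monotone time at row {int(bad[0]) + 1}")


def read_events(path: str | Path, maze: MazeGraph | None = None) -> pd.DataFrame:
    """Behaviour event log: session_id, time_s, event, location, trial_idx,
    state; timestamps must be monotone and locations valid maze codes."""
    maze = maze or MazeGraph.grid()
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events file missing columns: {sorted(missing)}")
    df["state"] = df["state"].fillna("").astype(str)
    bad = ~df["event"].isin(EVENT_TYPES)
    if bad.any():
        raise ValueError(
            f"row {int(np.flatnonzero(bad)[0])}: unknown event type "
            f"{df.loc[bad, 'event'].iloc[0]!r}")
    for sid, sub in df.groupby("session_id"):
        _check_monotone(sub["time_s"], f"events session {sid}")
    for i, loc in enumerate(df["location"]):
        _validate_location(loc, maze, i)
    return df


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_spikes(path: str | Path) -> pd.DataFrame:
    """Spike table: neuron_id, time_s (monotone within neuron)."""
    df = pd.read_csv(path, sep="\t")
    if not {"neuron_id", "time_s"} <= set(df.columns):
        raise ValueError("spike file needs columns neuron_id, time_s")
    for nid, sub in df.groupby("neuron_id"):
        _check_monotone(sub["time_s"], f"spikes neuron {nid}")
    return df


def write_spikes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_positions(path: str | Path,
                   maze: MazeGraph | None = None) -> pd.DataFrame:
    """Position log: time_s, location (node or edge code)."""
    maze = maze or MazeGraph.grid()
    df = pd.read_csv(path, sep="\t")
    if not {"time_s", "location"} <= set(df.columns):
        raise ValueError("positions file needs columns time_s, location")
    _check_monotone(df["time_s"], "positions")
    for i, loc in enumerate(df["location"]):
        _validate_location(loc, maze, i)
    return df


def write_positions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_neuron_specs(specs, path: str | Path) -> None:
    """Ground-truth generator parameters, serialized beside every simulated
    dataset."""
    Path(path).write_text(json.dumps([s.to_dict() for s in specs], indent=2)
                          + "\n")


def read_neuron_specs(path: str | Path):
    from .synthetic import SyntheticNeuronSpec
    return [SyntheticNeuronSpec(**d) for d in json.loads(Path(path).read_text())]
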