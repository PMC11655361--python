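"""Synthetic behaviour, task-aligned spike trains and offline activity.

The generator produces the three ingredients every downstream analysis needs,
with known ground truth:

* behaviour of an agent on the grid maze with configurable policy optimality
  and pre-task step biases (``simulate_behaviour``),
* spike trains of neurons defined by a behavioural-step anchor (goal-progress
  bin x location), a task-space lag and Poisson noise (``simulate_spikes``),
* offline (sleep) activity whose pairwise coactivity is organised on a ring
  or, as a control, a delay line (``simulate_offline``).

Task angle during simulation is computed from the agent's own reward timeline
(goal progress = elapsed fraction of the inter-reward interval), mirroring the
analysis-side convention so generator and analyser agree by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maze import MazeGraph, TaskConfig
from .behaviour import TrialTable, trial_table_from_events


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

@dataclass
class AgentPolicy:
    """Step policy of the simulated animal.

    With probability ``epsilon`` the agent takes a step along a shortest path
    to the current goal (ties between equally short next steps are broken
    uniformly, or stickily with probability ``path_stickiness`` by repeating
    the choice made at the same decision point on the previous trial). With
    probability 1 - epsilon it samples a step from ``bias_matrix`` (uniform
    over neighbours when None). Dwell time per node is lognormal with mean
    ``dwell_mean_s`` and coefficient of variation ``dwell_cv``.
    """

    epsilon: float = 1.0
    bias_matrix: np.ndarray | None = None
    dwell_mean_s: float = 1.0
    dwell_cv: float = 0.8
    reward_dwell_s: float = 2.5
    path_stickiness: float = 0.0


@dataclass
class SimulatedBehaviour:
    events: pd.DataFrame
    positions: pd.DataFrame
    trials: TrialTable
    task: TaskConfig


def _sample_dwell(rng, mean, cv):
    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    mu = np.log(mean) - sigma ** 2 / 2
    return float(rng.lognormal(mu, sigma))


def simulate_behaviour(maze: MazeGraph, task: TaskConfig, policy: AgentPolicy,
                       n_trials: int, seed: int,
                       session_id: str = "sim") -> SimulatedBehaviour:
    """Simulate one session of ``n_trials`` complete trials.

    The event stream obeys task logic: rewards are delivered only in sequence
    and a tone accompanies every reward at location a. Deterministic under
    ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    bias = policy.bias_matrix
    if bias is None:
        bias = np.zeros((9, 9))
        for n in maze.nodes:
            for m in maze.neighbors(n):
                bias[n - 1, m - 1] = 1.0 / len(maze.neighbors(n))

    node = int(rng.choice([n for n in maze.nodes if n != task.rewards[0]]))
    t = 0.0
    goal_idx = 0  # index into rewards; current goal = rewards[goal_idx]
    rewards_at_a = 0
    sticky_choice: dict[tuple[int, int], int] = {}  # (goal, node) -> next node

    ev_rows = [dict(session_id=session_id, time_s=t, event="position",
                    location=node, trial_idx=-1, state="")]
    pos_rows = [dict(time_s=t, location=node)]
    trial_idx = -1
    state = ""

    while rewards_at_a <= n_trials:
        goal = task.rewards[goal_idx]
        if node == goal:
            # poke -> reward
            ev_rows.append(dict(session_id=session_id, time_s=t, event="poke",
                                location=node, trial_idx=trial_idx, state=state))
            ev_rows.append(dict(session_id=session_id, time_s=t, event="reward",
                                location=node, trial_idx=trial_idx, state=state))
            if goal_idx == 0:
                rewards_at_a += 1
                trial_idx += 1
                ev_rows.append(dict(session_id=session_id, time_s=t,
                                    event="tone", location=node,
                                    trial_idx=trial_idx, state="A"))
            if rewards_at_a > n_trials:
                break
            state = "ABCDE"[goal_idx]
            goal_idx = (goal_idx + 1) % task.periodicity
            t += _sample_dwell(rng, policy.reward_dwell_s, policy.dwell_cv)
        else:
            t += _sample_dwell(rng, policy.dwell_mean_s, policy.dwell_cv)

        goal = task.rewards[goal_idx]
        nbrs = maze.neighbors(node)
        if rng.random() < policy.epsilon:
            reducing = [m for m in nbrs
                        if maze.manhattan(m, goal) < maze.manhattan(node, goal)]
            key = (goal, node)
            prev = sticky_choice.get(key)
            if (prev in reducing and policy.path_stickiness > 0
                    and rng.random() < policy.path_stickiness):
                nxt = prev
            else:
                nxt = int(rng.choice(reducing))
            sticky_choice[key] = nxt
        else:
            nxt = int(rng.choice(9, p=bias[node - 1]) + 1)
        node = nxt
        ev_rows.append(dict(session_id=session_id, time_s=t, event="position",
                            location=node, trial_idx=trial_idx, state=state))
        pos_rows.append(dict(time_s=t, location=node))

    events = pd.DataFrame(ev_rows)
    positions = pd.DataFrame(pos_rows)
    trials = trial_table_from_events(events, task)
    return SimulatedBehaviour(events=events, positions=positions,
                              trials=trials, task=task)


# ---------------------------------------------------------------------------
# task-angle timeline (shared by the spike generator and the analyses)
# ---------------------------------------------------------------------------

def unwrapped_angle(times: np.ndarray, trials: TrialTable) -> np.ndarray:
    """Unwrapped task angle (degrees, trial k spans [k*360, (k+1)*360)) at
    arbitrary times; NaN outside the trial-covered span."""
    edges = trials.state_edges()
    span = trials.task.state_span_deg
    idx = np.searchsorted(edges, times, side="right") - 1
    out = np.full(len(times), np.nan)
    ok = (idx >= 0) & (idx < len(edges) - 1)
    i = idx[ok]
    frac = (times[ok] - edges[i]) / (edges[i + 1] - edges[i])
    out[ok] = i * span + frac * span
    return out


def node_at_times(times: np.ndarray, positions: pd.DataFrame) -> np.ndarray:
    pt = positions["time_s"].to_numpy()
    pl = positions["location"].to_numpy()
    idx = np.clip(np.searchsorted(pt, times, side="right") - 1, 0, len(pt) - 1)
    return pl[idx].astype(int)


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticNeuronSpec:
    """Ground-truth generative parameters of one buffer neuron.

    The neuron's activity bump arrives ``lag_deg`` of task space after each
    visit to its anchor (a goal-progress bin x location conjunction). The
    bump is a von-Mises-like function of angle-since-anchor-visit with
    concentration ``kappa_task``; goal-progress modulation (concentration
    ``kappa_gp``) is centred on the goal-progress phase at which the bump
    arrives, so lagged cells retain goal-progress tuning.
    """

    neuron_id: int
    anchor_gp: int          # 0 = early, 1 = intermediate, 2 = late
    anchor_loc: int         # node 1-9
    lag_deg: float          # [0, 360)
    kappa_task: float = 15.0
    kappa_gp: float = 2.0
    peak_rate: float = 20.0
    baseline_rate: float = 0.2

    def __post_init__(self):
        if self.peak_rate < 0 or self.baseline_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.anchor_gp not in (0, 1, 2):
            raise ValueError("anchor_gp must be 0, 1 or 2")

    def preferred_gp_phase_deg(self, span_deg: float = 90.0) -> float:
        """Goal-progress phase (0-360 over one state) at the bump."""
        anchor_phase = (self.anchor_gp + 0.5) * span_deg / 3.0
        return ((anchor_phase + self.lag_deg) % span_deg) / span_deg * 360.0

    def preferred_gp_bin(self, span_deg: float = 90.0) -> int:
        return int(self.preferred_gp_phase_deg(span_deg) // 120.0)

    def to_dict(self) -> dict:
        return dict(neuron_id=self.neuron_id, anchor_gp=self.anchor_gp,
                    anchor_loc=self.anchor_loc, lag_deg=self.lag_deg,
                    kappa_task=self.kappa_task, kappa_gp=self.kappa_gp,
                    peak_rate=self.peak_rate, baseline_rate=self.baseline_rate)


def anchor_visit_times(behaviour: SimulatedBehaviour, anchor_gp: int,
                       anchor_loc: int, dt: float = 0.01) -> np.ndarray:
    """Times of visits to a behavioural step (node occupied during the
    goal-progress bin); consecutive occupancy collapses to one visit."""
    grid, ang, occupied = _occupancy_grid(behaviour, dt)
    hit = occupied == anchor_loc
    gp_bin = np.floor((np.mod(ang, behaviour.task.state_span_deg)
                       / behaviour.task.state_span_deg) * 3).astype(int)
    hit &= gp_bin == anchor_gp
    hit &= ~np.isnan(ang)
    starts = np.flatnonzero(hit & ~np.concatenate(([False], hit[:-1])))
    return grid[starts]


def _occupancy_grid(behaviour: SimulatedBehaviour, dt: float):
    edges = behaviour.trials.state_edges()
    grid = np.arange(edges[0], edges[-1], dt)
    ang = unwrapped_angle(grid, behaviour.trials)
    occupied = node_at_times(grid, behaviour.positions)
    return grid, ang, occupied


def simulate_spikes(behaviour: SimulatedBehaviour,
                    neurons: list[SyntheticNeuronSpec], seed: int,
                    dt: float = 0.01,
                    interval_gain: dict[int, np.ndarray] | None = None,
                    ) -> pd.DataFrame:
    """Inhomogeneous-Poisson spike trains for a set of buffer neurons.

    Intensity = baseline + peak * g_task(angle since last anchor visit;
    lag, kappa_task) * g_gp(goal-progress phase; kappa_gp). Optional
    ``interval_gain[neuron_id] = (times_s, gains)`` multiplies the
    task-locked component by a step function of time (each gain applies from
    its time until the next), which lets a caller couple bump amplitude to
    upcoming behaviour. Neurons whose anchor is never visited emit baseline
    spikes only.

    Returns a spike table with columns neuron_id, time_s.
    """
    rng = np.random.default_rng(seed)
    grid, ang, occupied = _occupancy_grid(behaviour, dt)
    span = behaviour.task.state_span_deg
    gp_phase = np.mod(ang, span) / span * 360.0  # 0-360 within a state
    gp_bin = np.floor(gp_phase / 120.0).astype(int)
    valid = ~np.isnan(ang)

    rows_id, rows_t = [], []
    for spec in neurons:
        hit = valid & (occupied == spec.anchor_loc) & (gp_bin == spec.anchor_gp)
        starts = np.flatnonzero(hit & ~np.concatenate(([False], hit[:-1])))
        lam = np.full(len(grid), spec.baseline_rate)
        if len(starts) == 0:
            import warnings
            warnings.warn(f"neuron {spec.neuron_id}: anchor "
                          f"(gp={spec.anchor_gp}, loc={spec.anchor_loc}) never "
                          "visited; baseline activity only")
        else:
            visit_ang = ang[starts]
            # index of most recent visit for every grid point (-1 = none yet)
            last = np.searchsorted(starts, np.arange(len(grid)), side="right") - 1
            has = last >= 0
            delta = np.where(has, ang - visit_ang[np.clip(last, 0, None)], np.nan)
            g_task = np.exp(spec.kappa_task
                            * (np.cos(np.radians(delta - spec.lag_deg)) - 1.0))
            pref_phase = spec.preferred_gp_phase_deg(span)
            g_gp = np.exp(spec.kappa_gp
                          * (np.cos(np.radians(gp_phase - pref_phase)) - 1.0))
            gain = np.ones(len(grid))
            if interval_gain and spec.neuron_id in interval_gain:
                g_times, g_vals = interval_gain[spec.neuron_id]
                g_times = np.asarray(g_times, float)
                g_vals = np.asarray(g_vals, float)
                gi = np.searchsorted(g_times, grid, side="right") - 1
                gain = np.where(gi >= 0, g_vals[np.clip(gi, 0, None)], 1.0)
            bump = np.where(has & valid,
                            spec.peak_rate * gain * g_task * g_gp, 0.0)
            lam = lam + np.nan_to_num(bump)
        counts = rng.poisson(lam * dt)
        spk_bins = np.repeat(np.arange(len(grid)), counts)
        times = grid[spk_bins] + rng.random(len(spk_bins)) * dt
        rows_id.append(np.full(len(times), spec.neuron_id))
        rows_t.append(np.sort(times))
    return pd.DataFrame({"neuron_id": np.concatenate(rows_id).astype(int),
                         "time_s": np.concatenate(rows_t)})


def simulate_rate_spikes(behaviour: SimulatedBehaviour, rate_fn, seed: int,
                         dt: float = 0.01, neuron_id: int = 0) -> pd.DataFrame:
    """Poisson spikes from an arbitrary intensity function.

    ``rate_fn(angle_unwrapped_deg, gp_phase_deg, node)`` receives aligned
    arrays over the simulation grid and returns nonnegative rates (Hz).
    Useful for constructing pure place, pure goal-progress, trajectory-tuned
    or structureless control neurons.
    """
    rng = np.random.default_rng(seed)
    grid, ang, occupied = _occupancy_grid(behaviour, dt)
    span = behaviour.task.state_span_deg
    gp_phase = np.mod(ang, span) / span * 360.0
    lam = np.asarray(rate_fn(ang, gp_phase, occupied), dtype=float)
    counts = rng.poisson(np.clip(lam, 0, None) * dt)
    spk_bins = np.repeat(np.arange(len(grid)), counts)
    times = np.sort(grid[spk_bins] + rng.random(len(spk_bins)) * dt)
    return pd.DataFrame({"neuron_id": np.full(len(times), neuron_id, dtype=int),
                         "time_s": times})


# ---------------------------------------------------------------------------
# offline (sleep) activity
# ---------------------------------------------------------------------------

@dataclass
class OfflineModule:
    """One co-anchored module: neuron ids and their lags on the buffer."""

    neuron_ids: list[int]
    lags_deg: list[float]
    peak_rate: float = 12.0
    baseline_rate: float = 0.3
    kappa: float = 1.5


@dataclass
class OfflineGeneratorSpec:
    """Latent-phase generator for offline coactivity.

    The latent phase performs a random walk; on a ``ring`` it wraps at 360
    degrees, so coactivity falls with *circular* lag distance (V-shaped
    against forward distance), whereas on a ``delay_line`` it reflects at the
    ends, so coactivity falls with *forward* distance throughout. Identical
    dynamics up to the boundary rule keep the two topologies comparable.
    """

    topology: str  # "ring" | "delay_line"
    modules: list[OfflineModule] = field(default_factory=list)
    phase_sigma_deg: float = 150.0   # phase diffusion, deg / sqrt(s)
    line_margin_deg: float = 90.0    # delay line extends past the lag range

    def __post_init__(self):
        if self.topology not in ("ring", "delay_line"):
            raise ValueError("topology must be 'ring' or 'delay_line'")
        for m in self.modules:
            if len(m.neuron_ids) < 2:
                raise ValueError("each module needs >= 2 neurons")


def simulate_offline(spec: OfflineGeneratorSpec, duration_s: float,
                     seed: int, dt: float = 0.05) -> pd.DataFrame:
    """Sleep spike table (neuron_id, time_s) under the latent-phase model."""
    rng = np.random.default_rng(seed)
    n_bins = int(round(duration_s / dt))
    t = np.arange(n_bins) * dt
    rows_id, rows_t = [], []
    for mod in spec.modules:
        steps = rng.normal(0.0, spec.phase_sigma_deg * np.sqrt(dt), n_bins)
        walk = np.cumsum(steps) + rng.uniform(0, 360)
        if spec.topology == "ring":
            phase = np.mod(walk, 360.0)
        else:
            # reflect at the ends of the line (no wrap-around); the line
            # extends one margin beyond the outermost lags so end neurons'
            # fields are not truncated
            lo, hi = -spec.line_margin_deg, 360.0 + spec.line_margin_deg
            span = hi - lo
            m = np.mod(walk - lo, 2.0 * span)
            phase = lo + np.where(m > span, 2.0 * span - m, m)
        for nid, lag in zip(mod.neuron_ids, mod.lags_deg):
            if spec.topology == "ring":
                g = np.exp(mod.kappa * (np.cos(np.radians(phase - lag)) - 1.0))
            else:
                # linear (non-wrapping) distance along the delay line
                width = 360.0 / (2.0 * np.pi) / np.sqrt(mod.kappa)
                g = np.exp(-0.5 * ((phase - lag) / width) ** 2)
            lam = mod.baseline_rate + mod.peak_rate * g
            counts = rng.poisson(lam * dt)
            spk_bins = np.repeat(np.arange(n_bins), counts)
            times = t[spk_bins] + rng.random(len(spk_bins)) * dt
            rows_id.append(np.full(len(times), nid))
            rows_t.append(np.sort(times))
    return pd.DataFrame({"neuron_id": np.concatenate(rows_id).astype(int),
                         "time_s": np.concatenate(rows_t)})
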