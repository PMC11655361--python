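"""Projection of spikes onto circular task coordinates.

Every state is resampled to the same number of bins (90 by default), so an
ABCD trial occupies 360 bins (1 bin = 1 degree) and an ABCDE trial 450 bins
(1 bin = 0.8 degree); a full trial always spans 360 degrees of task angle.
Goal progress is the within-state fraction, binned into thirds (operational)
or fifths (encoding model).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .behaviour import TrialTable
from .maze import MazeGraph
from .synthetic import node_at_times


@dataclass(frozen=True)
class NormalizationConfig:
    bins_per_state: int = 90
    sigma_deg: float = 10.0
    gp_bins: int = 3

    def n_bins(self, periodicity: int) -> int:
        return self.bins_per_state * periodicity

    def bin_deg(self, periodicity: int) -> float:
        return 360.0 / self.n_bins(periodicity)


@dataclass
class TaskAlignedActivity:
    """Per-trial firing rates on the normalized circular task axis (Hz)."""

    matrix: np.ndarray  # (n_trials, n_bins)
    neuron_id: int
    task_id: str
    periodicity: int
    cfg: NormalizationConfig = field(default_factory=NormalizationConfig)

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    @property
    def bin_deg(self) -> float:
        return 360.0 / self.n_bins

    def mean_curve(self, smoothed: bool = True) -> np.ndarray:
        m = self.matrix.mean(axis=0)
        if smoothed:
            m = smooth_circular(m, self.cfg.sigma_deg, self.bin_deg)
        return m

    def sem_curve(self) -> np.ndarray:
        return self.matrix.std(axis=0, ddof=1) / np.sqrt(self.n_trials)


def smooth_circular(curve: np.ndarray, sigma_deg: float,
                    bin_deg: float = 1.0) -> np.ndarray:
    """Circular Gaussian smoothing (no edge artefacts, mass preserving)."""
    return gaussian_filter1d(np.asarray(curve, float), sigma_deg / bin_deg,
                             mode="wrap", truncate=8.0)


def normalize_activity(spike_times: np.ndarray, trials: TrialTable,
                       cfg: NormalizationConfig | None = None,
                       neuron_id: int = 0, task_id: str = "task",
                       ) -> TaskAlignedActivity:
    """Time-normalize one neuron's spikes to the circular task axis.

    Each state interval is divided into ``bins_per_state`` equal-duration
    sub-intervals; the firing rate in each is the spike count divided by the
    sub-interval duration, so total spike mass per trial is conserved.
    """
    cfg = cfg or NormalizationConfig()
    p = trials.task.periodicity
    B = cfg.bins_per_state
    spikes = np.sort(np.asarray(spike_times, float))
    mats = []
    for trial, sub in trials.table.groupby("trial"):
        row = np.empty(p * B)
        for r in sub.itertuples():
            edges = np.linspace(r.t_start, r.t_end, B + 1)
            counts, _ = np.histogram(spikes, bins=edges)
            row[r.state_idx * B:(r.state_idx + 1) * B] = counts / np.diff(edges)
        mats.append(row)
    if not mats:
        raise ValueError("zero complete trials")
    return TaskAlignedActivity(matrix=np.vstack(mats), neuron_id=neuron_id,
                               task_id=task_id, periodicity=p, cfg=cfg)


def normalize_all(spikes: pd.DataFrame, trials: TrialTable,
                  cfg: NormalizationConfig | None = None,
                  task_id: str = "task") -> dict[int, TaskAlignedActivity]:
    return {int(nid): normalize_activity(sub["time_s"].to_numpy(), trials, cfg,
                                         neuron_id=int(nid), task_id=task_id)
            for nid, sub in spikes.groupby("neuron_id")}


def goal_progress_profile(act: TaskAlignedActivity, n_bins: int = 3) -> np.ndarray:
    """Mean rate per goal-progress bin, averaged across states and trials."""
    if n_bins not in (3, 5):
        raise ValueError("goal-progress bins must be 3 or 5")
    B = act.cfg.bins_per_state
    per_state = act.matrix.mean(axis=0).reshape(act.periodicity, B).mean(axis=0)
    return per_state.reshape(n_bins, B // n_bins).mean(axis=1)


def preferred_gp_bin(act: TaskAlignedActivity, n_bins: int = 3) -> int:
    """Argmax goal-progress bin (ties broken by the lowest index)."""
    return int(np.argmax(goal_progress_profile(act, n_bins)))


def goal_progress_consistency(profiles: list[np.ndarray]) -> float:
    """Mean pairwise cross-task Pearson r of goal-progress profiles.

    NaN when fewer than 2 tasks or a profile is constant (excluded: a flat
    profile has no defined correlation).
    """
    ok = [p for p in profiles if np.std(p) > 0]
    if len(ok) < 2:
        return float("nan")
    rs = [stats.pearsonr(a, b)[0]
          for i, a in enumerate(ok) for b in ok[i + 1:]]
    return float(np.mean(rs))


# ---------------------------------------------------------------------------
# binned behavioural covariates on the same circular grid
# ---------------------------------------------------------------------------

@dataclass
class BinnedSession:
    """Behavioural covariates per (trial, task-space bin).

    Arrays are (n_trials, n_bins) unless noted. ``gp3``/``gp5`` are static
    per-bin goal-progress levels; ``node`` is the node occupied at the bin
    centre; confounds are locomotion speed (node transitions / s, 1-s
    smoothed), its derivative, time from the last reward (s) and Manhattan
    distance to the current goal.
    """

    node: np.ndarray
    bin_time: np.ndarray
    speed: np.ndarray
    acceleration: np.ndarray
    time_from_reward: np.ndarray
    dist_from_reward: np.ndarray
    gp3: np.ndarray  # (n_bins,)
    gp5: np.ndarray  # (n_bins,)
    periodicity: int
    cfg: NormalizationConfig

    @property
    def n_trials(self) -> int:
        return self.node.shape[0]

    @property
    def n_bins(self) -> int:
        return self.node.shape[1]

    def flat(self, name: str) -> np.ndarray:
        a = getattr(self, name)
        return a.reshape(-1) if a.ndim == 2 else np.tile(a, self.n_trials)


def bin_session(trials: TrialTable, positions: pd.DataFrame, maze: MazeGraph,
                cfg: NormalizationConfig | None = None) -> BinnedSession:
    cfg = cfg or NormalizationConfig()
    p = trials.task.periodicity
    B = cfg.bins_per_state
    nb = p * B
    gp3 = (np.arange(nb) % B) // (B // 3)
    gp5 = (np.arange(nb) % B) // (B // 5)

    # instantaneous speed from node-entry times, smoothed over 1 s
    pt = positions["time_s"].to_numpy()
    t_hi = np.arange(pt[0], trials.table["t_end"].iloc[-1] + 0.1, 0.1)
    trans_counts, _ = np.histogram(pt, bins=np.append(t_hi, t_hi[-1] + 0.1))
    speed_hi = gaussian_filter1d(trans_counts / 0.1, sigma=10, mode="nearest")
    accel_hi = np.gradient(speed_hi, 0.1)

    n_trials = trials.n_trials
    node = np.zeros((n_trials, nb), int)
    bt = np.zeros((n_trials, nb))
    tfr = np.zeros((n_trials, nb))
    dfr = np.zeros((n_trials, nb))
    for r in trials.table.itertuples():
        centers = r.t_start + (np.arange(B) + 0.5) * (r.t_end - r.t_start) / B
        sl = np.s_[r.trial, r.state_idx * B:(r.state_idx + 1) * B]
        bt[sl] = centers
        node[sl] = node_at_times(centers, positions)
        tfr[sl] = centers - r.t_start
        dfr[sl] = [maze.manhattan(int(n), r.dst_loc) for n in node[sl]]
    idx = np.clip(np.searchsorted(t_hi, bt.reshape(-1)) - 1, 0, len(t_hi) - 1)
    speed = speed_hi[idx].reshape(n_trials, nb)
    accel = accel_hi[idx].reshape(n_trials, nb)
    return BinnedSession(node=node, bin_time=bt, speed=speed,
                         acceleration=accel, time_from_reward=tfr,
                         dist_from_reward=dfr, gp3=gp3, gp5=gp5,
                         periodicity=p, cfg=cfg)
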