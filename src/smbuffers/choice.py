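"""Distal prediction of behavioural choices from bump-time activity.

For a neuron with anchor (goal-progress bin, location) and task-space lag
``lag``, every moment the animal stands one maze step before the anchor (the
adjacent node, one goal-progress bin earlier) is a *candidate event*: the
animal may or may not proceed to the anchor. A logistic regression asks
whether the neuron's activity at its *bump time* - the window
[lag, lag + one lag bin) of task space after the most recent anchor visit -
predicts the outcome, over and above the animal's own choice history
(previous-trial outcomes collapsed through a fitted exponential kernel).
Control regressions replace the bump window by a random window, the decision
window (just before the event), or windows shifted by whole states.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .anchoring import AnchorSpace, visit_starts
from .maze import MazeGraph
from .task_space import BinnedSession, TaskAlignedActivity

ACTIVITY_TIMES = ("bump", "random", "decision", "shift90", "shift180",
                  "shift270")


@dataclass
class ChoiceDataset:
    """One row per candidate event; activity columns per window type."""

    table: pd.DataFrame
    anchor_gp: int
    anchor_loc: int
    lag_deg: float
    n_history: int = 10


def _window_mean(rates: np.ndarray, start: int, width: int) -> float:
    if start < 0 or start + width > len(rates):
        return float("nan")
    return float(rates[start:start + width].mean())


def candidate_events(bs: BinnedSession, anchor_gp: int, anchor_loc: int,
                     maze: MazeGraph | None = None,
                     space: AnchorSpace | None = None) -> pd.DataFrame:
    """Candidate events for one anchor: entries into a (previous
    goal-progress bin, node adjacent to the anchor) conjunction, with the
    binary outcome (did the next step enter the anchor conjunction) and the
    most recent prior anchor visit. Events with no prior visit are dropped;
    the animal already standing at the anchor node is excluded by
    construction (adjacent nodes only)."""
    maze = maze or MazeGraph.grid()
    space = space or AnchorSpace(periodicity=bs.periodicity)
    node = bs.flat("node")
    gp = bs.flat("gp3")
    nb = bs.n_bins
    trial_of = np.arange(len(node)) // nb
    pre_gp = (anchor_gp - 1) % space.gp_bins
    adjacent = maze.neighbors(anchor_loc)
    starts_anchor = np.flatnonzero(visit_starts(bs, space)[
        space.index(anchor_gp, anchor_loc)])
    hit = np.isin(node, adjacent) & (gp == pre_gp)
    events = np.flatnonzero(hit & ~np.concatenate(([False], hit[:-1])))
    rows = []
    for k in events:
        future = node[k:]
        changed = np.flatnonzero(future != node[k])
        if len(changed) == 0:
            continue
        j = k + changed[0]
        outcome = int(node[j] == anchor_loc and gp[j] == anchor_gp)
        prev = starts_anchor[starts_anchor < k]
        if len(prev) == 0:
            continue
        rows.append(dict(event_bin=int(k), trial=int(trial_of[k]),
                         outcome=outcome, last_visit_bin=int(prev[-1])))
    return pd.DataFrame(rows, columns=["event_bin", "trial", "outcome",
                                       "last_visit_bin"])


def build_choice_dataset(act: TaskAlignedActivity, bs: BinnedSession,
                         anchor_gp: int, anchor_loc: int, lag_deg: float,
                         maze: MazeGraph | None = None,
                         space: AnchorSpace | None = None,
                         n_history: int = 10, seed: int = 0) -> ChoiceDataset:
    """Build the per-event design for one neuron in one task.

    Candidate events are entries into a (previous goal-progress bin, node
    adjacent to the anchor) conjunction; events where the animal already
    occupies the anchor node are excluded. Events with fewer than
    ``n_history`` prior trials are zero-padded and flagged.
    """
    maze = maze or MazeGraph.grid()
    space = space or AnchorSpace(periodicity=bs.periodicity)
    rng = np.random.default_rng(seed)
    rates = act.matrix.reshape(-1)
    nb = act.n_bins
    w = bs.cfg.bins_per_state // space.gp_bins  # one lag bin (30 deg in ABCD)
    lag_bins = int(round(lag_deg / 360.0 * nb))
    ev = candidate_events(bs, anchor_gp, anchor_loc, maze, space)
    starts_anchor = np.flatnonzero(visit_starts(bs, space)[
        space.index(anchor_gp, anchor_loc)])
    trial_of = np.arange(len(rates)) // nb
    visited_in_trial = np.zeros(act.n_trials, bool)
    for v in starts_anchor:
        visited_in_trial[trial_of[v]] = True

    rows = []
    for e in ev.itertuples():
        k, v, trial, outcome = (e.event_bin, e.last_visit_bin, e.trial,
                                e.outcome)

        def pre_event_window(start: int, recur: bool = False) -> float:
            # activity must precede the choice: windows reaching past the
            # event would leak post-outcome activity into the regressor.
            # The buffer re-activates every full trial of task space, so
            # visit-referenced windows advance to the most recent occurrence
            # of that task phase before the event.
            if recur and start + w <= k:
                start += ((k - w - start) // nb) * nb
            if start + w > k or start < 0:
                return float("nan")
            return _window_mean(rates, start, w)

        # the random control samples a different task phase than the bump
        bump_phase = (v + lag_bins) % nb
        for _ in range(50):
            rnd = int(rng.integers(0, nb - w))
            if min(abs(rnd - bump_phase), nb - abs(rnd - bump_phase)) > w:
                break
        row = dict(event_bin=k, trial=trial, outcome=outcome,
                   bump=pre_event_window(v + lag_bins, recur=True),
                   decision=pre_event_window(k - w),
                   random=pre_event_window(int(trial * nb + rnd)))
        span_bins = nb // space.periodicity
        for s, name in ((1, "shift90"), (2, "shift180"), (3, "shift270")):
            shifted = v + (lag_bins + s * span_bins) % nb
            row[name] = pre_event_window(shifted, recur=True)
        for h in range(1, n_history + 1):
            row[f"hist_{h}"] = (float(visited_in_trial[trial - h])
                                if trial - h >= 0 else 0.0)
        row["padded"] = trial < n_history
        rows.append(row)
    table = pd.DataFrame(rows).dropna(subset=["bump"])
    return ChoiceDataset(table=table, anchor_gp=anchor_gp,
                         anchor_loc=anchor_loc, lag_deg=lag_deg,
                         n_history=n_history)


@dataclass
class HistoryKernel:
    raw_coefficients: np.ndarray
    amplitude: float
    decay: float
    weights: np.ndarray
    fitted: bool  # False -> fall back to raw per-lag history columns


def _fit_logit(X: np.ndarray, y: np.ndarray, coef_cap: float = 20.0):
    """Unpenalized logistic fit; returns (params, se) or None on separation
    or non-convergence (detected via a coefficient magnitude cap)."""
    import statsmodels.api as sm
    if len(np.unique(y)) < 2:
        return None
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                disp=0, maxiter=200)
    except Exception:
        return None
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)) or np.abs(params[1:]).max() > coef_cap:
        return None
    return params, np.asarray(res.bse)


def fit_history_kernel(datasets: list[ChoiceDataset]) -> HistoryKernel:
    """First-pass logistic fit with one column per history lag, pooled over
    tasks, followed by a least-squares exponential decay fit to the history
    coefficients. Non-decaying coefficients trigger a flagged fallback to the
    raw columns."""
    n_h = datasets[0].n_history
    cols = [f"hist_{h}" for h in range(1, n_h + 1)]
    tab = pd.concat([d.table for d in datasets], ignore_index=True)
    fit = _fit_logit(tab[cols].to_numpy(), tab["outcome"].to_numpy())
    if fit is None:
        raw = np.zeros(n_h)
        return HistoryKernel(raw, 0.0, 0.0, np.zeros(n_h), False)
    coefs = fit[0][1:]
    lags = np.arange(1, n_h + 1, dtype=float)
    try:
        (a, b), _ = curve_fit(lambda x, a, b: a * np.exp(-b * x), lags,
                              coefs, p0=(max(coefs[0], 0.1), 0.5),
                              bounds=([0.0, 0.0], [np.inf, np.inf]),
                              maxfev=2000)
        weights = a * np.exp(-b * lags)
        ok = a > 0
    except RuntimeError:
        ok = False
        a = b = 0.0
        weights = np.zeros(n_h)
    if not ok:
        return HistoryKernel(coefs, 0.0, 0.0, np.zeros(n_h), False)
    return HistoryKernel(coefs, float(a), float(b), weights, True)


def collapsed_history(dataset: ChoiceDataset, kernel: HistoryKernel) -> np.ndarray:
    cols = [f"hist_{h}" for h in range(1, dataset.n_history + 1)]
    H = dataset.table[cols].to_numpy()
    if kernel.fitted and kernel.weights.sum() > 0:
        return H @ (kernel.weights / kernel.weights.sum())
    return H @ np.ones(dataset.n_history) / dataset.n_history


def predict_future_choice(datasets: list[ChoiceDataset],
                          kernel: HistoryKernel,
                          activity_time: str = "bump") -> pd.DataFrame:
    """Per-task logistic regression of outcome on the chosen activity window
    plus collapsed choice history. Returns one row per task (NaN beta where
    the fit was degenerate or separated; excluded from aggregation)."""
    if activity_time not in ACTIVITY_TIMES:
        raise ValueError(f"unknown activity time {activity_time!r}")
    rows = []
    for ti, d in enumerate(datasets):
        tab = d.table
        x = tab[activity_time].to_numpy()
        ok = np.isfinite(x)
        hist = collapsed_history(d, kernel)
        sd = x[ok].std()
        beta = se = float("nan")
        if ok.sum() >= 10 and sd > 0:
            X = np.column_stack([(x[ok] - x[ok].mean()) / sd, hist[ok]])
            fit = _fit_logit(X, tab["outcome"].to_numpy()[ok])
            if fit is not None:
                beta, se = float(fit[0][1]), float(fit[1][1])
        rows.append(dict(task=ti, activity_time=activity_time, beta=beta,
                         se=se, n_events=int(ok.sum())))
    return pd.DataFrame(rows)


def population_ttest(coef_table: pd.DataFrame) -> tuple[float, float]:
    """One-sample t-test of per-task activity coefficients against zero."""
    b = coef_table["beta"].to_numpy()
    b = b[np.isfinite(b)]
    if len(b) < 3:
        return float("nan"), float("nan")
    t, p = stats.ttest_1samp(b, 0.0)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# synthetic choice-prediction experiment
# ---------------------------------------------------------------------------

def simulate_choice_task(seed: int, coupled: bool,
                         maze: MazeGraph | None = None, n_trials: int = 40,
                         epsilon: float = 0.9, stickiness: float = 0.5,
                         coupling: float = 2.0, min_lag_deg: float = 60.0,
                         require_gp: int | None = None) -> ChoiceDataset | None:
    """One synthetic task for the choice-prediction experiment.

    The agent is habitual (sticky path choices), so outcomes autocorrelate
    across trials. A buffer neuron anchored at a step with variable outcomes
    is simulated; with ``coupled=True`` its bump amplitude after each anchor
    visit is multiplied by (1 + coupling) whenever the animal will proceed to
    the anchor at the next candidate event, injecting a genuine
    activity-to-choice link beyond habit. Returns None when the task offers
    no anchor with both outcome classes.
    """
    from .maze import generate_task_set
    from .synthetic import AgentPolicy, SyntheticNeuronSpec, simulate_behaviour, simulate_spikes
    from .task_space import bin_session, normalize_activity

    maze = maze or MazeGraph.grid()
    space = AnchorSpace()
    rng = np.random.default_rng(seed)
    task = generate_task_set(maze, 1, seed=int(rng.integers(2 ** 31)))[0]
    beh = simulate_behaviour(maze, task,
                             AgentPolicy(epsilon=epsilon,
                                         path_stickiness=stickiness),
                             n_trials, seed=int(rng.integers(2 ** 31)))
    bs = bin_session(beh.trials, beh.positions, maze)

    # find an anchor whose candidate events have both outcome classes
    choices = []
    for a in rng.permutation(space.n_anchors):
        g, loc = space.anchor(int(a))
        if require_gp is not None and g != require_gp:
            continue
        ev = candidate_events(bs, g, loc, maze, space)
        if len(ev) >= n_trials // 2 and 0.25 <= ev["outcome"].mean() <= 0.75:
            choices.append((int(a), ev))
            break
    if not choices:
        return None
    a, ev = choices[0]
    g, loc = space.anchor(a)
    lag = float(rng.uniform(min_lag_deg, 360.0 - min_lag_deg))
    spec = SyntheticNeuronSpec(neuron_id=0, anchor_gp=g, anchor_loc=loc,
                               lag_deg=lag, kappa_task=20.0, kappa_gp=0.5)
    gain = None
    if coupled:
        # bump amplitude between consecutive candidate events encodes the
        # upcoming outcome (the activity-to-choice link to be detected)
        bt = bs.flat("bin_time")
        ev_times = bt[ev["event_bin"].to_numpy()]
        outcomes = ev["outcome"].to_numpy()
        times = np.concatenate(([bt[0] - 1.0], ev_times[:-1]))
        gains = 1.0 + coupling * outcomes
        gain = {0: (times, gains)}
    spk = simulate_spikes(beh, [spec], seed=int(rng.integers(2 ** 31)),
                          interval_gain=gain)
    act = normalize_activity(spk["time_s"].to_numpy(), beh.trials,
                             neuron_id=0, task_id="choice")
    return build_choice_dataset(act, bs, g, loc, lag, maze, space,
                                seed=int(rng.integers(2 ** 31)))


def run_choice_experiment(n_tasks: int, coupled: bool, seed: int,
                          **task_kwargs) -> dict:
    """Simulate ``n_tasks`` tasks, fit the history kernel, and run the
    logistic regression for the bump window and every control window.

    Returns per-window coefficient tables and population t-statistics.
    """
    rng = np.random.default_rng(seed)
    datasets = []
    attempts = 0
    while len(datasets) < n_tasks and attempts < 4 * n_tasks:
        d = simulate_choice_task(int(rng.integers(2 ** 31)), coupled,
                                 **task_kwargs)
        attempts += 1
        if d is not None and len(d.table) >= 10:
            datasets.append(d)
    kernel = fit_history_kernel(datasets)
    out = {"kernel": kernel, "tables": {}, "tests": {}}
    for at in ACTIVITY_TIMES:
        tab = predict_future_choice(datasets, kernel, at)
        out["tables"][at] = tab
        out["tests"][at] = population_ttest(tab)
    return out
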