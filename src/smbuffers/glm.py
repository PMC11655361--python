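"""Cross-validated encoding model for goal-progress, place and trajectory
tuning, with circular-shift permutation nulls.

The design follows a leave-one-(task x state)-out scheme: training periods
provide, per variable, the neuron's mean firing rate at each level (5
goal-progress bins, 9 nodes, or 24 place-next-place conjunctions); in the
held-out period the regressor for a variable takes the training-mean rate of
the current bin's level. Ordinary least squares is fitted per fold, together
with locomotion confounds, and a neuron counts as tuned to a variable when
(1) its mean coefficient exceeds the 95th percentile of coefficients from
circularly shifted activity and (2) its cross-task level-map correlations are
significantly above zero.

The null shifts each session's spike train circularly in *time* and re-bins
it through the same normalization, so the shifted activity keeps its
autocorrelation but loses any systematic alignment to task coordinates
(a shift of the already-normalized array would spuriously re-align periodic
variables whenever the shift is close to a multiple of the state span).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behaviour import TrialTable
from .maze import MazeGraph
from .task_space import TaskAlignedActivity, BinnedSession

CONFOUND_NAMES = ("speed", "acceleration", "time_from_reward", "dist_from_reward")


@dataclass
class GlmTaskData:
    """Per-task inputs for the encoding model: normalized activity, binned
    behavioural covariates, and the raw spike train + trial table used to
    generate time-shifted permutations."""

    act: TaskAlignedActivity
    bs: BinnedSession
    spike_times: np.ndarray
    trials: TrialTable


@dataclass
class TuningVerdict:
    variable: str
    mean_beta: float
    perm_threshold: float  # 95th percentile of the permutation mean betas
    xcorr_mean: float
    xcorr_p: float
    tuned: bool
    fold_betas: np.ndarray | None = None


def _edge_codes(maze: MazeGraph) -> dict[tuple[int, int], int]:
    """Directed-edge (place, next place) conjunction codes, 0..23."""
    codes = {}
    for a, b in sorted(maze.graph.edges):
        codes[(a, b)] = len(codes)
        codes[(b, a)] = len(codes)
    return codes


def _next_place_labels(node_flat: np.ndarray, maze: MazeGraph) -> np.ndarray:
    """Conjunction label per bin: current node x next (different) node."""
    codes = _edge_codes(maze)
    n = len(node_flat)
    nxt_node = np.empty(n, int)
    upcoming = node_flat[-1]  # tail bins carry a self-pair -> label -1
    for i in range(n - 1, -1, -1):
        nxt_node[i] = upcoming
        if i > 0 and node_flat[i] != node_flat[i - 1]:
            upcoming = node_flat[i]
    return np.array([codes.get((int(a), int(b)), -1)
                     for a, b in zip(node_flat, nxt_node)])


def _bin_edges(trials: TrialTable, bins_per_state: int) -> np.ndarray:
    """Contiguous sub-interval edges matching the normalized (trial x bin)
    flattening order."""
    edges = []
    for r in trials.table.itertuples():
        e = np.linspace(r.t_start, r.t_end, bins_per_state + 1)
        edges.append(e[:-1])
    edges.append(np.array([trials.table["t_end"].iloc[-1]]))
    return np.concatenate(edges)


@dataclass
class _NeuronDesign:
    y: np.ndarray            # (N,) rates, tasks concatenated
    fold: np.ndarray         # (N,) fold id = task_idx * periodicity + state
    labels: dict[str, np.ndarray]   # variable -> (N,) level codes (-1 invalid)
    n_levels: dict[str, int]
    confounds: np.ndarray    # (N, 4)
    task_slices: list[slice]
    n_folds: int
    edges: list[np.ndarray]          # per-task time-bin edges
    spikes: list[np.ndarray]         # per-task spike times


def build_neuron_design(task_data: list[GlmTaskData],
                        maze: MazeGraph | None = None,
                        trajectory: bool = False) -> _NeuronDesign:
    maze = maze or MazeGraph.grid()
    ys, folds, gp5s, nodes, trajs, confs, slices = [], [], [], [], [], [], []
    edges, spikes = [], []
    off = 0
    p = task_data[0].act.periodicity
    for ti, td in enumerate(task_data):
        act, bs = td.act, td.bs
        B = act.cfg.bins_per_state
        y = act.matrix.reshape(-1)
        state = np.tile(np.arange(act.n_bins) // B, act.n_trials)
        ys.append(y)
        folds.append(ti * p + state)
        gp5s.append(bs.flat("gp5"))
        nodes.append(bs.flat("node") - 1)
        if trajectory:
            trajs.append(_next_place_labels(bs.flat("node"), maze))
        confs.append(np.column_stack([bs.flat(c) for c in CONFOUND_NAMES]))
        slices.append(slice(off, off + len(y)))
        off += len(y)
        edges.append(_bin_edges(td.trials, B))
        t0, t1 = td.trials.state_edges()[0], td.trials.state_edges()[-1]
        st = np.asarray(td.spike_times, float)
        spikes.append(st[(st >= t0) & (st < t1)])
    labels = {"goal_progress": np.concatenate(gp5s),
              "place": np.concatenate(nodes)}
    n_levels = {"goal_progress": 5, "place": 9}
    if trajectory:
        labels["trajectory"] = np.concatenate(trajs)
        n_levels["trajectory"] = 24
    return _NeuronDesign(y=np.concatenate(ys), fold=np.concatenate(folds),
                         labels=labels, n_levels=n_levels,
                         confounds=np.vstack(confs), task_slices=slices,
                         n_folds=p * len(task_data), edges=edges, spikes=spikes)


def _shifted_stack(design: _NeuronDesign, n_perm: int, rng,
                   min_shift_frac: float = 0.05) -> np.ndarray:
    """(n_perm + 1, N) activity; row 0 is the real activity, the rest are
    re-binned spike trains circularly shifted in time (shift uniform on
    [f, 1-f] of the session span to avoid near-identity shifts)."""
    N = len(design.y)
    Y = np.empty((n_perm + 1, N))
    Y[0] = design.y
    widths = [np.diff(e) for e in design.edges]
    for pi in range(1, n_perm + 1):
        for sl, e, st, w in zip(design.task_slices, design.edges,
                                design.spikes, widths):
            t0, t1 = e[0], e[-1]
            span = t1 - t0
            shift = rng.uniform(min_shift_frac, 1.0 - min_shift_frac) * span
            shifted = t0 + np.mod(st - t0 + shift, span)
            counts, _ = np.histogram(shifted, bins=e)
            Y[pi, sl] = counts / w
    return Y


def _fold_level_means(Y: np.ndarray, codes: np.ndarray, n_codes: int,
                      n_folds: int, n_levels: int) -> np.ndarray:
    """Leave-fold-out level means, (n_rows, n_folds, n_levels)."""
    counts = np.bincount(codes, minlength=n_codes).reshape(n_folds, n_levels)
    sums = np.stack([np.bincount(codes, weights=row, minlength=n_codes)
                     for row in Y]).reshape(len(Y), n_folds, n_levels)
    tot_sum = sums.sum(axis=1, keepdims=True)
    tot_cnt = counts.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = (tot_sum - sums) / (tot_cnt - counts)
    return np.nan_to_num(means)


def _standardize_fold(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Z-score regressor columns (in place, intercept excluded) and the
    target within a fold, so fold coefficients are on a correlation scale
    and folds with near-degenerate regressors cannot dominate the average."""
    mu = X[:, :, 1:].mean(axis=1, keepdims=True)
    sd = X[:, :, 1:].std(axis=1, keepdims=True)
    X[:, :, 1:] = (X[:, :, 1:] - mu) / np.where(sd < 1e-12, 1.0, sd)
    ymu = y.mean(axis=1, keepdims=True)
    ysd = y.std(axis=1, keepdims=True)
    return (y - ymu) / np.where(ysd < 1e-12, 1.0, ysd)


def fit_and_test(task_data: list[GlmTaskData], n_perm: int = 100, seed: int = 0,
                 variables: tuple[str, ...] = ("goal_progress", "place"),
                 trajectory: bool = False, include_confounds: bool = True,
                 maze: MazeGraph | None = None,
                 alpha: float = 0.05) -> dict[str, TuningVerdict]:
    """Fit the cross-validated encoding model for one neuron across tasks.

    Returns one TuningVerdict per requested variable. With
    ``trajectory=True`` the place variable is replaced by the 24
    place-next-place conjunctions and only the permutation criterion applies
    (the deliberately lenient exclusion screen).
    """
    if len(task_data) < 2:
        raise ValueError("need >= 2 tasks for cross-validated training means")
    if trajectory:
        variables = ("trajectory", "goal_progress")
    rng = np.random.default_rng(seed)
    design = build_neuron_design(task_data, maze=maze, trajectory=trajectory)
    Y = _shifted_stack(design, n_perm, rng)

    fold_means = {}
    for var in variables:
        lv = design.labels[var]
        L = design.n_levels[var]
        valid = lv >= 0
        codes = design.fold * L + np.where(valid, lv, 0)
        Ym = np.where(valid[None, :], Y, 0.0)
        fold_means[var] = _fold_level_means(Ym, codes, design.n_folds * L,
                                            design.n_folds, L)

    # regressor values must come from the fold currently held out; rearrange
    # to per-fold lookup inside the regression loop
    fold_betas = {}
    P = len(Y)
    k = 1 + len(variables) + (design.confounds.shape[1] if include_confounds else 0)
    fold_betas = {var: np.full((P, design.n_folds), np.nan) for var in variables}
    for f in range(design.n_folds):
        idx = np.flatnonzero(design.fold == f)
        if len(idx) == 0:
            continue
        X = np.empty((P, len(idx), k))
        X[:, :, 0] = 1.0
        degenerate = {}
        for vi, var in enumerate(variables):
            lv = design.labels[var][idx]
            col = fold_means[var][:, f, :][:, np.where(lv >= 0, lv, 0)]
            col[:, lv < 0] = 0.0
            X[:, :, 1 + vi] = col
            degenerate[var] = col.std(axis=1) < 1e-12
        if include_confounds:
            X[:, :, 1 + len(variables):] = design.confounds[idx]
        yf = _standardize_fold(X, Y[:, idx])
        XtX = np.einsum("pik,pil->pkl", X, X) + np.eye(k) * 1e-9
        Xty = np.einsum("pik,pi->pk", X, yf)
        beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        for vi, var in enumerate(variables):
            b = beta[:, 1 + vi].copy()
            b[degenerate[var]] = np.nan
            fold_betas[var][:, f] = b

    out = {}
    for var in variables:
        mean_b = np.nanmean(fold_betas[var], axis=1)
        thresh = float(np.percentile(mean_b[1:], 95))
        xr, xp = _cross_task_map_stats(design, var)
        passes_perm = bool(mean_b[0] > thresh)
        if var == "trajectory":
            tuned = passes_perm
        else:
            tuned = bool(passes_perm and np.isfinite(xp) and xp < alpha
                         and xr > 0)
        out[var] = TuningVerdict(variable=var, mean_beta=float(mean_b[0]),
                                 perm_threshold=thresh, xcorr_mean=xr,
                                 xcorr_p=xp, tuned=tuned,
                                 fold_betas=fold_betas[var][0])
    return out


def _task_level_maps(design: _NeuronDesign, var: str,
                     y: np.ndarray | None = None) -> np.ndarray:
    L = design.n_levels[var]
    y = design.y if y is None else y
    maps = np.full((len(design.task_slices), L), np.nan)
    for ti, sl in enumerate(design.task_slices):
        lv, yy = design.labels[var][sl], y[sl]
        ok = lv >= 0
        cnt = np.bincount(lv[ok], minlength=L)
        s = np.bincount(lv[ok], weights=yy[ok], minlength=L)
        maps[ti] = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    return maps


def _map_corr_ttest(maps_a: np.ndarray, maps_b: np.ndarray | None = None):
    """Pairwise map correlations (within one stack, or across two) t-tested
    against zero; returns (mean r, p)."""
    rs = []
    if maps_b is None:
        pairs = [(maps_a[i], maps_a[j]) for i in range(len(maps_a))
                 for j in range(i + 1, len(maps_a))]
    else:
        pairs = [(ma, mb) for ma in maps_a for mb in maps_b]
    for ma, mb in pairs:
        ok = np.isfinite(ma) & np.isfinite(mb)
        if ok.sum() >= 3 and ma[ok].std() > 0 and mb[ok].std() > 0:
            rs.append(stats.pearsonr(ma[ok], mb[ok])[0])
    if len(rs) < 2:
        return (float(np.mean(rs)) if rs else float("nan")), float("nan")
    _, p = stats.ttest_1samp(rs, 0.0)
    return float(np.mean(rs)), float(p)


def _cross_task_map_stats(design: _NeuronDesign, var: str):
    return _map_corr_ttest(_task_level_maps(design, var))


def trajectory_glm(task_data, n_perm: int = 100, seed: int = 0,
                   maze: MazeGraph | None = None) -> TuningVerdict:
    """Lenient trajectory-tuning screen (permutation criterion only), used to
    exclude cells with place-next-place conjunction tuning downstream."""
    res = fit_and_test(task_data, n_perm=n_perm, seed=seed,
                       trajectory=True, maze=maze)
    return res["trajectory"]


def cross_structure_glm(train_data: list[GlmTaskData],
                        test_data: list[GlmTaskData],
                        n_perm: int = 100, seed: int = 0,
                        include_confounds: bool = True,
                        alpha: float = 0.05) -> dict[str, TuningVerdict]:
    """Cross-structure generalization: goal-progress/place level means from
    one task structure (e.g. the five-reward loop) serve as regressors for
    activity recorded in the other structure, with the same permutation and
    map-correlation significance machinery."""
    rng = np.random.default_rng(seed)
    variables = ("goal_progress", "place")
    tr = build_neuron_design(train_data)
    te = build_neuron_design(test_data)
    Ytr = _shifted_stack(tr, n_perm, rng)
    Yte = _shifted_stack(te, n_perm, rng)
    P = n_perm + 1

    means = {}
    for var in variables:
        L = tr.n_levels[var]
        lv = tr.labels[var]
        valid = lv >= 0
        cnt = np.bincount(lv[valid], minlength=L)
        s = np.stack([np.bincount(lv[valid], weights=row[valid], minlength=L)
                      for row in Ytr])
        with np.errstate(invalid="ignore"):
            means[var] = np.nan_to_num(s / np.maximum(cnt, 1))  # (P, L)

    k = 1 + len(variables) + (te.confounds.shape[1] if include_confounds else 0)
    fold_betas = {var: np.full((P, te.n_folds), np.nan) for var in variables}
    for f in range(te.n_folds):
        idx = np.flatnonzero(te.fold == f)
        if len(idx) == 0:
            continue
        X = np.empty((P, len(idx), k))
        X[:, :, 0] = 1.0
        degen = {}
        for vi, var in enumerate(variables):
            lv = te.labels[var][idx]
            col = means[var][:, np.where(lv >= 0, lv, 0)]
            col[:, lv < 0] = 0.0
            X[:, :, 1 + vi] = col
            degen[var] = col.std(axis=1) < 1e-12
        if include_confounds:
            X[:, :, 1 + len(variables):] = te.confounds[idx]
        yf = _standardize_fold(X, Yte[:, idx])
        XtX = np.einsum("pik,pil->pkl", X, X) + np.eye(k) * 1e-9
        Xty = np.einsum("pik,pi->pk", X, yf)
        beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        for vi, var in enumerate(variables):
            b = beta[:, 1 + vi].copy()
            b[degen[var]] = np.nan
            fold_betas[var][:, f] = b

    out = {}
    for var in variables:
        mean_b = np.nanmean(fold_betas[var], axis=1)
        thresh = float(np.percentile(mean_b[1:], 95))
        xr, xp = _map_corr_ttest(_task_level_maps(tr, var),
                                 _task_level_maps(te, var))
        tuned = bool(mean_b[0] > thresh and np.isfinite(xp) and xp < alpha
                     and xr > 0)
        out[var] = TuningVerdict(variable=var, mean_beta=float(mean_b[0]),
                                 perm_threshold=thresh, xcorr_mean=xr,
                                 xcorr_p=xp, tuned=tuned,
                                 fold_betas=fold_betas[var][0])
    return out
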