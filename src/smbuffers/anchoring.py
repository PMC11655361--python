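"""Anchor and task-space-lag inference: the core buffer analyses.

Each neuron is modelled as firing at a fixed task-space lag from a
*behavioural step* (a goal-progress bin x maze location conjunction, its
anchor). Three complementary, cross-validated methods infer the anchor and
lag:

1. **Single-anchor alignment**: activity is re-aligned to visits of every
   candidate anchor; the anchor (and reference training task) minimizing the
   mean cross-task rotation distance 1 - cos(theta) between aligned curves is
   selected on training tasks and validated on the held-out task.
2. **Lagged spatial maps**: spatial tuning to where the animal was at
   successive task lags in the past; the preferred lag maximizes cross-task
   map correlation on training tasks and is validated on the test task.
3. **Anchor-lag regression**: an elastic-net linear model on binary
   indicators "the current bin lies at lag L after a visit to anchor a"
   (one reference anchor level dropped per lag, giving 312 columns for the
   3x3 maze / 3 goal-progress bins / 12 lags), trained on all-but-one task
   and evaluated by predicted-vs-actual correlation on the held-out task.

All three operate in the neuron's preferred goal-progress bin to factor out
the dominant goal-progress tuning.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import ElasticNet

from ._circ import signed_deg
from .remapping import best_rotation, rotation_angles_batch
from .task_space import BinnedSession, TaskAlignedActivity, smooth_circular

REFERENCE_ANCHOR = 26  # dropped dummy level in the lag regression (loc 9, late)


@dataclass(frozen=True)
class AnchorSpace:
    """All goal-progress x location conjunctions and the lag grid."""

    gp_bins: int = 3
    n_locations: int = 9
    periodicity: int = 4

    @property
    def n_anchors(self) -> int:
        return self.gp_bins * self.n_locations

    @property
    def n_lags(self) -> int:
        return self.gp_bins * self.periodicity

    def anchor(self, index: int) -> tuple[int, int]:
        """(gp_bin, location) of anchor ``index`` (location-major order)."""
        return index % self.gp_bins, index // self.gp_bins + 1

    def index(self, gp_bin: int, location: int) -> int:
        return (location - 1) * self.gp_bins + gp_bin

    def lag_deg(self, lag_idx: int) -> float:
        return lag_idx * 360.0 / self.n_lags


def visit_starts(bs: BinnedSession, space: AnchorSpace | None = None) -> np.ndarray:
    """(n_anchors, N) boolean visit-start flags on the flattened bin axis.

    A visit starts at the first bin of a maximal run in which the animal
    occupies the anchor's node during the anchor's goal-progress bin.
    """
    space = space or AnchorSpace(periodicity=bs.periodicity)
    node = bs.flat("node")
    gp = bs.flat("gp3")
    N = len(node)
    out = np.zeros((space.n_anchors, N), bool)
    for a in range(space.n_anchors):
        g, loc = space.anchor(a)
        hit = (node == loc) & (gp == g)
        out[a] = hit & ~np.concatenate(([False], hit[:-1]))
    return out


def align_to_anchor(rates_flat: np.ndarray, starts: np.ndarray, n_bins: int,
                    sigma_deg: float = 10.0) -> tuple[np.ndarray, int]:
    """Mean anchor-aligned curve: one trial-length window per visit, averaged
    and circularly smoothed. Returns (curve or NaN curve, n_windows)."""
    idx = np.flatnonzero(starts)
    idx = idx[idx + n_bins <= len(rates_flat)]
    if len(idx) == 0:
        return np.full(n_bins, np.nan), 0
    win = rates_flat[idx[:, None] + np.arange(n_bins)[None, :]]
    curve = smooth_circular(win.mean(axis=0), sigma_deg, 360.0 / n_bins)
    return curve, len(idx)


def anchor_curve_tensor(task_data: list[tuple[TaskAlignedActivity, BinnedSession]],
                        space: AnchorSpace | None = None):
    """(n_tasks, n_anchors, n_bins) aligned mean curves + visit counts."""
    space = space or AnchorSpace(periodicity=task_data[0][0].periodicity)
    n_tasks = len(task_data)
    nb = task_data[0][0].n_bins
    curves = np.full((n_tasks, space.n_anchors, nb), np.nan)
    counts = np.zeros((n_tasks, space.n_anchors), int)
    for t, (act, bs) in enumerate(task_data):
        rates = act.matrix.reshape(-1)
        starts = visit_starts(bs, space)
        for a in range(space.n_anchors):
            curves[t, a], counts[t, a] = align_to_anchor(
                rates, starts[a], nb, act.cfg.sigma_deg)
    return curves, counts


@dataclass
class AnchorFit:
    anchor_gp: int
    anchor_loc: int
    anchor_index: int
    lag_deg: float
    ref_task: int
    test_task: int
    test_angle_deg: float
    anchored: bool | None        # None = anchor untestable in the test task
    test_corr: float
    mean_distance: float


def _pairwise_angle_tensor(curves: np.ndarray) -> np.ndarray:
    """(n_tasks, n_tasks, n_anchors) best-rotation angles between aligned
    curves (NaN where either curve is missing)."""
    n_tasks, n_anchors, nb = curves.shape
    angles = np.full((n_tasks, n_tasks, n_anchors), np.nan)
    for i in range(n_tasks):
        for j in range(n_tasks):
            if i == j:
                angles[i, j] = 0.0
                continue
            refs = curves[i]
            oths = curves[j]
            ok = np.isfinite(refs).all(axis=1) & np.isfinite(oths).all(axis=1)
            if ok.any():
                angles[i, j, ok] = rotation_angles_batch(refs[ok], oths[ok])
    return angles


def _gp_mask_for_anchor(anchor_gp: int, preferred_gp: int, n_bins: int,
                        periodicity: int, gp_bins: int = 3) -> np.ndarray:
    """Bins of an anchor-aligned curve whose implied current goal-progress
    bin equals the neuron's preferred bin (visit taken at the gp-bin start)."""
    B = n_bins // periodicity
    w = B // gp_bins
    cur = ((anchor_gp * w + np.arange(n_bins)) % B) // w
    return cur == preferred_gp


def fit_single_anchor(curves: np.ndarray, counts: np.ndarray, test_idx: int,
                      preferred_gp: int, space: AnchorSpace,
                      window_deg: float = 45.0,
                      angles: np.ndarray | None = None) -> AnchorFit | None:
    """Method 1 for one held-out task.

    ``curves``/``counts`` come from :func:`anchor_curve_tensor` over all
    tasks; the best (reference training task, anchor) pair minimizes the mean
    rotation distance 1 - cos(theta) over training-task comparisons.
    """
    n_tasks, n_anchors, nb = curves.shape
    train = [t for t in range(n_tasks) if t != test_idx]
    if len(train) < 2:
        raise ValueError("need >= 3 tasks")
    if angles is None:
        angles = _pairwise_angle_tensor(curves)
    dist = 1.0 - np.cos(np.radians(angles))
    # mean distance per (reference training task, anchor) over other train tasks
    M_mean = np.full((len(train), n_anchors), np.nan)
    import warnings as _warnings
    for ri, i in enumerate(train):
        others = [j for j in train if j != i]
        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            M_mean[ri] = np.nanmean(dist[i, others, :], axis=0)
        M_mean[ri, counts[i] == 0] = np.nan
        # anchors compared in fewer than 2 training tasks are unreliable
        valid = (counts[train] > 0).sum(axis=0) >= 2
        M_mean[ri, ~valid] = np.nan
    if np.all(np.isnan(M_mean)):
        return None
    ri, a = np.unravel_index(np.nanargmin(M_mean), M_mean.shape)
    ref = train[ri]
    g, loc = space.anchor(a)
    ref_curve = curves[ref, a]
    lag = float(np.argmax(ref_curve) * 360.0 / nb)
    if counts[test_idx, a] == 0 or not np.isfinite(curves[test_idx, a]).all():
        return AnchorFit(g, loc, int(a), lag, ref, test_idx, float("nan"),
                         None, float("nan"), float(M_mean[ri, a]))
    rot = best_rotation(ref_curve, curves[test_idx, a])
    anchored = bool(abs(signed_deg(rot.angle_deg)) <= window_deg)
    mask = _gp_mask_for_anchor(g, preferred_gp, nb, space.periodicity,
                               space.gp_bins)
    x, y = ref_curve[mask], curves[test_idx, a][mask]
    corr = (float(stats.pearsonr(x, y)[0])
            if x.std() > 0 and y.std() > 0 else float("nan"))
    return AnchorFit(g, loc, int(a), lag, ref, test_idx,
                     float(rot.angle_deg), anchored, corr,
                     float(M_mean[ri, a]))


def consistent_anchor(fits: list[AnchorFit], space: AnchorSpace,
                      min_fraction: float = 0.5):
    """Modal (anchor, lag-bin) over cross-validation folds; None unless the
    same anchor and lag recur in at least ``min_fraction`` of folds."""
    fits = [f for f in fits if f is not None]
    if not fits:
        return None
    lag_w = 360.0 / space.n_lags
    keys = [(f.anchor_index, int(f.lag_deg // lag_w)) for f in fits]
    vals, cnts = np.unique(keys, axis=0, return_counts=True)
    best = np.argmax(cnts)
    if cnts[best] < min_fraction * len(fits):
        return None
    a, lag_bin = vals[best]
    lags = [f.lag_deg for f, k in zip(fits, keys)
            if k == (int(a), int(lag_bin))]
    g, loc = space.anchor(int(a))
    return dict(anchor_gp=g, anchor_loc=loc, anchor_index=int(a),
                lag_deg=float(np.mean(lags)), n_folds=int(cnts[best]),
                n_total=len(fits))


# ---------------------------------------------------------------------------
# Method 2: lagged spatial maps
# ---------------------------------------------------------------------------

def lagged_spatial_maps(act: TaskAlignedActivity, bs: BinnedSession,
                        preferred_gp: int,
                        space: AnchorSpace | None = None,
                        n_lags: int | None = None) -> np.ndarray:
    """(n_lags, 9) spatial maps: current firing rate (preferred goal-progress
    bins only) related to the node occupied ``lag`` degrees earlier in task
    space. Lag 0 is the conventional occupancy-normalized rate map; by
    circularity, past lag X is equivalent to future lag 360 - X."""
    space = space or AnchorSpace(periodicity=act.periodicity)
    n_lags = n_lags or space.n_lags
    rates = act.matrix.reshape(-1)
    node = bs.flat("node")
    gp = bs.flat("gp3")
    N = len(rates)
    w = act.n_bins // n_lags
    maps = np.full((n_lags, 9), np.nan)
    sel_now = gp == preferred_gp
    for li in range(n_lags):
        shift = li * w
        ok = np.arange(N) >= shift
        sel = sel_now & ok
        lagged_node = np.empty(N, int)
        lagged_node[shift:] = node[:N - shift] if shift else node
        if shift:
            lagged_node[:shift] = -1
        for n in range(1, 10):
            m = sel & (lagged_node == n)
            if m.any():
                maps[li, n - 1] = rates[m].mean()
    return maps


def _nan_pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
        return float("nan")
    return float(stats.pearsonr(a[ok], b[ok])[0])


@dataclass
class LagMapFit:
    preferred_lag_idx: int
    preferred_lag_deg: float
    test_corr: float
    anchor_gp: int
    anchor_loc: int
    anchor_index: int
    train_mean_map: np.ndarray


def crossval_lag(maps: np.ndarray, test_idx: int, preferred_gp: int,
                 space: AnchorSpace) -> LagMapFit | None:
    """Method 2 for one held-out task. ``maps`` is (n_tasks, n_lags, 9)."""
    n_tasks = maps.shape[0]
    train = [t for t in range(n_tasks) if t != test_idx]
    mean_r = np.full(space.n_lags, np.nan)
    for li in range(space.n_lags):
        rs = [_nan_pearson(maps[i, li], maps[j, li])
              for k, i in enumerate(train) for j in train[k + 1:]]
        rs = [r for r in rs if np.isfinite(r)]
        if rs:
            mean_r[li] = np.mean(rs)
    if np.all(np.isnan(mean_r)):
        return None
    li = int(np.nanargmax(mean_r))  # argmax; earliest lag wins ties
    with np.errstate(invalid="ignore"):
        train_map = np.nanmean(maps[train, li], axis=0)
    test_corr = _nan_pearson(train_map, maps[test_idx, li])
    # a real-valued lag straddles adjacent 30-degree bins: locate the anchor
    # on the training map pooled over the preferred bin and its better
    # neighbour
    neigh = [(li - 1) % space.n_lags, (li + 1) % space.n_lags]
    nb_best = neigh[int(np.nanargmax([mean_r[n] if np.isfinite(mean_r[n])
                                      else -np.inf for n in neigh]))]
    with np.errstate(invalid="ignore"):
        pooled = np.nanmean(maps[train][:, [li, nb_best], :], axis=(0, 1))
    loc = int(np.nanargmax(pooled)) + 1
    g = int((preferred_gp - li) % space.gp_bins)
    return LagMapFit(preferred_lag_idx=li, preferred_lag_deg=space.lag_deg(li),
                     test_corr=test_corr, anchor_gp=g, anchor_loc=loc,
                     anchor_index=space.index(g, loc), train_mean_map=train_map)


# ---------------------------------------------------------------------------
# Method 3: anchor-lag regression
# ---------------------------------------------------------------------------

def lag_design_columns(space: AnchorSpace) -> list[tuple[int, int]]:
    """(anchor, lag) column order with the reference anchor dropped per lag.

    At every moment exactly one behavioural step was occupied L degrees ago,
    so per lag the full set of anchor indicators is (near-)collinear; one
    reference anchor level is dropped per lag, yielding
    (n_anchors - 1) x n_lags columns (312 in the standard configuration).
    """
    return [(a, li) for a in range(space.n_anchors) if a != REFERENCE_ANCHOR
            for li in range(space.n_lags)]


def build_lag_design(bs: BinnedSession,
                     space: AnchorSpace | None = None) -> np.ndarray:
    """(N, n_columns) binary design: column (a, L) indicates that the *most
    recent* visit to anchor a fell within the 30-degree lag window L before
    the current bin (one-hot over lags per anchor, matching the buffer's
    reset-at-visit semantics; bins more than a full trial past the last visit
    activate no column for that anchor)."""
    space = space or AnchorSpace(periodicity=bs.periodicity)
    starts = visit_starts(bs, space)
    N = starts.shape[1]
    w = bs.cfg.bins_per_state // space.gp_bins
    cols = lag_design_columns(space)
    col_of = {al: ci for ci, al in enumerate(cols)}
    X = np.zeros((N, len(cols)), dtype=np.float64)
    k = np.arange(N)
    for a in range(space.n_anchors):
        v = np.flatnonzero(starts[a])
        if len(v) == 0:
            continue
        last = np.searchsorted(v, k, side="right") - 1
        has = last >= 0
        delta = np.where(has, k - v[np.clip(last, 0, None)], N)
        li = delta // w
        for lag in range(space.n_lags):
            ci = col_of.get((a, lag))
            if ci is not None:
                X[:, ci] = has & (li == lag)
    return X


@dataclass
class LagRegressionFit:
    coef: np.ndarray             # (n_columns,)
    columns: list[tuple[int, int]]
    top_anchor_index: int
    top_anchor_gp: int
    top_anchor_loc: int
    top_lag_deg: float
    top3_lags_deg: np.ndarray
    pred_corr: float
    n_columns: int


def fit_lag_regression(task_data, test_idx: int, preferred_gp: int,
                       space: AnchorSpace | None = None, alpha: float = 0.01,
                       designs: list[np.ndarray] | None = None,
                       model: str = "linear") -> LagRegressionFit:
    """Method 3 for one held-out task.

    Fits the neuron's normalized rate (restricted to its preferred
    goal-progress bin) on the anchor-lag indicator design with an elastic-net
    penalty (equal L1:L2 weights; regularization 0.01 for the linear variant,
    1.0 for the Poisson/log-link variant ``model="lnp"``).
    """
    space = space or AnchorSpace(periodicity=task_data[0][0].periodicity)
    cols = lag_design_columns(space)
    if designs is None:
        designs = [build_lag_design(bs, space) for _, bs in task_data]
    Xs, ys = [], []
    for t, (act, bs) in enumerate(task_data):
        sel = bs.flat("gp3") == preferred_gp
        X = designs[t][sel]
        y = act.matrix.reshape(-1)[sel]
        Xs.append((t, X, y))
    X_tr = np.vstack([X for t, X, y in Xs if t != test_idx])
    y_tr = np.concatenate([y for t, X, y in Xs if t != test_idx])
    X_te = next(X for t, X, y in Xs if t == test_idx)
    y_te = next(y for t, X, y in Xs if t == test_idx)

    if model == "linear":
        net = ElasticNet(alpha=alpha, l1_ratio=0.5, max_iter=5000)
        net.fit(X_tr, y_tr)
        coef = net.coef_
        pred = net.predict(X_te)
    elif model == "lnp":
        import statsmodels.api as sm
        Xc = sm.add_constant(X_tr, has_constant="add")
        fam = sm.families.Poisson()
        res = sm.GLM(y_tr, Xc, family=fam).fit_regularized(
            method="elastic_net", alpha=alpha, L1_wt=0.5, maxiter=200)
        coef = np.asarray(res.params)[1:]
        pred = np.exp(np.asarray(res.params)[0] + X_te @ coef)
    else:
        raise ValueError("model must be 'linear' or 'lnp'")

    # a real-valued lag straddles two adjacent 30-degree windows, splitting
    # its coefficient mass; score anchors by the best circular adjacent-pair
    # sum rather than the single largest column
    C = np.zeros((space.n_anchors, space.n_lags))
    for ci, (ai, lj) in enumerate(cols):
        C[ai, lj] = coef[ci]
    pair = np.clip(C, 0, None) + np.roll(np.clip(C, 0, None), -1, axis=1)
    a, li = np.unravel_index(np.argmax(pair), pair.shape)
    # report the stronger column of the winning pair
    if C[a, (li + 1) % space.n_lags] > C[a, li]:
        li = (li + 1) % space.n_lags
    a, li = int(a), int(li)
    g, loc = space.anchor(a)
    order = np.argsort(coef)[::-1][:3]
    top3 = np.array([space.lag_deg(cols[i][1]) for i in order])
    if y_te.std() > 0 and np.std(pred) > 0:
        pc = float(stats.pearsonr(pred, y_te)[0])
    else:
        pc = float("nan")
    return LagRegressionFit(coef=coef, columns=cols, top_anchor_index=int(a),
                            top_anchor_gp=g, top_anchor_loc=loc,
                            top_lag_deg=space.lag_deg(li), top3_lags_deg=top3,
                            pred_corr=pc, n_columns=len(cols))


def fit_lag_regression_lnp(task_data, test_idx: int, preferred_gp: int,
                           space: AnchorSpace | None = None,
                           alpha: float = 1.0) -> LagRegressionFit:
    """Linear-nonlinear-Poisson variant of Method 3 (logarithmic link)."""
    return fit_lag_regression(task_data, test_idx, preferred_gp, space=space,
                              alpha=alpha, model="lnp")


def nonzero_lag_prediction(fit: LagRegressionFit, task_data, test_idx: int,
                           preferred_gp: int, min_lag_deg: float = 30.0,
                           space: AnchorSpace | None = None,
                           designs: list[np.ndarray] | None = None) -> float:
    """Predicted-vs-actual correlation using only coefficients at lags at
    least ``min_lag_deg`` away (on either side) from every anchor; applies to
    neurons whose top-3 coefficients all sit at such non-zero lags."""
    space = space or AnchorSpace(periodicity=task_data[0][0].periodicity)
    if designs is None:
        designs = [build_lag_design(bs, space) for _, bs in task_data]
    lagd = np.array([space.lag_deg(li) for a, li in fit.columns])
    keep = np.minimum(lagd, 360.0 - lagd) >= min_lag_deg
    act, bs = task_data[test_idx]
    sel = bs.flat("gp3") == preferred_gp
    pred = designs[test_idx][sel][:, keep] @ fit.coef[keep]
    y = act.matrix.reshape(-1)[sel]
    if pred.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(pred, y)[0])
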