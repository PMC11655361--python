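"""State tuning, cross-task rotation (generalization), pairwise coherence and
coherence clustering.

A neuron's cross-task angle is the rotation (10-degree grid) of its tuning
curve in one task that maximizes the Pearson correlation with its curve in a
reference task; pairs of neurons are *coherent* when their pairwise angle
changes by at most 45 degrees across all task comparisons. Because the
45-degree window covers one quarter of the rotation circle, the chance level
for generalization/coherence is (1/4)^m over m comparisons.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from statsmodels.stats.proportion import proportions_ztest

from ._circ import signed_deg
from .task_space import TaskAlignedActivity


# ---------------------------------------------------------------------------
# state tuning
# ---------------------------------------------------------------------------

@dataclass
class StateTuningResult:
    peak_matrix: np.ndarray      # (n_trials, periodicity) per-state peak rates
    z_matrix: np.ndarray         # row-z-scored (constant rows dropped)
    preferred_state: int
    p_value: float
    tuned_05: bool
    tuned_01: bool


def state_tuning(act: TaskAlignedActivity) -> StateTuningResult:
    """Peak-rate z-scoring test of state preference within one task.

    Each trial's per-state peak rates are z-scored across states and the
    preferred state's z-scores are t-tested against zero across trials. The
    preferred state is selected on the odd trials and tested on the even
    trials: selecting and testing on the same trials would inflate the
    false-positive rate well above the nominal level (the argmax of four
    zero-mean averages is positively biased).
    """
    if act.n_trials < 5:
        raise ValueError("state tuning needs >= 5 trials")
    p = act.periodicity
    B = act.cfg.bins_per_state
    peaks = act.matrix.reshape(act.n_trials, p, B).max(axis=2)
    sd = peaks.std(axis=1)
    keep = sd > 0
    z = (peaks[keep] - peaks[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    if len(z) < 5:
        return StateTuningResult(peaks, z, 0, 1.0, False, False)
    select = z[0::2]
    test = z[1::2]
    preferred = int(np.argmax(select.mean(axis=0)))
    _, pv = stats.ttest_1samp(test[:, preferred], 0.0)
    tuned = bool(pv < 0.05 and test[:, preferred].mean() > 0)
    strict = bool(pv < 0.01 and test[:, preferred].mean() > 0)
    return StateTuningResult(peak_matrix=peaks, z_matrix=z,
                             preferred_state=preferred, p_value=float(pv),
                             tuned_05=tuned, tuned_01=strict)


def robust_state_tuned(results: list[StateTuningResult],
                       fraction: float = 1.0 / 3.0, strict: bool = False) -> bool:
    """Tuned in more than ``fraction`` of the recorded tasks."""
    flags = [(r.tuned_01 if strict else r.tuned_05) for r in results]
    return sum(flags) > fraction * len(flags)


# ---------------------------------------------------------------------------
# best rotation
# ---------------------------------------------------------------------------

@dataclass
class RotationResult:
    angle_deg: float             # grid angle in [0, 360)
    correlation: float
    correlations: np.ndarray     # one per grid rotation
    grid_deg: np.ndarray


def _circular_corr_all_shifts(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Pearson correlation of ref with other rotated by every bin shift.

    Rotation by r bins moves other's bin i to bin i + r; computed for all
    shifts at once via the cross-power spectrum.
    """
    B = ref.shape[-1]
    rz = ref - ref.mean(axis=-1, keepdims=True)
    oz = other - other.mean(axis=-1, keepdims=True)
    denom = np.sqrt((rz ** 2).sum(axis=-1) * (oz ** 2).sum(axis=-1))
    cross = np.fft.irfft(np.fft.rfft(rz, axis=-1)
                         * np.conj(np.fft.rfft(oz, axis=-1)), n=B, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return cross / denom[..., None]


def best_rotation(curve_ref: np.ndarray, curve_other: np.ndarray,
                  step_deg: float = 10.0) -> RotationResult:
    """Exhaustive grid search for the rotation of ``curve_other`` that
    maximizes its correlation with ``curve_ref``.

    Ties are broken by the smallest absolute (signed) angle. Returns NaN
    angle for zero-variance curves.
    """
    ref = np.asarray(curve_ref, float)
    oth = np.asarray(curve_other, float)
    B = len(ref)
    if ref.std() == 0 or oth.std() == 0:
        return RotationResult(float("nan"), float("nan"),
                              np.full(1, np.nan), np.zeros(1))
    bin_deg = 360.0 / B
    shifts = np.unique(np.round(np.arange(0.0, 360.0, step_deg) / bin_deg)
                       .astype(int) % B)
    corr_all = _circular_corr_all_shifts(ref, oth)
    corrs = corr_all[shifts]
    grid = shifts * bin_deg
    best = np.flatnonzero(corrs == corrs.max())
    winner = best[np.argmin(np.abs(signed_deg(grid[best])))]
    return RotationResult(angle_deg=float(grid[winner]),
                          correlation=float(corrs[winner]),
                          correlations=corrs, grid_deg=grid)


def rotation_angles_batch(refs: np.ndarray, others: np.ndarray,
                          step_deg: float = 10.0) -> np.ndarray:
    """Vectorized best-rotation angles for stacks of curve pairs (N, B)."""
    refs = np.atleast_2d(refs)
    others = np.atleast_2d(others)
    B = refs.shape[1]
    bin_deg = 360.0 / B
    shifts = np.unique(np.round(np.arange(0.0, 360.0, step_deg) / bin_deg)
                       .astype(int) % B)
    corr = _circular_corr_all_shifts(refs, others)[:, shifts]
    grid = shifts * bin_deg
    # ties -> smallest |signed angle|: sort grid by |signed| and take argmax
    order = np.argsort(np.abs(signed_deg(grid)), kind="stable")
    corr_sorted = corr[:, order]
    idx = np.argmax(corr_sorted, axis=1)
    angles = grid[order][idx]
    bad = ~np.isfinite(corr).any(axis=1)
    angles = angles.astype(float)
    angles[bad] = np.nan
    return angles


def peak_to_peak_angle(curve_ref: np.ndarray, curve_other: np.ndarray) -> float:
    """Circular difference of argmax bins (the alternative angle measure)."""
    B = len(curve_ref)
    return float(((np.argmax(curve_other) - np.argmax(curve_ref)) * 360.0 / B)
                 % 360.0)


def concordant_remapping(curves: np.ndarray, window_deg: float = 45.0,
                         step_deg: float = 10.0) -> np.ndarray:
    """Neurons whose best-rotation and peak-to-peak angles agree within
    ``window_deg`` in every cross-task comparison.

    The best-rotation measure uses the whole curve shape and is robust to
    multi-peaked cells; restricting analyses to concordant neurons replicates
    results without that robustness argument.
    """
    n, n_tasks, B = curves.shape
    ok = np.ones(n, bool)
    for k in range(1, n_tasks):
        rot = rotation_angles_batch(curves[:, 0], curves[:, k], step_deg)
        p2p = np.array([peak_to_peak_angle(curves[i, 0], curves[i, k])
                        for i in range(n)])
        ok &= np.abs(signed_deg(rot - p2p)) <= window_deg
    return ok


# ---------------------------------------------------------------------------
# generalization and coherence
# ---------------------------------------------------------------------------

@dataclass
class GeneralizationSummary:
    angles: np.ndarray           # (n_neurons, n_comparisons) grid angles
    generalizing: np.ndarray     # (n_neurons,) bool
    proportion: float
    chance: float
    z_stat: float
    p_value: float


def _vs_chance(flags: np.ndarray, chance: float):
    n = len(flags)
    if n == 0:
        return float("nan"), float("nan"), float("nan")
    prop = float(np.mean(flags))
    z, p = proportions_ztest(count=int(flags.sum()), nobs=n, value=chance)
    return prop, float(z), float(p)


def generalization_histogram(curves: np.ndarray, window_deg: float = 45.0,
                             step_deg: float = 10.0) -> GeneralizationSummary:
    """Single-neuron state-tuning generalization across tasks.

    ``curves``: (n_neurons, n_tasks, n_bins) smoothed mean curves; the first
    task is the reference, every later task contributes one comparison. A
    neuron generalizes when its best-rotation angle stays within
    ``window_deg`` of zero (inclusive) in all comparisons; chance is
    (1/4)^m for m comparisons.
    """
    n, n_tasks, B = curves.shape
    m = n_tasks - 1
    angles = np.column_stack([
        rotation_angles_batch(curves[:, 0], curves[:, k], step_deg)
        for k in range(1, n_tasks)])
    gen = (np.abs(signed_deg(angles)) <= window_deg).all(axis=1)
    gen &= np.isfinite(angles).all(axis=1)
    chance = 0.25 ** m
    prop, z, p = _vs_chance(gen, chance)
    return GeneralizationSummary(angles=angles, generalizing=gen,
                                 proportion=prop, chance=chance,
                                 z_stat=z, p_value=p)


@dataclass
class CoherenceSummary:
    pair_index: np.ndarray       # (n_pairs, 2) neuron indices
    pair_angles: np.ndarray      # (n_pairs, n_tasks) between-neuron angles
    max_change: np.ndarray       # (n_pairs,) max |angle change| across comparisons
    coherent: np.ndarray
    proportion: float
    chance: float
    z_stat: float
    p_value: float


def coherence_analysis(curves: np.ndarray, window_deg: float = 45.0,
                       step_deg: float = 10.0,
                       pairs: np.ndarray | None = None) -> CoherenceSummary:
    """Pairwise coherence of state remapping across tasks.

    For every simultaneously recorded pair the between-neuron rotation angle
    is computed per task; the pair is coherent when that angle changes by at
    most ``window_deg`` (relative to the reference task) in every comparison.
    """
    n, n_tasks, B = curves.shape
    if pairs is None:
        pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    pair_angles = np.column_stack([
        rotation_angles_batch(curves[pairs[:, 0], t], curves[pairs[:, 1], t],
                              step_deg)
        for t in range(n_tasks)])
    change = signed_deg(pair_angles[:, 1:] - pair_angles[:, [0]])
    max_change = np.abs(change).max(axis=1)
    coherent = (max_change <= window_deg) & np.isfinite(pair_angles).all(axis=1)
    chance = 0.25 ** (n_tasks - 1)
    prop, z, p = _vs_chance(coherent, chance)
    return CoherenceSummary(pair_index=pairs, pair_angles=pair_angles,
                            max_change=max_change, coherent=coherent,
                            proportion=prop, chance=chance, z_stat=z,
                            p_value=p)


# ---------------------------------------------------------------------------
# coherence clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterQuality:
    labels: np.ndarray
    embedding: np.ndarray
    silhouette: float
    n_clusters: int


def _incoherence_matrix(curves: np.ndarray, step_deg: float = 10.0) -> np.ndarray:
    """Pairwise incoherence 1 - cos(max angle change), in [0, 2]."""
    n, n_tasks, B = curves.shape
    pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    summ = coherence_analysis(curves, step_deg=step_deg, pairs=pairs)
    D = np.zeros((n, n))
    vals = 1.0 - np.cos(np.radians(summ.max_change))
    D[pairs[:, 0], pairs[:, 1]] = vals
    D[pairs[:, 1], pairs[:, 0]] = vals
    return D


def cluster_day(curves: np.ndarray, seed: int = 0, perplexity: float = 5.0,
                distance_threshold: float = 300.0,
                step_deg: float = 10.0) -> ClusterQuality:
    """Embed the incoherence matrix (t-SNE) and cluster it (agglomerative,
    fixed distance threshold); silhouette is computed in the embedding."""
    n = curves.shape[0]
    if n < 10:
        raise ValueError("need >= 10 robust state-tuned neurons in the day")
    D = _incoherence_matrix(curves, step_deg)
    emb = TSNE(n_components=2, perplexity=min(perplexity, (n - 1) / 3.0),
               metric="precomputed", init="random",
               random_state=seed).fit_transform(D)
    labels = AgglomerativeClustering(
        n_clusters=None, distance_threshold=distance_threshold).fit_predict(emb)
    k = len(np.unique(labels))
    if k < 2 or k >= n:
        sil = float("nan")
    else:
        sil = float(silhouette_score(emb, labels))
    return ClusterQuality(labels=labels, embedding=emb, silhouette=sil,
                          n_clusters=k)


def permuted_remapping(curves: np.ndarray, rng) -> np.ndarray:
    """Null for the clustering: keep each neuron's reference-task tuning and
    goal-progress phase, but remap randomly (independent whole-state
    rotations of the later tasks' curves)."""
    n, n_tasks, B = curves.shape
    out = curves.copy()
    p_states = 4 if B % 4 == 0 else 5
    state_bins = B // p_states
    for i in range(n):
        for t in range(1, n_tasks):
            k = int(rng.integers(p_states))
            out[i, t] = np.roll(curves[i, t], k * state_bins)
    return out


def coherence_clustering(curves: np.ndarray, seed: int = 0,
                         step_deg: float = 10.0,
                         distance_threshold: float = 300.0,
                         ) -> tuple[ClusterQuality, ClusterQuality]:
    """Real-vs-permuted cluster quality for one recording day.

    The permuted control keeps each neuron's reference-task state preference
    and goal-progress tuning but randomizes its remapping across tasks.
    """
    rng = np.random.default_rng(seed)
    real = cluster_day(curves, seed=seed, step_deg=step_deg,
                       distance_threshold=distance_threshold)
    null = cluster_day(permuted_remapping(curves, rng), seed=seed + 1,
                       step_deg=step_deg,
                       distance_threshold=distance_threshold)
    return real, null
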