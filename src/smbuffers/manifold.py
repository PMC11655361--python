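"""Low-dimensional embedding of within-task population activity and the
goal-progress/state distance contrast.

The embedding input stacks every neuron-task z-scored mean tuning curve as a
feature; the embedded points are the task-position bins (360 for a 4-state
task). The bespoke content is the input construction and the distance
contrast (bins in different states are closer when they share a goal-progress
bin); the embedding itself is delegated to UMAP with the standard parameters
(3 output dimensions, cosine metric, 50 neighbours, min_dist 0.6).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task_space import TaskAlignedActivity


@dataclass(frozen=True)
class ManifoldConfig:
    n_components: int = 3
    metric: str = "cosine"
    n_neighbors: int = 50
    min_dist: float = 0.6
    min_neurons: int = 10
    min_tasks: int = 6


def stack_day_curves(acts_by_task: list[list[TaskAlignedActivity]],
                     shuffle_states_seed: int | None = None) -> np.ndarray:
    """(n_neuron_tasks, n_bins) z-scored mean curves for one recording day.

    ``acts_by_task[t][i]`` is neuron i's activity in task t. With
    ``shuffle_states_seed`` set, state identity is shuffled across trials
    before averaging (the floor control that destroys systematic state
    tuning while preserving goal-progress structure).
    """
    rng = (np.random.default_rng(shuffle_states_seed)
           if shuffle_states_seed is not None else None)
    rows = []
    for acts in acts_by_task:
        for act in acts:
            m = act.matrix
            if rng is not None:
                p = act.periodicity
                B = act.cfg.bins_per_state
                blocks = m.reshape(act.n_trials, p, B).copy()
                for tr in range(act.n_trials):
                    blocks[tr] = blocks[tr][rng.permutation(p)]
                m = blocks.reshape(act.n_trials, p * B)
            curve = m.mean(axis=0)
            sd = curve.std()
            rows.append((curve - curve.mean()) / (sd if sd > 0 else 1.0))
    return np.asarray(rows)


def embed_task_manifold(day_curves: np.ndarray, seed: int = 0,
                        cfg: ManifoldConfig | None = None) -> np.ndarray:
    """Embed the task-position bins of one day into 3-D.

    ``day_curves`` is (n_neuron_tasks, n_bins); the embedded samples are the
    n_bins columns. Coordinates are only meaningful up to rotation -
    downstream analyses use distances only. Deterministic under ``seed``.
    """
    import umap

    cfg = cfg or ManifoldConfig()
    if day_curves.shape[0] < cfg.min_neurons:
        raise ValueError(
            f"too few neuron-task rows ({day_curves.shape[0]}) for embedding")
    reducer = umap.UMAP(n_components=cfg.n_components, metric=cfg.metric,
                        n_neighbors=cfg.n_neighbors, min_dist=cfg.min_dist,
                        random_state=seed)
    return np.asarray(reducer.fit_transform(day_curves.T))


def bin_labels(n_bins: int, periodicity: int, gp_bins: int = 3):
    """(state, goal-progress bin) label per task-position bin."""
    B = n_bins // periodicity
    state = np.arange(n_bins) // B
    gp = (np.arange(n_bins) % B) // (B // gp_bins)
    return state, gp


def manifold_distance_contrast(embedding: np.ndarray, periodicity: int,
                               gp_bins: int = 3) -> dict[str, float]:
    """Mean 3-D distances between bins of different states that share the
    same goal-progress bin (within_gp) versus lie in different goal-progress
    bins (across_gp)."""
    n_bins = embedding.shape[0]
    state, gp = bin_labels(n_bins, periodicity, gp_bins)
    diff = embedding[:, None, :] - embedding[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    ds = state[:, None] != state[None, :]
    same_gp = gp[:, None] == gp[None, :]
    iu = np.triu_indices(n_bins, 1)
    mask_within = (ds & same_gp)[iu]
    mask_across = (ds & ~same_gp)[iu]
    d = dist[iu]
    return {"within_gp": float(d[mask_within].mean()),
            "across_gp": float(d[mask_across].mean())}


def distance_contrast_with_shuffle(acts_by_task, seed: int = 0,
                                   cfg: ManifoldConfig | None = None,
                                   ) -> dict[str, float]:
    """Full contrast for one day: embed the real data and the trial-state
    shuffled control (re-embedded with the same seed), returning mean
    across-gp, within-gp and shuffled (within-gp, state destroyed) distances.
    """
    cfg = cfg or ManifoldConfig()
    p = acts_by_task[0][0].periodicity
    real = stack_day_curves(acts_by_task)
    emb = embed_task_manifold(real, seed=seed, cfg=cfg)
    out = manifold_distance_contrast(emb, p)
    shuf = stack_day_curves(acts_by_task, shuffle_states_seed=seed + 1)
    emb_s = embed_task_manifold(shuf, seed=seed, cfg=cfg)
    out["shuffled"] = manifold_distance_contrast(emb_s, p)["within_gp"]
    return out
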