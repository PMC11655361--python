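"""Offline (sleep/rest) coactivity structure: ring versus delay line.

Pairwise coactivity is the zero-lag Pearson correlation of 250-ms binned
spike counts. For co-anchored neurons with lags on the task loop, a ring-like
internal organization predicts coactivity falling with *circular* lag
distance (V-shaped against forward distance), whereas a delay line predicts a
monotone fall with *forward* distance. A linear regression separates the two
while controlling for goal-progress-tuning distance and awake spatial-map
similarity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._circ import circ_dist_deg


def sleep_crosscorr(spikes: pd.DataFrame, bin_s: float = 0.25,
                    min_duration_s: float = 0.0) -> pd.DataFrame:
    """Zero-lag Pearson correlation of binned spike counts for every neuron
    pair; silent neurons are excluded. Returns a long-format pair table
    (neuron_i < neuron_j, corr)."""
    t0, t1 = spikes["time_s"].min(), spikes["time_s"].max()
    if t1 - t0 < min_duration_s:
        raise ValueError("session shorter than the required minimum")
    edges = np.arange(t0, t1 + bin_s, bin_s)
    ids = np.sort(spikes["neuron_id"].unique())
    counts = np.stack([
        np.histogram(spikes.loc[spikes["neuron_id"] == nid, "time_s"],
                     bins=edges)[0] for nid in ids])
    active = counts.sum(axis=1) > 0
    ids, counts = ids[active], counts[active]
    if len(ids) < 2:
        raise ValueError("fewer than 2 active neurons")
    C = np.corrcoef(counts)
    rows = [dict(neuron_i=int(ids[i]), neuron_j=int(ids[j]),
                 corr=float(C[i, j]))
            for i in range(len(ids)) for j in range(i + 1, len(ids))]
    return pd.DataFrame(rows)


def pair_metadata(lags_deg: dict[int, float],
                  anchors: dict[int, int] | None = None,
                  gp_phase_deg: dict[int, float] | None = None,
                  spatial_maps: dict[int, np.ndarray] | None = None,
                  ) -> pd.DataFrame:
    """Per-pair state-space geometry: forward distance (|lag_j - lag_i|),
    circular distance (wrapped to [0, 180]), same-anchor flag and optional
    goal-progress distance / awake spatial-map correlation."""
    ids = sorted(lags_deg)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            fwd = abs(lags_deg[b] - lags_deg[a]) % 360.0
            row = dict(neuron_i=a, neuron_j=b, fwd_dist=fwd,
                       circ_dist=float(circ_dist_deg(fwd)))
            if anchors is not None:
                row["same_anchor"] = anchors[a] == anchors[b]
            if gp_phase_deg is not None:
                row["gp_dist"] = float(circ_dist_deg(
                    gp_phase_deg[a] - gp_phase_deg[b]))
            if spatial_maps is not None:
                ma, mb = spatial_maps[a], spatial_maps[b]
                ok = np.isfinite(ma) & np.isfinite(mb)
                row["spatial_corr"] = (
                    float(stats.pearsonr(ma[ok], mb[ok])[0])
                    if ok.sum() >= 3 and ma[ok].std() > 0 and mb[ok].std() > 0
                    else 0.0)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StateSpaceRegression:
    params: pd.Series
    bse: pd.Series
    n_pairs: int
    collinear: bool

    @property
    def circular_coef(self) -> float:
        return float(self.params.get("circ_dist", np.nan))

    @property
    def forward_coef(self) -> float:
        return float(self.params.get("fwd_dist", np.nan))


def state_space_regression(pairs: pd.DataFrame,
                           regressors: tuple[str, ...] = (
                               "circ_dist", "fwd_dist", "gp_dist",
                               "spatial_corr"),
                           min_pairs: int = 10) -> StateSpaceRegression:
    """OLS of sleep coactivity on circular distance, forward distance and the
    control regressors, with analytic standard errors."""
    cols = [c for c in regressors if c in pairs.columns]
    tab = pairs.dropna(subset=["corr", *cols])
    if len(tab) < min_pairs:
        raise ValueError(f"fewer than {min_pairs} usable pairs")
    X = sm.add_constant(tab[cols].to_numpy(), has_constant="add")
    collinear = np.linalg.matrix_rank(X) < X.shape[1]
    res = sm.OLS(tab["corr"].to_numpy(), X).fit()
    names = ["const", *cols]
    return StateSpaceRegression(params=pd.Series(res.params, index=names),
                                bse=pd.Series(res.bse, index=names),
                                n_pairs=len(tab), collinear=bool(collinear))


def compare_subsets(within: StateSpaceRegression,
                    between: StateSpaceRegression,
                    coef: str = "circ_dist") -> tuple[float, float]:
    """Welch-style comparison of one coefficient between the within-anchor
    and between-anchor regressions, using the analytic standard errors.
    Returns (z, one-sided p for within < between)."""
    d = within.params[coef] - between.params[coef]
    se = float(np.hypot(within.bse[coef], between.bse[coef]))
    z = d / se
    return float(z), float(stats.norm.cdf(z))


@dataclass
class VCurveResult:
    r_low: float    # corr(coactivity, fwd) on [0, 180)
    r_high: float   # corr(coactivity, fwd) on [180, 360)
    topology: str   # "ring" if the high half rises, else "delay_line"


def v_curve(pairs: pd.DataFrame, split_deg: float = 180.0) -> VCurveResult:
    """Coactivity against forward distance in the two halves of the loop.

    A ring yields a V (negative then positive correlation); a delay line
    falls monotonically (negative in both halves).
    """
    lo = pairs[pairs["fwd_dist"] < split_deg].dropna(subset=["corr"])
    hi = pairs[pairs["fwd_dist"] >= split_deg].dropna(subset=["corr"])
    if len(lo) < 3 or len(hi) < 3:
        raise ValueError("need pairs in both forward-distance halves")
    r_low = float(stats.pearsonr(lo["fwd_dist"], lo["corr"])[0])
    r_high = float(stats.pearsonr(hi["fwd_dist"], hi["corr"])[0])
    topology = "ring" if (r_low < 0 and r_high > 0) else "delay_line"
    return VCurveResult(r_low=r_low, r_high=r_high, topology=topology)


def v_curve_session_tests(per_session: list[VCurveResult]):
    """Population t-tests of the two half-slopes against zero and their
    paired difference across sessions."""
    lo = np.array([v.r_low for v in per_session])
    hi = np.array([v.r_high for v in per_session])
    t_lo, p_lo = stats.ttest_1samp(lo, 0.0)
    t_hi, p_hi = stats.ttest_1samp(hi, 0.0)
    t_d, p_d = stats.ttest_rel(lo, hi)
    return {"low": (float(t_lo), float(p_lo)),
            "high": (float(t_hi), float(p_hi)),
            "paired": (float(t_d), float(p_d))}


def sleep_epoch_contrast(epochs: dict[str, pd.DataFrame],
                         **kwargs) -> pd.DataFrame:
    """Same state-space regression per labelled epoch (e.g. pre/post task)
    with pairwise coefficient-difference z statistics."""
    if len(epochs) < 2:
        raise ValueError("need at least 2 epochs")
    fits = {name: state_space_regression(tab, **kwargs)
            for name, tab in epochs.items()}
    names = list(fits)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for coef in ("circ_dist", "fwd_dist", "spatial_corr"):
                if coef in fits[a].params and coef in fits[b].params:
                    d = fits[a].params[coef] - fits[b].params[coef]
                    se = float(np.hypot(fits[a].bse[coef], fits[b].bse[coef]))
                    rows.append(dict(epoch_a=a, epoch_b=b, coef=coef,
                                     diff=float(d), z=float(d / se),
                                     p=float(2 * stats.norm.sf(abs(d / se)))))
    return pd.DataFrame(rows)
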