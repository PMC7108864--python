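"""Cortical-state tracking and its relation to collective activity.

Cortical state per epoch is indexed by silence density CS(t): the fraction of
20-ms bins, within the epoch's spontaneous windows, in which the merged
population (single units and multi-units) fired no spike.  High CS marks the
synchronized (up/down alternating) state, low CS the desynchronized state.
This module also provides epoch-to-epoch similarity measures for observables,
parameters and pattern distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mem import js_divergence
from .spike_io import SpikeDataset, EpochWindows, binarize

logger = logging.getLogger(__name__)

__all__ = [
    "silence_density",
    "pairwise_pattern_divergence",
    "state_divergence_correlation",
    "observable_timeseries",
    "state_observable_correlation",
    "sensitivity_state_relation",
    "similarity_gamma",
    "lagged_model_fit",
]


def silence_density(
    dataset: SpikeDataset,
    epoch_windows: EpochWindows,
    bin_width: float = 0.020,
    units=None,
) -> np.ndarray:
    """Silence density CS(t) per epoch: fraction of empty ``bin_width`` bins
    within the epoch's spontaneous windows, merging spikes of all units
    (single + multi by default).  Epochs with no windows yield NaN."""
    if units is None:
        units = dataset.unit_ids
    sel = dataset.spikes["unit_id"].isin(np.asarray(units))
    t = np.sort(dataset.spikes.loc[sel, "time_s"].to_numpy())
    cs = np.full(epoch_windows.n_epochs, np.nan)
    for e, wins in enumerate(epoch_windows.windows):
        empty = total = 0
        for w0, w1 in wins:
            nbins = int(round((w1 - w0) / bin_width))
            lo = np.searchsorted(t, w0, side="left")
            hi = np.searchsorted(t, w1, side="left")
            idx = np.floor((t[lo:hi] - w0) / bin_width + 1e-9).astype(int)
            idx = idx[idx < nbins]
            occupied = np.unique(idx).size
            empty += nbins - occupied
            total += nbins
        if total:
            cs[e] = empty / total
    return cs


def pairwise_pattern_divergence(dists_per_ensemble: list[list]) -> np.ndarray:
    """Matrix DJS(t, t') between empirical pattern distributions of epochs,
    averaged over ensembles.  Symmetric with zero diagonal."""
    n_epochs = len(dists_per_ensemble[0])
    out = np.zeros((n_epochs, n_epochs))
    for t in range(n_epochs):
        for u in range(t + 1, n_epochs):
            vals = [js_divergence(d[t], d[u]) for d in dists_per_ensemble]
            out[t, u] = out[u, t] = float(np.mean(vals))
    return out


def state_divergence_correlation(
    djs: np.ndarray,
    cs: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    n_bins: int = 8,
) -> dict:
    """Correlation between pattern-distribution divergence DJS(t,t') and
    cortical-state change d = |CS(t) - CS(t')| across epoch pairs.

    Returns rc (Pearson over the upper triangle), a permutation p-value
    (epoch labels of CS permuted), and a binned mean curve of DJS vs d.
    rc is NaN when CS is constant (d identically 0)."""
    djs = np.asarray(djs)
    cs = np.asarray(cs, dtype=np.float64)
    iu, ju = np.triu_indices(len(cs), k=1)
    d = np.abs(cs[iu] - cs[ju])
    y = djs[iu, ju]
    ok = ~np.isnan(d) & ~np.isnan(y)
    d, y, iu, ju = d[ok], y[ok], iu[ok], ju[ok]
    if d.size < 2 or np.ptp(d) == 0:
        logger.warning("cortical state constant; DJS-state correlation undefined")
        return {"rc": np.nan, "p": np.nan, "curve": pd.DataFrame()}
    rc = float(stats.pearsonr(d, y)[0])
    rng = np.random.default_rng(seed)
    count = 0
    valid_epochs = np.unique(np.concatenate([iu, ju]))
    for _ in range(n_perm):
        perm = rng.permutation(valid_epochs)
        remap = dict(zip(valid_epochs, perm))
        dp = np.abs(cs[[remap[i] for i in iu]] - cs[[remap[j] for j in ju]])
        if np.ptp(dp) == 0:
            continue
        if abs(stats.pearsonr(dp, y)[0]) >= abs(rc):
            count += 1
    p = (1 + count) / (n_perm + 1)
    edges = np.linspace(d.min(), d.max(), n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    curve = pd.DataFrame(
        {
            "d_mid": 0.5 * (edges[:-1] + edges[1:]),
            "mean_djs": [
                y[which == b].mean() if (which == b).any() else np.nan
                for b in range(n_bins)
            ],
            "n_pairs": [(which == b).sum() for b in range(n_bins)],
        }
    )
    return {"rc": rc, "p": p, "curve": curve}


def observable_timeseries(
    dataset: SpikeDataset,
    epoch_windows: EpochWindows,
    unit_ids=None,
    dt: float = 0.010,
) -> dict:
    """Per-epoch firing rates (Hz) and pairwise Pearson correlations of the
    +/-1 binarized trains of single units, over spontaneous windows.

    Returns {"rates": (NE, n_units), "correlations": (NE, n_pairs),
    "unit_ids", "pairs"}; undefined correlations (constant trains) are NaN.
    """
    if unit_ids is None:
        unit_ids = dataset.single_unit_ids
    unit_ids = np.asarray(unit_ids)
    n = unit_ids.size
    iu, ju = np.triu_indices(n, k=1)
    rates = np.full((epoch_windows.n_epochs, n), np.nan)
    corrs = np.full((epoch_windows.n_epochs, iu.size), np.nan)
    for e, wins in enumerate(epoch_windows.windows):
        if not wins:
            continue
        raster = binarize(dataset, wins, dt=dt, units=unit_ids)
        V = raster.values.astype(np.float64)
        spont_s = raster.n_bins * dt
        rates[e] = (V > 0).sum(axis=1) / spont_s
        sd = V.std(axis=1)
        good = sd > 0
        if good.sum() < n:
            logger.warning(
                "epoch %d: %d constant unit(s); their correlations are NaN",
                e,
                int(n - good.sum()),
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(V)
        C[~good, :] = np.nan
        C[:, ~good] = np.nan
        corrs[e] = C[iu, ju]
    return {
        "rates": rates,
        "correlations": corrs,
        "unit_ids": unit_ids,
        "pairs": list(zip(unit_ids[iu], unit_ids[ju])),
    }


def state_observable_correlation(
    series: np.ndarray, cs: np.ndarray, min_epochs: int = 3
) -> np.ndarray:
    """Absolute Pearson correlation rcs between CS(t) and each observable
    column across epochs; NaN when fewer than ``min_epochs`` valid epochs."""
    series = np.asarray(series, dtype=np.float64)
    cs = np.asarray(cs, dtype=np.float64)
    out = np.full(series.shape[1], np.nan)
    for k in range(series.shape[1]):
        ok = ~np.isnan(series[:, k]) & ~np.isnan(cs)
        if ok.sum() < min_epochs:
            continue
        x = series[ok, k]
        if np.ptp(x) == 0 or np.ptp(cs[ok]) == 0:
            continue
        out[k] = abs(stats.pearsonr(x, cs[ok])[0])
    return out


def sensitivity_state_relation(
    rcs: np.ndarray,
    s: np.ndarray,
    labels: np.ndarray | None = None,
    per_ensemble_pairs: list[tuple[float, float]] | None = None,
) -> dict:
    """Relation between sensitivity s and state correlation rcs.

    Reports the Pearson correlation (with 95% CI and p) over covered
    elements, a Welch two-sample test of rcs for stiff vs sloppy elements,
    and, when per-ensemble (stiff mean, sloppy mean) pairs are supplied, a
    paired t-test across ensembles."""
    rcs = np.asarray(rcs, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    ok = ~np.isnan(rcs) & ~np.isnan(s)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 covered elements with defined rcs")
    res = stats.pearsonr(rcs[ok], s[ok])
    ci = res.confidence_interval(0.95)
    out = {
        "rc": float(res.statistic),
        "p": float(res.pvalue),
        "ci": (float(ci.low), float(ci.high)),
        "n": int(ok.sum()),
    }
    if labels is not None:
        labels = np.asarray(labels, dtype=object)
        stiff = rcs[ok & (labels == "stiff")]
        sloppy = rcs[ok & (labels == "sloppy")]
        if stiff.size >= 2 and sloppy.size >= 2:
            t = stats.ttest_ind(stiff, sloppy, equal_var=False)
            out["group_means"] = (float(np.mean(stiff)), float(np.mean(sloppy)))
            out["welch_t"] = float(t.statistic)
            out["welch_p"] = float(t.pvalue)
    if per_ensemble_pairs:
        a = np.array([p[0] for p in per_ensemble_pairs])
        b = np.array([p[1] for p in per_ensemble_pairs])
        if len(a) >= 2:
            t = stats.ttest_rel(a, b)
            out["paired_t"] = float(t.statistic)
            out["paired_p"] = float(t.pvalue)
    return out


def similarity_gamma(series: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Similarity gamma(dt) = mean over t of Pearson(series(t), series(t+dt)).

    ``series`` is (NE, D) with one row per epoch (FIMs should be vectorized
    beforehand).  gamma(0) = 1 by definition.  Lags with no valid epoch pair
    yield NaN."""
    series = np.asarray(series, dtype=np.float64)
    n_epochs = series.shape[0]
    if max_lag is None:
        max_lag = n_epochs - 1
    out = np.full(max_lag + 1, np.nan)
    for lag in range(max_lag + 1):
        vals = []
        for t in range(n_epochs - lag):
            a, b = series[t], series[t + lag]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < 3 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
                continue
            vals.append(stats.pearsonr(a[ok], b[ok])[0])
        if vals:
            out[lag] = float(np.mean(vals))
    return out


def lagged_model_fit(
    empirical_dists: list, model_dists: list, max_lag: int | None = None
) -> np.ndarray:
    """<DJS>(dt) = mean over t of DJS(P_data,t ; P_model,t+dt).

    At dt = 0 this is the within-epoch goodness-of-fit; growth with dt means
    the collective statistics drift so a model fitted later misses them."""
    n_epochs = len(empirical_dists)
    if len(model_dists) != n_epochs:
        raise ValueError("need one model distribution per epoch")
    if max_lag is None:
        max_lag = n_epochs - 1
    out = np.full(max_lag + 1, np.nan)
    for lag in range(max_lag + 1):
        vals = [
            js_divergence(empirical_dists[t], model_dists[t + lag])
            for t in range(n_epochs - lag)
        ]
        if vals:
            out[lag] = float(np.mean(vals))
    return out
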