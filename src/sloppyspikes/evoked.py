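"""Stimulus-response quantification and its relation to sensitivity.

Responsiveness of a unit is summarized by the modulation index

    MI = |r_stim - r_spon| / (r_stim + r_spon)

where r_spon is the mean spike count in the 0.5-s pre-stimulus interval and
r_stim the mean count from stimulus onset to 0.5 s after onset.  MI is 1 for
a response appearing from (or vanishing into) silence, 0 for no modulation,
and treats excitation and suppression symmetrically.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .spike_io import SpikeDataset, EpochWindows

logger = logging.getLogger(__name__)

__all__ = [
    "trial_counts",
    "modulation_index",
    "response_sign",
    "mi_sensitivity_relation",
    "mi_eigvec_correlation",
    "delta_mi_by_state",
    "normalized_psth",
]


def trial_counts(
    dataset: SpikeDataset,
    epoch_windows: EpochWindows,
    unit_ids=None,
    pre: float = 0.5,
    post: float = 0.5,
) -> dict:
    """Per-unit mean pre/post-stimulus spike counts, averaged within epochs.

    Counts are taken in [onset - pre, onset) and [onset, onset + post).
    Returns {"rspon", "rstim"}: arrays (NE, n_units); NaN for epochs with no
    events."""
    if unit_ids is None:
        unit_ids = dataset.single_unit_ids
    unit_ids = np.asarray(unit_ids)
    n_epochs = epoch_windows.n_epochs
    rspon = np.full((n_epochs, unit_ids.size), np.nan)
    rstim = np.full((n_epochs, unit_ids.size), np.nan)
    for u, uid in enumerate(unit_ids):
        t = np.sort(dataset.spike_times(uid))
        for e, events in enumerate(epoch_windows.events):
            if len(events) == 0:
                continue
            pre_counts = np.searchsorted(t, events) - np.searchsorted(t, events - pre)
            post_counts = np.searchsorted(t, events + post) - np.searchsorted(t, events)
            rspon[e, u] = pre_counts.mean()
            rstim[e, u] = post_counts.mean()
    return {"rspon": rspon, "rstim": rstim, "unit_ids": unit_ids}


def modulation_index(rspon, rstim) -> np.ndarray:
    """MI = |r_stim - r_spon| / (r_stim + r_spon); 0 where both are 0."""
    rspon = np.asarray(rspon, dtype=np.float64)
    rstim = np.asarray(rstim, dtype=np.float64)
    denom = rspon + rstim
    with np.errstate(invalid="ignore", divide="ignore"):
        mi = np.abs(rstim - rspon) / denom
    mi = np.where(denom == 0, 0.0, mi)
    return np.where(np.isnan(rspon) | np.isnan(rstim), np.nan, mi)


def response_sign(rspon, rstim) -> np.ndarray:
    """Session-pooled response sign per unit: excited / suppressed / null."""
    rspon = np.asarray(rspon, dtype=np.float64)
    rstim = np.asarray(rstim, dtype=np.float64)
    if rspon.ndim == 2:  # pool over epochs
        rspon = np.nanmean(rspon, axis=0)
        rstim = np.nanmean(rstim, axis=0)
    diff = rstim - rspon
    out = np.full(diff.shape, "null", dtype=object)
    out[diff > 0] = "excited"
    out[diff < 0] = "suppressed"
    return out


def mi_sensitivity_relation(mi_per_unit, s_units) -> dict:
    """Pearson correlation between session MI and unit-level sensitivity s."""
    mi = np.asarray(mi_per_unit, dtype=np.float64)
    s = np.asarray(s_units, dtype=np.float64)
    ok = ~np.isnan(mi) & ~np.isnan(s)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 units with defined MI and s")
    res = stats.pearsonr(mi[ok], s[ok])
    return {"rc": float(res.statistic), "p": float(res.pvalue), "n": int(ok.sum())}


def mi_eigvec_correlation(mi_epochs: np.ndarray, fims: list) -> dict:
    """Per-epoch correlation between the ensemble units' MI(t) and the
    absolute h-block components of the first FIM eigenvector.

    ``mi_epochs`` is (NE, N) for one ensemble.  Returns the correlation
    series and its median; aggregate medians across ensembles with
    :func:`sign_test_negative`."""
    mi_epochs = np.asarray(mi_epochs, dtype=np.float64)
    n_epochs, n = mi_epochs.shape
    series = np.full(n_epochs, np.nan)
    for t, f in enumerate(fims):
        v = np.abs(f.first_eigenvector()[:n])  # h-block only
        mi = mi_epochs[t]
        ok = ~np.isnan(mi)
        if ok.sum() < 3 or np.ptp(mi[ok]) == 0 or np.ptp(v[ok]) == 0:
            continue
        series[t] = stats.pearsonr(mi[ok], v[ok])[0]
    med = float(np.nanmedian(series)) if np.isfinite(series).any() else np.nan
    return {"series": series, "median": med}


def sign_test_negative(medians) -> float:
    """One-sided sign-test p that ensemble medians are negative."""
    m = np.asarray([v for v in medians if np.isfinite(v)])
    if m.size == 0:
        return float("nan")
    k = int((m < 0).sum())
    return float(stats.binomtest(k, m.size, 0.5, alternative="greater").pvalue)


def delta_mi_by_state(
    mi_epochs: np.ndarray,
    labels: np.ndarray,
    cs: np.ndarray,
    n_bins: int = 8,
    min_epochs: int = 3,
) -> pd.DataFrame:
    """Difference in MI between sloppy and stiff units by cortical-state bin.

    For each of ``n_bins`` equal-width bins over the observed CS range,
    epochs falling in the bin contribute mean MI of sloppy units minus mean
    MI of stiff units; bins with fewer than ``min_epochs`` epochs are
    dropped."""
    mi_epochs = np.asarray(mi_epochs, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    cs = np.asarray(cs, dtype=np.float64)
    sloppy = labels == "sloppy"
    stiff = labels == "stiff"
    if not sloppy.any() or not stiff.any():
        raise ValueError("need both sloppy and stiff units")
    ok = ~np.isnan(cs) & ~np.isnan(mi_epochs).all(axis=1)
    lo, hi = np.nanmin(cs[ok]), np.nanmax(cs[ok])
    edges = np.linspace(lo, hi, n_bins + 1)
    rows = []
    which = np.clip(np.digitize(cs, edges) - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = ok & (which == b)
        if sel.sum() < min_epochs:
            continue
        d = np.nanmean(mi_epochs[np.ix_(sel, sloppy)]) - np.nanmean(
            mi_epochs[np.ix_(sel, stiff)]
        )
        rows.append(
            {
                "cs_mid": 0.5 * (edges[b] + edges[b + 1]),
                "delta_mi": float(d),
                "n_epochs": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def normalized_psth(
    dataset: SpikeDataset,
    events: np.ndarray,
    unit_ids=None,
    window: tuple[float, float] = (-0.5, 0.5),
    dt: float = 0.010,
) -> dict:
    """Trial-averaged peri-stimulus rate per unit, normalized by the mean
    pre-stimulus rate r0.  Units with r0 = 0 are excluded with a warning."""
    if unit_ids is None:
        unit_ids = dataset.single_unit_ids
    unit_ids = np.asarray(unit_ids)
    events = np.asarray(events, dtype=np.float64)
    lo, hi = window
    edges = np.arange(lo, hi + dt / 2, dt)
    n_bins = edges.size - 1
    times = 0.5 * (edges[:-1] + edges[1:])
    curves = np.full((unit_ids.size, n_bins), np.nan)
    kept = []
    for u, uid in enumerate(unit_ids):
        t = np.sort(dataset.spike_times(uid))
        counts = np.zeros(n_bins)
        for e in events:
            rel = t[(t >= e + lo) & (t < e + hi)] - e
            idx = np.clip(np.floor((rel - lo) / dt + 1e-9).astype(int), 0, n_bins - 1)
            np.add.at(counts, idx, 1)
        rate = counts / (len(events) * dt)
        r0 = rate[times < 0].mean()
        if r0 == 0:
            logger.warning("unit %s has zero pre-stimulus rate; excluded", uid)
            continue
        curves[u] = rate / r0
        kept.append(uid)
    return {"times": times, "curves": curves, "unit_ids": unit_ids, "kept": kept}
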