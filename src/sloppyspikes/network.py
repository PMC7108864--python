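"""Functional-connectivity graph, centrality and population coupling.

The functional graph has single units as nodes; an edge joins a pair whose
epoch-wise Pearson correlation differs significantly from zero (one-sample
t-test over the NE epochs, Bonferroni-corrected p < 0.05, either sign).
Betweenness centrality counts the shortest paths passing through a node;
neuron-to-population coupling is the correlation between a unit's binarized
train and the co-active count of the remaining single units.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .classify import roc_auc, permutation_test

logger = logging.getLogger(__name__)

__all__ = [
    "build_graph",
    "betweenness",
    "population_coupling",
    "topology_class_comparison",
]


def build_graph(
    corr_epochs: np.ndarray, unit_ids=None, alpha: float = 0.05
) -> dict:
    """Binary functional graph from per-epoch pairwise correlations.

    ``corr_epochs`` is (NE, n_pairs) in upper-triangle row-major order (or
    (NE, N, N) matrices).  For each pair the NE correlation values are tested
    against zero (one-sample t-test); Bonferroni correction over all pairs;
    an edge is added when the corrected p < alpha regardless of sign.  A
    zero-variance series is treated as significant when its mean is nonzero
    (degenerate t statistic), with a warning.

    Returns {"graph": networkx.Graph, "edges": DataFrame(i, j, mean_r,
    p_corrected)}.
    """
    corr_epochs = np.asarray(corr_epochs, dtype=np.float64)
    if corr_epochs.ndim == 3:
        n = corr_epochs.shape[1]
        iu, ju = np.triu_indices(n, k=1)
        corr_epochs = corr_epochs[:, iu, ju]
    n_epochs, n_pairs = corr_epochs.shape
    if n_epochs < 3:
        raise ValueError("need at least 3 epochs to test correlations")
    # recover N from n_pairs
    n = int(round((1 + np.sqrt(1 + 8 * n_pairs)) / 2))
    if n * (n - 1) // 2 != n_pairs:
        raise ValueError("n_pairs is not N(N-1)/2 for any integer N")
    if unit_ids is None:
        unit_ids = np.arange(n)
    unit_ids = np.asarray(unit_ids)
    iu, ju = np.triu_indices(n, k=1)

    mean_r = np.nanmean(corr_epochs, axis=0)
    pvals = np.ones(n_pairs)
    for k in range(n_pairs):
        x = corr_epochs[:, k]
        x = x[~np.isnan(x)]
        if x.size < 3:
            continue
        if np.ptp(x) == 0:
            if x[0] != 0:
                logger.warning("pair %d: zero-variance nonzero correlation; edge kept", k)
                pvals[k] = 0.0
            continue
        pvals[k] = stats.ttest_1samp(x, 0.0).pvalue
    p_corr = np.minimum(pvals * n_pairs, 1.0)

    G = nx.Graph()
    G.add_nodes_from(int(u) for u in unit_ids)
    edges = pd.DataFrame(
        {
            "i": unit_ids[iu],
            "j": unit_ids[ju],
            "mean_r": mean_r,
            "p_corrected": p_corr,
        }
    )
    for _, row in edges[edges["p_corrected"] < alpha].iterrows():
        G.add_edge(int(row["i"]), int(row["j"]), weight=float(row["mean_r"]))
    return {"graph": G, "edges": edges}


def betweenness(G: nx.Graph) -> dict[int, float]:
    """Unnormalized shortest-path betweenness centrality over unordered node
    pairs k < l (k != i != l); disconnected pairs contribute 0."""
    return nx.betweenness_centrality(G, normalized=False)


def population_coupling(rasters: list, unit_ids=None) -> np.ndarray:
    """Neuron-to-population coupling per unit, averaged across epochs.

    For each epoch raster ((n_units, n_bins) +/-1 values or a BinaryRaster),
    the coupling of unit i is the Pearson correlation between its train and
    the number of co-active units (sigma = +1) excluding i."""
    mats = []
    for r in rasters:
        V = r.values if hasattr(r, "values") and not isinstance(r, np.ndarray) else r
        mats.append(np.asarray(V, dtype=np.float64))
    n = mats[0].shape[0]
    per_epoch = np.full((len(mats), n), np.nan)
    for e, V in enumerate(mats):
        active = (V > 0).astype(np.float64)
        total = active.sum(axis=0)
        for i in range(n):
            x = V[i]
            pop = total - active[i]
            if np.ptp(x) == 0 or np.ptp(pop) == 0:
                continue
            per_epoch[e, i] = stats.pearsonr(x, pop)[0]
    with np.errstate(invalid="ignore"):
        return np.nanmean(per_epoch, axis=0)


def topology_class_comparison(
    quantities: dict[str, np.ndarray],
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """ROC/AUC separation of stiff vs sloppy classes for each quantity.

    ``quantities`` maps a name (e.g. "rate", "bc", "coupling") to per-element
    values aligned with ``labels``.  AUC = 1 means stiff values entirely
    exceed sloppy ones.  Returns a table with AUC, permutation p and class
    sizes."""
    labels = np.asarray(labels, dtype=object)
    rows = []
    ss = np.random.SeedSequence(seed)
    for (name, vals), child in zip(quantities.items(), ss.spawn(len(quantities))):
        vals = np.asarray(vals, dtype=np.float64)
        ok = ~np.isnan(vals) & np.isin(labels, ("stiff", "sloppy"))
        res = roc_auc(vals[ok], labels[ok])
        p = permutation_test(
            vals[ok],
            labels[ok],
            n_perm=n_perm,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        rows.append(
            {
                "quantity": name,
                "auc": res.auc,
                "p": p,
                "n_stiff": res.n_positive,
                "n_sloppy": res.n_negative,
            }
        )
    return pd.DataFrame(rows)
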