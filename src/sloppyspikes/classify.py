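"""ROC/AUC separation of stiff vs sloppy distributions, with permutation p.

The AUC is the probability that a randomly drawn stiff value exceeds a
randomly drawn sloppy value (ties half credit) — the normalized Mann-Whitney
rank statistic, equivalent to the threshold-sweep integral of the ROC curve.
AUC = 1 means complete separation with stiff > sloppy; 0.5 means the classes
are indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ROCResult", "roc_auc", "permutation_test"]


@dataclass
class ROCResult:
    auc: float
    positive_class: str
    n_positive: int
    n_negative: int
    p: float | None = None
    n_perm: int | None = None
    seed: int | None = None


def _auc(values: np.ndarray, is_pos: np.ndarray) -> float:
    ranks = stats.rankdata(values)  # average ranks handle ties (half credit)
    n_pos = int(is_pos.sum())
    n_neg = int((~is_pos).sum())
    r_pos = ranks[is_pos].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_auc(values, labels, positive: str = "stiff") -> ROCResult:
    """AUC separating the two label classes; ``positive`` class on top.

    Raises if either class is empty.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    is_pos = labels == positive
    n_pos = int(is_pos.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    return ROCResult(
        auc=float(_auc(values, is_pos)),
        positive_class=positive,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def permutation_test(
    values,
    labels,
    positive: str = "stiff",
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Two-sided permutation p-value for AUC != 0.5.

    Labels are shuffled n_perm times; p = (1 + #{|AUC_perm - 0.5| >=
    |AUC_obs - 0.5|}) / (n_perm + 1), so the smallest attainable p is
    1/(n_perm + 1)."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    obs = abs(roc_auc(values, labels, positive).auc - 0.5)
    is_pos = labels == positive
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(is_pos)
        if abs(_auc(values, perm) - 0.5) >= obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)
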