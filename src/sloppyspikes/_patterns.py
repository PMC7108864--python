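"""Canonical orderings for binary patterns, parameters and observables.

Everything downstream (model fitting, Fisher information, sensitivity maps)
relies on a single fixed convention:

* patterns are vectors in {-1, +1}^N;
* the canonical pattern order is binary counting with -1 <-> 0, +1 <-> 1 and
  unit 0 as the most significant bit, so ``all_patterns(2)`` lists
  ``(-1,-1), (-1,+1), (+1,-1), (+1,+1)``;
* the parameter vector is ``[h_1..h_N, J_12, J_13, ..., J_(N-1)N]`` (upper
  triangle, row-major), and the observable vector uses the same ordering,
  ``[s_1..s_N, s_1 s_2, s_1 s_3, ...]``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "all_patterns",
    "pattern_index",
    "pair_indices",
    "n_parameters",
    "observable_matrix",
    "parameter_vector",
    "parameter_index_table",
]


def n_parameters(n_units: int) -> int:
    """Number of free parameters / observables: N + N(N-1)/2."""
    return n_units + n_units * (n_units - 1) // 2


@lru_cache(maxsize=32)
def _cached_patterns(n_units: int) -> np.ndarray:
    idx = np.arange(2**n_units, dtype=np.int64)
    shifts = np.arange(n_units - 1, -1, -1)
    bits = (idx[:, None] >> shifts[None, :]) & 1
    pats = (2 * bits - 1).astype(np.int8)
    pats.setflags(write=False)
    return pats


def all_patterns(n_units: int) -> np.ndarray:
    """All 2^N patterns in canonical order, shape (2^N, N), dtype int8."""
    if n_units > 20:
        raise ValueError(
            f"enumeration of 2^{n_units} patterns exceeds the N<=20 bound; "
            "use Metropolis sampling instead"
        )
    return _cached_patterns(n_units)


def pattern_index(X: np.ndarray) -> np.ndarray:
    """Map +/-1 patterns (n_samples, N) to canonical pattern indices."""
    X = np.asarray(X)
    n = X.shape[-1]
    bits = (X > 0).astype(np.int64)
    shifts = np.arange(n - 1, -1, -1)
    return bits @ (1 << shifts)


@lru_cache(maxsize=32)
def pair_indices(n_units: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major upper-triangle pair indices (i, j), i < j."""
    iu, ju = np.triu_indices(n_units, k=1)
    iu.setflags(write=False)
    ju.setflags(write=False)
    return iu, ju


def observable_matrix(X: np.ndarray) -> np.ndarray:
    """Observable vectors x = [s_i ..., s_i s_j ...] for each pattern row."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    iu, ju = pair_indices(X.shape[1])
    return np.hstack([X, X[:, iu] * X[:, ju]])


def parameter_vector(h: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Flatten (h, J) into the canonical parameter vector Omega."""
    h = np.asarray(h, dtype=np.float64)
    J = np.asarray(J, dtype=np.float64)
    iu, ju = pair_indices(h.shape[0])
    return np.concatenate([h, J[iu, ju]])


def parameter_index_table(n_units: int, unit_ids=None) -> list[dict]:
    """Published index map: parameter index <-> unit or unit pair."""
    if unit_ids is None:
        unit_ids = list(range(n_units))
    rows = [
        {"index": i, "kind": "unit", "members": (unit_ids[i],)}
        for i in range(n_units)
    ]
    iu, ju = pair_indices(n_units)
    for k, (i, j) in enumerate(zip(iu, ju)):
        rows.append(
            {
                "index": n_units + k,
                "kind": "pair",
                "members": (unit_ids[int(i)], unit_ids[int(j)]),
            }
        )
    return rows
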