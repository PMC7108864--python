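"""Fisher information matrices, sloppiness spectra and sensitivity measures.

For an Ising model (exponential family) the Fisher information matrix equals
the covariance matrix of the observable vector x = [s_1..s_N, s_1 s_2, ...]
under the model distribution,

    FIM_kl = <x_k x_l> - <x_k><x_l>.

Eigen-decomposing the FIM separates stiff parameter combinations (few, large
eigenvalues) from sloppy ones (many, small eigenvalues).  The per-parameter
sensitivity within one ensemble is the epoch-averaged absolute contribution
to the first eigenvector; a weighted variant averages over all eigenvectors
weighted by their eigenvalues.  Population-level sensitivities aggregate over
the random ensembles that cover each unit or pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._patterns import all_patterns, observable_matrix, pair_indices, n_parameters
from .mem import PairwiseMaxEnt, metropolis_sample, empirical_distribution

logger = logging.getLogger(__name__)

__all__ = [
    "FIMResult",
    "compute_fim",
    "project_parameters",
    "projection_variance_by_rank",
    "sensitivity_first_eig",
    "sensitivity_weighted",
    "aggregate_population_sensitivity",
    "median_split",
    "make_stationary_surrogates",
    "split_half_sensitivity_reliability",
]


@dataclass
class FIMResult:
    """FIM of one fitted model plus its eigen-decomposition.

    ``eigenvalues`` are sorted descending; ``eigenvectors[:, k]`` is the unit
    eigenvector of rank k (rank 0 = stiffest), sign-fixed so its
    largest-magnitude component is positive.
    """

    fim: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    method: str = "exact"
    epoch: int | None = None
    seed: int | None = None

    @property
    def n_params(self) -> int:
        return self.fim.shape[0]

    def first_eigenvector(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


def _eigendecompose(F: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(F)
    order = np.argsort(vals, kind="stable")[::-1]  # descending, stable ties
    vals = vals[order]
    vecs = vecs[:, order]
    if (vals < -1e-8).any():
        logger.warning(
            "FIM (%s) not PSD beyond tolerance (min eig %.3g); flooring at 0",
            method,
            vals.min(),
        )
    vals = np.maximum(vals, 0.0)
    # fix arbitrary sign: largest-magnitude component positive
    for k in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, k]))
        if vecs[i, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return vals, vecs


def compute_fim(
    model: PairwiseMaxEnt,
    method: str = "exact",
    n_steps: int = 500_000,
    seed: int | None = None,
) -> FIMResult:
    """Observable-covariance FIM of a fitted model, with eigenpairs.

    ``method="exact"`` enumerates all 2^N patterns (N <= 20);
    ``method="metropolis"`` estimates the covariance from ``n_steps``
    recorded Metropolis sweeps.
    """
    if method == "exact":
        obs = observable_matrix(all_patterns(model.n_units_))
        p = model.pattern_distribution().probs
        mu = p @ obs
        second = (obs * p[:, None]).T @ obs
        F = second - np.outer(mu, mu)
    elif method == "metropolis":
        X = metropolis_sample(model.h_, model.J_, n_steps, seed=seed)
        F = np.cov(observable_matrix(X), rowvar=False, ddof=0)
    else:
        raise ValueError(f"unknown FIM method {method!r}")
    F = 0.5 * (F + F.T)
    vals, vecs = _eigendecompose(F, method)
    return FIMResult(
        fim=F,
        eigenvalues=vals,
        eigenvectors=vecs,
        method=method,
        epoch=model.epoch_,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# parameter trajectories in FIM eigenbases


def project_parameters(omegas: np.ndarray, fim_at_t: FIMResult, t: int) -> np.ndarray:
    """Project parameters Omega(t') for all t' != t onto the eigenvectors of
    the FIM at reference epoch t.  Raw (uncentered) projections; rows index
    the retained epochs in order, columns index eigenvector rank."""
    omegas = np.asarray(omegas, dtype=np.float64)
    keep = np.arange(omegas.shape[0]) != t
    return omegas[keep] @ fim_at_t.eigenvectors


def projection_variance_by_rank(
    fims: list[FIMResult], omegas: np.ndarray
) -> np.ndarray:
    """Variance across epochs t' != t of the rank-k projections, averaged
    over reference epochs t.  Population (1/n) variance so the two-epoch
    boundary case is defined.  One curve of length n_params."""
    omegas = np.asarray(omegas, dtype=np.float64)
    n_epochs = omegas.shape[0]
    if n_epochs != len(fims):
        raise ValueError("one FIM per epoch required")
    if n_epochs < 2:
        raise ValueError("need at least two epochs")
    curves = []
    for t in range(n_epochs):
        proj = project_parameters(omegas, fims[t], t)
        curves.append(proj.var(axis=0, ddof=0))
    return np.mean(curves, axis=0)


# ---------------------------------------------------------------------------
# sensitivities


def sensitivity_first_eig(fims: list[FIMResult]) -> np.ndarray:
    """Ensemble sensitivity s_ne: epoch-averaged |first-eigenvector| components."""
    if not fims:
        raise ValueError("no FIMs")
    return np.mean([np.abs(f.first_eigenvector()) for f in fims], axis=0)


def sensitivity_weighted(fims: list[FIMResult]) -> np.ndarray:
    """Eigenvalue-weighted sensitivity s_ne^w averaged over epochs:
    (1/NE) sum_t sum_k a_tk |v_tk(i)| / sum_k a_tk."""
    if not fims:
        raise ValueError("no FIMs")
    per_epoch = []
    for f in fims:
        tot = f.eigenvalues.sum()
        if tot == 0:
            per_epoch.append(np.zeros(f.n_params))
            continue
        per_epoch.append(np.abs(f.eigenvectors) @ (f.eigenvalues / tot))
    return np.mean(per_epoch, axis=0)


def _element_key(kind: str, members) -> tuple:
    return (kind, tuple(int(m) for m in members))


def population_element_index(unit_ids) -> pd.DataFrame:
    """The population index set I: every single unit and every unordered pair."""
    unit_ids = sorted(int(u) for u in unit_ids)
    rows = [{"kind": "unit", "members": (u,)} for u in unit_ids]
    for a in range(len(unit_ids)):
        for b in range(a + 1, len(unit_ids)):
            rows.append({"kind": "pair", "members": (unit_ids[a], unit_ids[b])})
    return pd.DataFrame(rows)


def aggregate_population_sensitivity(
    s_ne_per_ensemble: list[np.ndarray],
    ensembles,
    population_unit_ids,
) -> pd.DataFrame:
    """Population sensitivity map: per unit and per pair of the whole
    population, the mean of s_ne over the ensembles covering that element.

    Returns a DataFrame with columns kind, members, s, coverage; elements
    never covered by any ensemble have s = NaN and coverage 0.
    """
    table = population_element_index(population_unit_ids)
    acc: dict[tuple, list[float]] = {}
    for s_ne, ens in zip(s_ne_per_ensemble, ensembles):
        ens = np.asarray(ens)
        n = ens.shape[0]
        if s_ne.shape[0] != n_parameters(n):
            raise ValueError("s_ne length does not match ensemble size")
        for i in range(n):
            acc.setdefault(_element_key("unit", (ens[i],)), []).append(s_ne[i])
        iu, ju = pair_indices(n)
        for k, (a, b) in enumerate(zip(iu, ju)):
            pair = tuple(sorted((int(ens[a]), int(ens[b]))))
            acc.setdefault(_element_key("pair", pair), []).append(s_ne[n + k])
    s_vals, cov = [], []
    for _, row in table.iterrows():
        vals = acc.get(_element_key(row["kind"], row["members"]), [])
        cov.append(len(vals))
        s_vals.append(np.mean(vals) if vals else np.nan)
    table["s"] = s_vals
    table["coverage"] = cov
    return table


def median_split(s: np.ndarray) -> np.ndarray:
    """Label covered elements stiff (s > median) or sloppy (s <= median).

    Exact-median ties go to the sloppy class.  NaN entries (uncovered
    elements) get the empty label "" and are excluded from the median.
    Returns an object array of labels {"stiff", "sloppy", ""}.
    """
    s = np.asarray(s, dtype=np.float64)
    labels = np.full(s.shape, "", dtype=object)
    valid = ~np.isnan(s)
    if not valid.any():
        return labels
    med = np.median(s[valid])
    if np.all(s[valid] == s[valid][0]):
        logger.warning("all sensitivities equal; every element labelled sloppy")
    labels[valid & (s > med)] = "stiff"
    labels[valid & (s <= med)] = "sloppy"
    return labels


# ---------------------------------------------------------------------------
# surrogates and reliability


def make_stationary_surrogates(
    model: PairwiseMaxEnt,
    n_epochs: int,
    n_patterns: int = 5000,
    seed: int | None = None,
    fim_method: str = "exact",
    **fit_params,
) -> dict:
    """Stationary surrogate set: NE independent Metropolis draws from one
    reference model, each refit and its FIM computed.

    By construction all parameter fluctuation across the surrogate epochs is
    model-estimation error.  Returns {"models", "fims", "omegas",
    "distributions"}.
    """
    ss = np.random.SeedSequence(seed)
    models, fims, omegas, dists = [], [], [], []
    for k, child in enumerate(ss.spawn(n_epochs)):
        s = int(child.generate_state(1)[0] % (2**31))
        X = model.sample(n_patterns, seed=s)
        refit = PairwiseMaxEnt(**{**model.get_params(), **fit_params}).fit(X)
        refit.epoch_ = k
        models.append(refit)
        fims.append(compute_fim(refit, method=fim_method))
        omegas.append(refit.theta_)
        dists.append(empirical_distribution(X))
    return {
        "models": models,
        "fims": fims,
        "omegas": np.array(omegas),
        "distributions": dists,
    }


def split_half_sensitivity_reliability(
    fims_per_ensemble: list[list[FIMResult]],
    ensembles,
    population_unit_ids,
    weighted: bool = False,
) -> float:
    """Pearson correlation between population sensitivities computed from the
    first and second halves of the epochs (covered elements only)."""
    measure = sensitivity_weighted if weighted else sensitivity_first_eig
    halves = []
    for part in (0, 1):
        s_list = []
        for fims in fims_per_ensemble:
            half = len(fims) // 2
            sel = fims[:half] if part == 0 else fims[half:]
            s_list.append(measure(sel))
        tab = aggregate_population_sensitivity(s_list, ensembles, population_unit_ids)
        halves.append(tab["s"].to_numpy())
    a, b = halves
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 covered elements")
    return float(stats.pearsonr(a[ok], b[ok])[0])
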