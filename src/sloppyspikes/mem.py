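"""Pairwise and independent maximum-entropy (Ising) models of +/-1 patterns.

The pairwise model is the maximum-entropy distribution over N-dimensional
+/-1 patterns constrained to match the empirical activation rates <s_i> and
pairwise moments <s_i s_j>.  It has Boltzmann form

    P(s) = exp(-E(s)) / Z,     E(s) = - sum_i h_i s_i - 1/2 sum_ij J_ij s_i s_j

with intrinsic biases h and symmetric zero-diagonal couplings J.  Parameters
are learned by gradient descent on the moment discrepancies,

    h_i  <- h_i  - alpha (<s_i>_model  - <s_i>_data)
    J_ij <- J_ij - alpha (<s_i s_j>_model - <s_i s_j>_data)

stopping when the max-abs discrepancy over all N + N(N-1)/2 moments falls
below ``tol`` or after ``max_iter`` iterations.  Model moments come either
from exact enumeration (N <= 20) or from Metropolis Monte Carlo sampling.

Estimators follow the scikit-learn protocol: hyperparameters in __init__,
``fit(X)`` with X an (n_samples, N) array of +/-1 values, fitted attributes
with trailing underscores (``h_``, ``J_``, ``converged_`` ...).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from ._patterns import (
    all_patterns,
    observable_matrix,
    pair_indices,
    parameter_vector,
    pattern_index,
    n_parameters,
)
from .spike_io import PatternSamples

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseMaxEnt",
    "IndependentMaxEnt",
    "PatternDistribution",
    "energy",
    "boltzmann_distribution",
    "model_moments",
    "metropolis_sample",
    "empirical_moments",
    "empirical_distribution",
    "kl_divergence",
    "js_divergence",
    "kl_ratio",
]

_CLIP = 1.0 - 1e-4  # rate clip before atanh for degenerate units


# ---------------------------------------------------------------------------
# distributions


@dataclass
class PatternDistribution:
    """Probabilities over all 2^N patterns in canonical order."""

    n_units: int
    probs: np.ndarray
    kind: str = "model"  # "model" or "empirical"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (2**self.n_units,):
            raise ValueError("probability vector must have length 2^N")
        if (self.probs < -1e-15).any():
            raise ValueError("negative probabilities")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")


def _as_X(samples) -> np.ndarray:
    if isinstance(samples, PatternSamples):
        samples = samples.X
    X = np.asarray(samples)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need a (n_samples, N) array with n_samples >= 1")
    if not np.isin(X, (-1, 1)).all():
        raise ValueError("patterns must take values in {-1, +1}")
    return X.astype(np.int8, copy=False)


def empirical_distribution(samples) -> PatternDistribution:
    """Relative pattern frequencies; unobserved patterns get probability 0."""
    X = _as_X(samples)
    n = X.shape[1]
    counts = np.bincount(pattern_index(X), minlength=2**n)
    return PatternDistribution(n, counts / counts.sum(), kind="empirical")


def empirical_moments(samples) -> tuple[np.ndarray, np.ndarray]:
    """Sample means of s_i and s_i s_j (upper-triangle order)."""
    X = _as_X(samples).astype(np.float64)
    iu, ju = pair_indices(X.shape[1])
    return X.mean(axis=0), (X[:, iu] * X[:, ju]).mean(axis=0)


# ---------------------------------------------------------------------------
# energies and exact model quantities


def energy(h, J, patterns) -> np.ndarray:
    """Pattern energy E = -h.s - 1/2 s'Js for one or many patterns."""
    h = np.asarray(h, dtype=np.float64)
    J = np.asarray(J, dtype=np.float64)
    s = np.asarray(patterns, dtype=np.float64)
    squeeze = s.ndim == 1
    if squeeze:
        s = s[None, :]
    if s.shape[1] != h.shape[0]:
        raise ValueError("pattern length does not match model size")
    E = -s @ h - 0.5 * np.einsum("ni,ij,nj->n", s, J, s)
    return E[0] if squeeze else E


def _theta_log_probs(theta: np.ndarray, n: int) -> np.ndarray:
    """Log Boltzmann probabilities from the flat parameter vector."""
    obs = observable_matrix(all_patterns(n))
    logw = obs @ theta  # = -E(s)
    return logw - logsumexp(logw)


def boltzmann_distribution(h, J) -> PatternDistribution:
    """Exact Boltzmann distribution by enumeration (N <= 20)."""
    h = np.asarray(h, dtype=np.float64)
    n = h.shape[0]
    theta = parameter_vector(h, J)
    return PatternDistribution(n, np.exp(_theta_log_probs(theta, n)))


def model_moments(
    h,
    J,
    method: str = "exact",
    n_samples: int = 100_000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Model expectations <s_i> and <s_i s_j>, exact or by Metropolis."""
    h = np.asarray(h, dtype=np.float64)
    n = h.shape[0]
    if method == "exact":
        theta = parameter_vector(h, J)
        p = np.exp(_theta_log_probs(theta, n))
        mom = p @ observable_matrix(all_patterns(n))
        return mom[:n], mom[n:]
    if method == "metropolis":
        if n_samples < 1000:
            logger.warning("Metropolis moments from only %d samples", n_samples)
        X = metropolis_sample(h, J, n_samples, seed=seed)
        return empirical_moments(X)
    raise ValueError(f"unknown moment method {method!r}")


# ---------------------------------------------------------------------------
# Metropolis sampling

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@_njit(cache=True)
def _mh_sweeps(h, J, sigma, field, sites, logu, n_record, burn_in, out):
    """Single-site-flip Metropolis; one recorded sample per sweep.

    ``field`` caches J @ sigma and is updated incrementally.  ``sites`` and
    ``logu`` hold pre-drawn site indices and log-uniforms, one per proposal.
    """
    n = h.shape[0]
    total = burn_in + n_record
    k = 0
    for sweep in range(total):
        for _ in range(n):
            i = sites[k]
            dE = 2.0 * sigma[i] * (h[i] + field[i])
            if dE <= 0.0 or logu[k] < -dE:
                old = sigma[i]
                sigma[i] = -old
                for j in range(n):
                    field[j] += J[j, i] * (sigma[i] - old)
            k += 1
        if sweep >= burn_in:
            for j in range(n):
                out[sweep - burn_in, j] = sigma[j]


def metropolis_sample(
    h,
    J,
    n_samples: int,
    seed: int | None = None,
    burn_in: int = 1000,
) -> np.ndarray:
    """Draw patterns from the Boltzmann distribution by Metropolis dynamics.

    One sweep = N single-site flip proposals with acceptance
    min(1, exp(-dE)); one sample is recorded per sweep after ``burn_in``
    discarded sweeps.  The chain starts from a uniform random pattern and is
    deterministic under a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    h = np.asarray(h, dtype=np.float64)
    J = np.asarray(J, dtype=np.float64)
    n = h.shape[0]
    rng = np.random.default_rng(seed)
    sigma = rng.choice(np.array([-1.0, 1.0]), size=n)
    total_props = (burn_in + n_samples) * n
    sites = rng.integers(0, n, size=total_props)
    logu = np.log(rng.random(size=total_props))
    field = J @ sigma
    out = np.empty((n_samples, n), dtype=np.float64)
    _mh_sweeps(h, J, sigma, field, sites, logu, n_samples, burn_in, out)
    return out.astype(np.int8)


# ---------------------------------------------------------------------------
# estimators


class PairwiseMaxEnt(BaseEstimator):
    """Pairwise maximum-entropy (Ising) model fitted by moment matching.

    Parameters
    ----------
    alpha : learning rate of the gradient-descent updates (default 0.1).
    tol : max-abs moment-discrepancy threshold for convergence (0.005).
    max_iter : iteration cap (100).
    moment_method : "exact" (enumeration, N <= 20) or "metropolis".
    n_mc : Metropolis samples per moment evaluation (100000).
    random_state : seed for the Metropolis moment evaluations.

    Attributes (after fit)
    ----------------------
    h_, J_ : fitted biases (N,) and symmetric zero-diagonal couplings (N, N).
    converged_, n_iter_, discrepancy_ : stopping diagnostics.
    target_rates_, target_corrs_ : data moments the fit matched.
    n_units_, unit_ids_, epoch_ : bookkeeping from the input samples.
    """

    _fits_j = True

    def __init__(
        self,
        alpha: float = 0.1,
        tol: float = 0.005,
        max_iter: int = 100,
        moment_method: str = "exact",
        n_mc: int = 100_000,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter
        self.moment_method = moment_method
        self.n_mc = n_mc
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None):
        unit_ids = epoch = None
        if isinstance(X, PatternSamples):
            unit_ids, epoch = X.unit_ids, X.epoch
        X = _as_X(X)
        n = X.shape[1]
        if self.moment_method == "exact" and n > 20:
            raise ValueError("exact moments require N <= 20; use metropolis")
        rates, corrs = empirical_moments(X)
        target = np.concatenate([rates, corrs])

        clipped = np.clip(rates, -_CLIP, _CLIP)
        if (np.abs(rates) >= _CLIP).any():
            logger.warning(
                "degenerate unit(s) always silent/active; rates clipped before atanh"
            )
        h = np.arctanh(clipped)
        J = np.zeros((n, n))
        iu, ju = pair_indices(n)

        obs = None
        if self.moment_method == "exact":
            obs = observable_matrix(all_patterns(n))

        disc = np.inf
        it = 0
        seed_seq = np.random.SeedSequence(self.random_state)
        for it in range(1, self.max_iter + 1):
            model_mom = self._moments(h, J, obs, seed_seq)
            g = model_mom - target
            disc = float(np.abs(g).max())
            if disc < self.tol:
                break
            h -= self.alpha * g[:n]
            dJ = self.alpha * g[n:]
            J[iu, ju] -= dJ
            J[ju, iu] -= dJ

        self.h_ = h
        self.J_ = J
        self.n_units_ = n
        self.unit_ids_ = unit_ids if unit_ids is not None else np.arange(n)
        self.epoch_ = epoch
        self.converged_ = disc < self.tol
        self.n_iter_ = it
        self.discrepancy_ = disc
        self.target_rates_ = rates
        self.target_corrs_ = corrs
        return self

    def _moments(self, h, J, obs, seed_seq) -> np.ndarray:
        if self.moment_method == "exact":
            theta = parameter_vector(h, J)
            logw = obs @ theta
            p = np.exp(logw - logsumexp(logw))
            return p @ obs
        seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
        r, c = model_moments(
            h, J, method="metropolis", n_samples=self.n_mc, seed=seed
        )
        return np.concatenate([r, c])

    @classmethod
    def from_parameters(cls, h, J, unit_ids=None, epoch=None, **params):
        """Rebuild a fitted model from stored parameters (h, J)."""
        model = cls(**params)
        model.h_ = np.asarray(h, dtype=np.float64)
        model.J_ = np.asarray(J, dtype=np.float64)
        n = model.h_.shape[0]
        if model.J_.shape != (n, n):
            raise ValueError("J must be (N, N)")
        model.n_units_ = n
        model.unit_ids_ = np.asarray(unit_ids) if unit_ids is not None else np.arange(n)
        model.epoch_ = epoch
        model.converged_ = True
        model.n_iter_ = 0
        model.discrepancy_ = float("nan")
        return model

    # -- fitted-model queries ---------------------------------------------

    @property
    def theta_(self) -> np.ndarray:
        """Flat parameter vector Omega = [h, J_upper]."""
        return parameter_vector(self.h_, self.J_)

    def energy(self, X) -> np.ndarray:
        return energy(self.h_, self.J_, X)

    def pattern_distribution(self) -> PatternDistribution:
        return boltzmann_distribution(self.h_, self.J_)

    def moments(self, method=None, n_samples=None, seed=None):
        return model_moments(
            self.h_,
            self.J_,
            method=method or self.moment_method,
            n_samples=n_samples or self.n_mc,
            seed=seed,
        )

    def sample(self, n_samples: int, seed: int | None = None, burn_in: int = 1000):
        return metropolis_sample(self.h_, self.J_, n_samples, seed=seed, burn_in=burn_in)

    def score(self, X, y=None) -> float:
        """Mean log-likelihood (nats/pattern) of patterns under the model."""
        X = _as_X(X)
        logp = _theta_log_probs(self.theta_, self.n_units_)
        return float(logp[pattern_index(X)].mean())


class IndependentMaxEnt(PairwiseMaxEnt):
    """Independent maximum-entropy model: only rates constrained, J = 0.

    The exact solution is h_i = atanh(<s_i>); the same gradient loop is run
    with the couplings frozen so the fitting controls match the pairwise
    model's.
    """

    _fits_j = False

    def fit(self, X, y=None):
        unit_ids = epoch = None
        if isinstance(X, PatternSamples):
            unit_ids, epoch = X.unit_ids, X.epoch
        X = _as_X(X)
        n = X.shape[1]
        rates, corrs = empirical_moments(X)
        clipped = np.clip(rates, -_CLIP, _CLIP)
        h = np.arctanh(clipped)
        disc = np.inf
        it = 0
        for it in range(1, self.max_iter + 1):
            g = np.tanh(h) - rates
            disc = float(np.abs(g).max())
            if disc < self.tol:
                break
            h -= self.alpha * g
        self.h_ = h
        self.J_ = np.zeros((n, n))
        self.n_units_ = n
        self.unit_ids_ = unit_ids if unit_ids is not None else np.arange(n)
        self.epoch_ = epoch
        self.converged_ = disc < self.tol
        self.n_iter_ = it
        self.discrepancy_ = disc
        self.target_rates_ = rates
        self.target_corrs_ = corrs
        return self


# ---------------------------------------------------------------------------
# divergences


def _aligned(p1, p2) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p1, PatternDistribution):
        p1 = p1.probs
    if isinstance(p2, PatternDistribution):
        p2 = p2.probs
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    if p1.shape != p2.shape:
        raise ValueError("distributions must be over the same pattern space")
    return p1, p2


def kl_divergence(p1, p2) -> float:
    """D_KL(P1 || P2) in nats; +inf if P2 misses support of P1."""
    p1, p2 = _aligned(p1, p2)
    sup = p1 > 0
    if (p2[sup] == 0).any():
        return math.inf
    return float(np.sum(p1[sup] * np.log(p1[sup] / p2[sup])))


def js_divergence(p1, p2) -> float:
    """Jensen-Shannon divergence in nats: symmetric, finite, in [0, ln 2]."""
    p1, p2 = _aligned(p1, p2)
    m = 0.5 * (p1 + p2)
    return 0.5 * kl_divergence(p1, m) + 0.5 * kl_divergence(p2, m)


def kl_ratio(p_data, p_independent, p_pairwise) -> tuple[float, float, float]:
    """Kullback-Leibler ratio R = (D1 - D2)/D1 with Dk = D_KL(data || model_k).

    R ranges between 0 (pairwise no better than independent) and 1 (pairwise
    model exactly reproduces the data distribution).  Returns (R, D1, D2);
    R is NaN when D1 = 0 (undefined).
    """
    d1 = kl_divergence(p_data, p_independent)
    d2 = kl_divergence(p_data, p_pairwise)
    if d1 == 0:
        warnings.warn("KL ratio undefined: independent model already exact")
        return float("nan"), d1, d2
    return (d1 - d2) / d1, d1, d2
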