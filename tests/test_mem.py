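import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sloppyspikes._patterns import all_patterns, pair_indices, parameter_vector
from sloppyspikes.mem import (
    IndependentMaxEnt,
    PairwiseMaxEnt,
    PatternDistribution,
    boltzmann_distribution,
    empirical_distribution,
    empirical_moments,
    energy,
    js_divergence,
    kl_divergence,
    kl_ratio,
    metropolis_sample,
    model_moments,
)
from sloppyspikes.synth import random_ising_model


def brute_force_energy(h, J, s):
    """Term-by-term oracle for E = -sum h_i s_i - 1/2 sum_ij J_ij s_i s_j."""
    n = len(h)
    e = -sum(h[i] * s[i] for i in range(n))
    e -= 0.5 * sum(J[i][j] * s[i] * s[j] for i in range(n) for j in range(n))
    return e


def brute_force_distribution(h, J):
    pats = list(itertools.product([-1, 1], repeat=len(h)))
    # canonical order: -1 before +1 with unit 0 most significant
    weights = [math.exp(-brute_force_energy(h, J, s)) for s in pats]
    z = sum(weights)
    return np.array([w / z for w in weights])


class TestEnergy:
    def test_zero_model_has_zero_energy(self):
        pats = all_patterns(4)
        assert np.allclose(energy(np.zeros(4), np.zeros((4, 4)), pats), 0)

    def test_single_unit_bias(self):
        assert energy([0.5], [[0.0]], [1]) == pytest.approx(-0.5)
        assert energy([0.5], [[0.0]], [-1]) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_model(self):
        rng = np.random.default_rng(0)
        h = rng.normal(size=3)
        J = rng.normal(size=(3, 3))
        J = np.triu(J, 1) + np.triu(J, 1).T
        for s in itertools.product([-1, 1], repeat=3):
            assert energy(h, J, list(s)) == pytest.approx(
                brute_force_energy(h, J, s)
            )

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            energy([0.1, 0.2], np.zeros((2, 2)), [1, 1, 1])


class TestBoltzmannDistribution:
    def test_zero_model_is_uniform_over_1024_patterns(self):
        d = boltzmann_distribution(np.zeros(10), np.zeros((10, 10)))
        assert d.probs.shape == (1024,)
        assert np.allclose(d.probs, 1 / 1024)

    def test_single_unit_closed_form(self):
        d = boltzmann_distribution([0.5], [[0.0]])
        assert d.probs[1] == pytest.approx(1 / (1 + math.exp(-1)))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        h = rng.normal(size=4)
        J = rng.normal(scale=0.5, size=(4, 4))
        J = np.triu(J, 1) + np.triu(J, 1).T
        d = boltzmann_distribution(h, J)
        np.testing.assert_allclose(d.probs, brute_force_distribution(h, J), atol=1e-12)

    def test_invariant_to_constant_energy_shift(self):
        h = np.array([0.3, -0.2])
        J = np.zeros((2, 2))
        # adding a constant to all energies = multiplying all weights: same P
        d = boltzmann_distribution(h, J)
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestModelMoments:
    def test_zero_model_has_zero_moments(self):
        r, c = model_moments(np.zeros(4), np.zeros((4, 4)))
        assert np.allclose(r, 0) and np.allclose(c, 0)

    def test_single_unit_tanh(self):
        r, _ = model_moments([0.5], [[0.0]])
        assert r[0] == pytest.approx(math.tanh(0.5))

    def test_metropolis_agrees_with_exact_within_3_se(self):
        h, J = random_ising_model(5, seed=0)
        r_ex, c_ex = model_moments(h, J)
        n = 100_000
        r_mc, c_mc = model_moments(h, J, method="metropolis", n_samples=n, seed=4)
        # autocorrelated chain: allow a generous effective-sample-size factor
        se_r = 3 * np.sqrt((1 - r_ex**2) / n) * 5
        assert (np.abs(r_mc - r_ex) < np.maximum(se_r, 0.01)).all()
        assert (np.abs(c_mc - c_ex) < 0.02).all()


class TestMetropolis:
    def test_strong_field_pins_all_units_up(self):
        X = metropolis_sample(10 * np.ones(4), np.zeros((4, 4)), 500, seed=0)
        assert (X == 1).mean() > 0.99

    def test_empirical_distribution_close_to_boltzmann(self):
        h, J = random_ising_model(5, seed=2)
        X = metropolis_sample(h, J, 100_000, seed=3)
        d_emp = empirical_distribution(X)
        d_true = boltzmann_distribution(h, J)
        assert js_divergence(d_emp, d_true) < 0.01

    def test_divergence_shrinks_with_more_samples(self):
        h, J = random_ising_model(5, seed=5)
        d_true = boltzmann_distribution(h, J)
        djs = [
            js_divergence(
                empirical_distribution(metropolis_sample(h, J, n, seed=6)), d_true
            )
            for n in (500, 50_000)
        ]
        assert djs[1] < djs[0]

    def test_same_seed_reproduces_stream(self):
        h, J = random_ising_model(4, seed=7)
        a = metropolis_sample(h, J, 200, seed=9)
        b = metropolis_sample(h, J, 200, seed=9)
        assert np.array_equal(a, b)


class TestEmpiricalStatistics:
    def test_all_silent_moments(self):
        X = -np.ones((50, 3), dtype=int)
        r, c = empirical_moments(X)
        assert np.allclose(r, -1) and np.allclose(c, 1)

    def test_anticorrelated_pair(self):
        X = np.array([[1, -1], [-1, 1]] * 10)
        _, c = empirical_moments(X)
        assert c[0] == pytest.approx(-1)

    def test_hand_computed_four_pattern_set(self):
        X = np.array([[1, 1], [1, -1], [-1, -1], [-1, -1]])
        r, c = empirical_moments(X)
        assert r.tolist() == [0.0, -0.5]
        assert c[0] == pytest.approx((1 - 1 + 1 + 1) / 4)

    def test_point_mass_distribution(self):
        X = np.tile([1, -1, 1], (7, 1))
        d = empirical_distribution(X)
        assert d.probs.max() == 1.0 and d.probs.sum() == 1.0

    def test_three_to_one_frequencies(self):
        X = np.array([[1, 1]] * 3 + [[-1, -1]])
        d = empirical_distribution(X)
        assert d.probs[3] == 0.75 and d.probs[0] == 0.25


class TestFitPairwise:
    def test_independent_samples_give_near_zero_couplings(self):
        rng = np.random.default_rng(0)
        X = np.where(rng.random((20_000, 5)) < 0.2, 1, -1)
        m = PairwiseMaxEnt().fit(X)
        assert np.abs(m.J_[np.triu_indices(5, 1)]).max() < 0.15

    def test_recovery_of_known_small_model(self):
        h, J = random_ising_model(5, seed=11)
        X = metropolis_sample(h, J, 5000, seed=12)
        m = PairwiseMaxEnt(max_iter=1000).fit(X)
        rates, corrs = empirical_moments(X)
        mr, mc = m.moments()
        assert np.abs(np.concatenate([mr - rates, mc - corrs])).max() < 0.005
        truth = parameter_vector(h, J)
        assert np.corrcoef(truth, m.theta_)[0, 1] > 0.9

    def test_parameter_count_is_55_for_n10(self):
        rng = np.random.default_rng(1)
        X = np.where(rng.random((300, 10)) < 0.1, 1, -1)
        m = PairwiseMaxEnt(max_iter=5).fit(X)
        assert m.theta_.shape == (55,)

    def test_converged_flag_tracks_tolerance(self):
        rng = np.random.default_rng(2)
        X = np.where(rng.random((2000, 4)) < 0.3, 1, -1)
        m = PairwiseMaxEnt(max_iter=500).fit(X)
        assert m.converged_
        assert m.discrepancy_ < m.tol

    def test_degenerate_unit_is_clipped_not_fatal(self):
        X = np.column_stack([np.ones(100), np.where(np.arange(100) % 2, 1, -1)])
        m = PairwiseMaxEnt(max_iter=10).fit(X.astype(int))
        assert np.isfinite(m.h_).all()

    def test_sklearn_param_interface(self):
        m = PairwiseMaxEnt(alpha=0.2)
        assert m.get_params()["alpha"] == 0.2
        m.set_params(tol=0.01)
        assert m.tol == 0.01


class TestFitIndependent:
    def test_zero_rate_gives_zero_bias(self):
        X = np.array([[1, -1], [-1, 1]] * 50)
        m = IndependentMaxEnt().fit(X)
        assert np.allclose(m.h_, 0, atol=1e-6)
        assert np.allclose(m.J_, 0)

    def test_bias_is_atanh_of_rate(self):
        rng = np.random.default_rng(3)
        X = np.where(rng.random((100_000, 1)) < 0.7311, 1, -1)
        m = IndependentMaxEnt().fit(X)
        assert m.h_[0] == pytest.approx(0.5, abs=0.05)

    def test_distribution_factorizes_over_units(self):
        rng = np.random.default_rng(4)
        X = np.where(rng.random((5000, 3)) < 0.3, 1, -1)
        m = IndependentMaxEnt().fit(X)
        probs = m.pattern_distribution().probs
        marg1 = probs.reshape(2, 2, 2).sum(axis=(1, 2))
        marg2 = probs.reshape(2, 2, 2).sum(axis=(0, 2))
        marg3 = probs.reshape(2, 2, 2).sum(axis=(0, 1))
        outer = np.einsum("i,j,k->ijk", marg1, marg2, marg3).ravel()
        np.testing.assert_allclose(probs, outer, atol=1e-10)


class TestDivergences:
    def test_kl_self_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == 0

    def test_kl_point_mass_vs_uniform_is_ln2(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(math.log(2))

    def test_kl_infinite_when_support_missing(self):
        assert kl_divergence([0.5, 0.5], [1.0, 0.0]) == math.inf

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_kl_nonnegative_and_js_symmetric_bounded(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(8))
        q = rng.dirichlet(np.ones(8))
        assert kl_divergence(p, q) >= 0
        assert js_divergence(p, q) == pytest.approx(js_divergence(q, p))
        assert 0 <= js_divergence(p, q) <= math.log(2) + 1e-12

    def test_js_disjoint_supports_is_ln2(self):
        assert js_divergence([1, 0], [0, 1]) == pytest.approx(math.log(2))

    def test_kl_ratio_limits(self):
        p_data = np.array([0.7, 0.1, 0.1, 0.1])
        p_ind = np.array([0.4, 0.3, 0.2, 0.1])
        r, d1, d2 = kl_ratio(p_data, p_ind, p_data)  # pairwise exact
        assert d2 == 0 and r == pytest.approx(1.0)
        r0, _, _ = kl_ratio(p_data, p_ind, p_ind)  # pairwise no better
        assert r0 == pytest.approx(0.0)

    def test_kl_ratio_undefined_when_independent_exact(self):
        p = np.array([0.5, 0.5])
        with pytest.warns(UserWarning):
            r, _, _ = kl_ratio(p, p, p)
        assert math.isnan(r)
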