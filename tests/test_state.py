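import numpy as np
import pytest

from sloppyspikes.mem import PatternDistribution, js_divergence
from sloppyspikes.spike_io import segment_epochs
from sloppyspikes.state import (
    lagged_model_fit,
    observable_timeseries,
    pairwise_pattern_divergence,
    silence_density,
    similarity_gamma,
    state_divergence_correlation,
    state_observable_correlation,
)

from conftest import make_dataset


def dist(probs):
    probs = np.asarray(probs, float)
    return PatternDistribution(int(np.log2(len(probs))), probs, kind="empirical")


class TestSilenceDensity:
    def test_no_spikes_gives_full_silence(self):
        ds = make_dataset([], units=[1], events=[50.0], duration=100.0)
        ew = segment_epochs(ds)
        assert silence_density(ds, ew)[0] == 1.0

    def test_spike_in_every_bin_gives_zero(self):
        times = [(1, 48.5 + 0.02 * k + 0.01) for k in range(75)]
        ds = make_dataset(times, events=[50.0], duration=100.0)
        ew = segment_epochs(ds)
        assert silence_density(ds, ew)[0] == 0.0

    def test_partial_occupancy_fraction(self):
        # occupy 45 of 75 bins in the single 1.5-s window -> CS = 0.4
        times = [(1, 48.5 + 0.02 * k + 0.005) for k in range(45)]
        ds = make_dataset(times, events=[50.0], duration=100.0)
        ew = segment_epochs(ds)
        assert silence_density(ds, ew)[0] == pytest.approx(0.4)

    def test_invariant_to_spikes_in_occupied_bins(self):
        base = [(1, 48.5 + 0.02 * k + 0.005) for k in range(45)]
        extra = base + [(2, t + 0.001) for _, t in base]
        ds1 = make_dataset(base, events=[50.0], duration=100.0, units=[1, 2])
        ds2 = make_dataset(extra, events=[50.0], duration=100.0, units=[1, 2])
        ew = segment_epochs(ds1)
        assert silence_density(ds1, ew)[0] == silence_density(ds2, ew)[0]


class TestPatternDivergence:
    def test_identical_epochs_give_zero(self):
        d = dist([0.5, 0.25, 0.125, 0.125])
        mat = pairwise_pattern_divergence([[d, d, d]])
        np.testing.assert_allclose(mat, 0.0)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        dists = [[dist(rng.dirichlet(np.ones(4))) for _ in range(4)]]
        mat = pairwise_pattern_divergence(dists)
        np.testing.assert_allclose(mat, mat.T)
        np.testing.assert_allclose(np.diag(mat), 0.0)

    def test_hand_case_two_distributions(self):
        d1, d2 = dist([1.0, 0.0]), dist([0.5, 0.5])
        mat = pairwise_pattern_divergence([[d1, d2]])
        assert mat[0, 1] == pytest.approx(js_divergence(d1, d2))

    def test_averaged_over_ensembles(self):
        d1, d2 = dist([1.0, 0.0]), dist([0.0, 1.0])
        mat = pairwise_pattern_divergence([[d1, d2], [d1, d1]])
        assert mat[0, 1] == pytest.approx(js_divergence(d1, d2) / 2)


class TestStateDivergenceCorrelation:
    def test_linear_relation_gives_unit_correlation(self):
        cs = np.array([0.1, 0.3, 0.6, 0.9])
        d = np.abs(cs[:, None] - cs[None, :])
        out = state_divergence_correlation(2.0 * d, cs, n_perm=200, seed=0)
        assert out["rc"] == pytest.approx(1.0)
        assert out["p"] < 0.05

    def test_constant_state_flagged_undefined(self):
        cs = np.full(4, 0.5)
        out = state_divergence_correlation(np.ones((4, 4)), cs, n_perm=50, seed=0)
        assert np.isnan(out["rc"])


class TestObservableTimeseries:
    def test_hand_raster(self):
        # unit 1 fires in every bin of the window, unit 2 in half of them
        spikes = [(1, 48.5 + 0.01 * k + 0.005) for k in range(150)]
        spikes += [(2, 48.5 + 0.02 * k + 0.005) for k in range(75)]
        ds = make_dataset(spikes, events=[50.0], duration=100.0, units=[1, 2])
        ew = segment_epochs(ds)
        obs = observable_timeseries(ds, ew, unit_ids=[1, 2])
        assert obs["rates"][0, 0] == pytest.approx(100.0)  # 150 bins / 1.5 s
        assert obs["rates"][0, 1] == pytest.approx(50.0)

    def test_constant_unit_correlation_missing(self):
        spikes = [(2, 48.5 + 0.02 * k + 0.005) for k in range(75)]
        ds = make_dataset(spikes, events=[50.0], duration=100.0, units=[1, 2])
        ew = segment_epochs(ds)
        obs = observable_timeseries(ds, ew, unit_ids=[1, 2])
        assert obs["rates"][0, 0] == 0.0
        assert np.isnan(obs["correlations"][0, 0])

    def test_perfectly_coactive_pair(self):
        spikes = []
        for k in range(0, 150, 2):
            t = 48.5 + 0.01 * k + 0.005
            spikes += [(1, t), (2, t)]
        ds = make_dataset(spikes, events=[50.0], duration=100.0, units=[1, 2])
        ew = segment_epochs(ds)
        obs = observable_timeseries(ds, ew, unit_ids=[1, 2])
        assert obs["correlations"][0, 0] == pytest.approx(1.0)


class TestStateObservableCorrelation:
    def test_observable_equal_to_state_has_rcs_one(self):
        cs = np.array([0.1, 0.4, 0.2, 0.8, 0.5])
        rcs = state_observable_correlation(cs[:, None], cs)
        assert rcs[0] == pytest.approx(1.0)

    def test_bounded_and_nan_for_short_series(self):
        cs = np.array([0.1, 0.4, np.nan, np.nan, np.nan])
        series = np.random.default_rng(0).random((5, 3))
        rcs = state_observable_correlation(series, cs)
        assert np.isnan(rcs).all()

    def test_independent_noise_near_null(self):
        rng = np.random.default_rng(1)
        cs = rng.random(40)
        series = rng.random((40, 50))
        rcs = state_observable_correlation(series, cs)
        assert np.nanmean(rcs) < 0.3
        assert ((rcs >= 0) & (rcs <= 1)).all()


class TestSimilarityGamma:
    def test_zero_lag_is_one(self):
        series = np.random.default_rng(0).random((5, 8))
        g = similarity_gamma(series)
        assert g[0] == pytest.approx(1.0)

    def test_white_noise_decorrelates(self):
        series = np.random.default_rng(1).normal(size=(60, 40))
        g = similarity_gamma(series, max_lag=5)
        assert np.abs(g[1:]).max() < 0.15

    def test_ar1_profile_decays_like_autocorrelation(self):
        rng = np.random.default_rng(2)
        phi = 0.8
        n_epochs, dim = 300, 30
        series = np.zeros((n_epochs, dim))
        series[0] = rng.normal(size=dim)
        for t in range(1, n_epochs):
            series[t] = phi * series[t - 1] + np.sqrt(1 - phi**2) * rng.normal(size=dim)
        g = similarity_gamma(series, max_lag=4)
        for lag in range(1, 5):
            assert g[lag] == pytest.approx(phi**lag, abs=0.12)


class TestLaggedModelFit:
    def test_zero_lag_equals_within_epoch_divergence(self):
        emp = [dist([0.7, 0.3]), dist([0.5, 0.5])]
        mod = [dist([0.6, 0.4]), dist([0.5, 0.5])]
        out = lagged_model_fit(emp, mod)
        expect0 = np.mean(
            [js_divergence(emp[0], mod[0]), js_divergence(emp[1], mod[1])]
        )
        assert out[0] == pytest.approx(expect0)

    def test_drifting_distributions_increase_with_lag(self):
        ps = [dist([0.9 - 0.1 * k, 0.1 + 0.1 * k]) for k in range(6)]
        out = lagged_model_fit(ps, ps, max_lag=4)
        assert (np.diff(out) > 0).all()
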