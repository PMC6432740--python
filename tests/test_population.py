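"""Population encoding and decoding against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from popmem import (
    BoundedSpace,
    CircularSpace,
    PopulationParams,
    PriorDistribution,
    decode_ml,
    decode_posterior_sample,
    decoding_grid,
    expected_rates,
    log_likelihood_grid,
    posterior_probabilities,
    preferred_values,
    sample_spikes,
    simulate_responses,
)

CIRC = CircularSpace(180.0)
BOUND = BoundedSpace(0.0, 100.0)


class TestExpectedRates:
    def test_rates_sum_to_gain_over_set_size(self):
        p = PopulationParams(100.0, 0.3)
        assert expected_rates(p, CIRC, 33.0, 1).sum() == pytest.approx(100.0, rel=1e-12)
        assert expected_rates(p, CIRC, 33.0, 5).sum() == pytest.approx(20.0, rel=1e-12)

    @given(
        gain=st.floats(1.0, 100.0),
        width=st.floats(0.1, 1.0),
        theta=st.floats(0.0, 179.9),
        set_size=st.integers(1, 5),
    )
    def test_normalization_conserved_circular(self, gain, width, theta, set_size):
        p = PopulationParams(gain, width)
        total = expected_rates(p, CIRC, theta, set_size).sum()
        assert total == pytest.approx(gain / set_size, rel=1e-10)

    @given(
        gain=st.floats(0.1, 1000.0),
        width=st.floats(0.5, 10.0),
        theta=st.floats(0.0, 100.0),
        set_size=st.integers(1, 5),
    )
    def test_normalization_conserved_bounded_even_at_edges(self, gain, width, theta, set_size):
        p = PopulationParams(gain, width)
        total = expected_rates(p, BOUND, theta, set_size).sum()
        assert total == pytest.approx(gain / set_size, rel=1e-10)

    def test_preferred_neuron_has_maximal_rate(self):
        # brute-force comparison of all rates at a neuron's own preferred value
        p = PopulationParams(50.0, 0.4, n_neurons=200)
        centers = preferred_values(CIRC, 200)
        k = 57
        rates = expected_rates(p, CIRC, centers[k], 1)
        assert int(np.argmax(rates)) == k

    def test_zero_set_size_rejected(self):
        with pytest.raises(ValueError):
            expected_rates(PopulationParams(10.0, 0.3), CIRC, 10.0, 0)

    def test_bounded_preferred_values_span_interval_inclusive(self):
        c = preferred_values(BOUND, 11)
        assert c[0] == 0.0 and c[-1] == 100.0
        assert np.allclose(np.diff(c), 10.0)


class TestSampleSpikes:
    def test_zero_rates_give_zero_counts(self, rng):
        assert sample_spikes(np.zeros(10), rng).sum() == 0

    def test_same_seed_reproduces_pattern(self):
        rates = expected_rates(PopulationParams(80.0, 0.3), CIRC, 45.0, 1)
        a = sample_spikes(rates, np.random.default_rng(7))
        b = sample_spikes(rates, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_negative_rates_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_spikes(np.array([1.0, -0.1]), rng)

    def test_sample_mean_matches_rate(self, rng):
        # Monte-Carlo oracle: mean of 1e5 draws within 3 SE of the rate
        rates = np.array([0.3, 2.0, 7.5])
        draws = rng.poisson(rates, size=(100_000, 3))
        se = np.sqrt(rates / 100_000)
        assert np.all(np.abs(draws.mean(axis=0) - rates) < 3 * se)


class TestLogLikelihoodGrid:
    def test_flat_for_zero_spikes(self):
        p = PopulationParams(40.0, 0.3)
        ll = log_likelihood_grid(np.zeros(p.n_neurons, dtype=int), p, CIRC, 2)
        assert np.ptp(ll) < 1e-10

    def test_single_spike_peaks_at_that_neuron(self):
        p = PopulationParams(40.0, 0.3)
        centers = preferred_values(CIRC, p.n_neurons)
        spikes = np.zeros(p.n_neurons, dtype=int)
        k = 400
        spikes[k] = 1
        grid = decoding_grid(CIRC)
        ll = log_likelihood_grid(spikes, p, CIRC, 1, grid)
        best = grid[np.argmax(ll)]
        # brute-force argmax oracle: nearest grid point to the neuron's center
        nearest = grid[np.argmin(np.abs(grid - centers[k]))]
        assert best == pytest.approx(nearest, abs=1.0)

    def test_doubling_counts_moves_argmax_at_most_one_step(self, rng):
        p = PopulationParams(60.0, 0.4)
        spikes = sample_spikes(expected_rates(p, CIRC, 77.0, 1), rng)
        grid = decoding_grid(CIRC)
        i1 = np.argmax(log_likelihood_grid(spikes, p, CIRC, 1, grid))
        i2 = np.argmax(log_likelihood_grid(spikes * 2, p, CIRC, 1, grid))
        assert abs(int(i1) - int(i2)) <= 1

    def test_matches_scipy_poisson_logpmf_argmax(self, rng):
        # independent oracle: full Poisson pmf including factorial terms
        for space, width in ((CIRC, 0.35), (BOUND, 8.0)):
            p = PopulationParams(50.0, width, n_neurons=300)
            tgt = 60.0
            spikes = sample_spikes(expected_rates(p, space, tgt, 2), rng)
            grid = decoding_grid(space)
            ll = log_likelihood_grid(spikes, p, space, 2, grid)
            rates = expected_rates(p, space, grid, 2)
            oracle = sstats.poisson.logpmf(spikes, rates).sum(axis=1)
            assert int(np.argmax(ll)) == int(np.argmax(oracle))


class TestDecoders:
    def test_decode_ml_is_loglik_argmax(self, rng):
        p = PopulationParams(30.0, 0.4)
        spikes = sample_spikes(expected_rates(p, CIRC, 120.0, 1), rng)
        grid = decoding_grid(CIRC)
        ll = log_likelihood_grid(spikes, p, CIRC, 1, grid)
        assert decode_ml(spikes, p, CIRC, 1, grid) == grid[np.argmax(ll)]

    def test_zero_spikes_tie_break_lowest_grid_point(self):
        p = PopulationParams(30.0, 0.4)
        grid = decoding_grid(CIRC)
        assert decode_ml(np.zeros(p.n_neurons, dtype=int), p, CIRC, 1, grid) == grid[0]

    def test_high_gain_decodes_within_one_tuning_width(self, rng):
        p = PopulationParams(10_000.0, 0.3)
        tgt = 58.0
        resp = simulate_responses(p, CIRC, tgt, 1, "ml", 1000, rng)
        err_doubled = np.abs(CIRC.to_doubled_radians(CIRC.signed_error(tgt, resp)))
        assert np.mean(err_doubled <= 0.3) >= 0.99

    def test_posterior_equals_prior_for_zero_spikes(self):
        for space, width in ((CIRC, 0.3), (BOUND, 10.0)):
            p = PopulationParams(50.0, width)
            prior = PriorDistribution.uniform(space)
            post = posterior_probabilities(
                np.zeros(p.n_neurons, dtype=int), p, space, 3, prior
            )
            assert np.max(np.abs(post - prior.weights)) < 1e-12

    def test_point_mass_prior_always_returns_that_value(self, rng):
        p = PopulationParams(50.0, 10.0)
        prior = PriorDistribution.point_mass(BOUND, 42.0)
        spikes = sample_spikes(expected_rates(p, BOUND, 80.0, 1), rng)
        for _ in range(5):
            assert decode_posterior_sample(spikes, p, BOUND, 1, prior, rng) == 42.0

    def test_posterior_argmax_equals_ml_under_uniform_prior(self, rng):
        p = PopulationParams(60.0, 0.35)
        prior = PriorDistribution.uniform(CIRC)
        for _ in range(20):
            spikes = sample_spikes(expected_rates(p, CIRC, rng.uniform(0, 180), 2), rng)
            post = posterior_probabilities(spikes, p, CIRC, 2, prior)
            assert prior.grid[np.argmax(post)] == decode_ml(spikes, p, CIRC, 2)

    @settings(max_examples=10)
    @given(seed=st.integers(0, 10_000))
    def test_posterior_sampling_mode_matches_ml_at_high_gain(self, seed):
        rng = np.random.default_rng(seed)
        p = PopulationParams(5000.0, 10.0)
        prior = PriorDistribution.uniform(BOUND)
        spikes = sample_spikes(expected_rates(p, BOUND, 30.0, 1), rng)
        draws = [decode_posterior_sample(spikes, p, BOUND, 1, prior, rng) for _ in range(200)]
        vals, counts = np.unique(draws, return_counts=True)
        assert vals[np.argmax(counts)] == pytest.approx(
            decode_ml(spikes, p, BOUND, 1), abs=1.0
        )


class TestSetSizeEffect:
    @pytest.mark.parametrize(
        "space,width,decoder",
        [(CIRC, 0.3, "ml"), (BOUND, 10.0, "posterior_sampling")],
    )
    def test_dispersion_grows_with_load(self, space, width, decoder):
        from popmem import dispersion

        sds = []
        for n in (1, 5):
            rng = np.random.default_rng(100 + n)
            tgt = 90.0 if isinstance(space, CircularSpace) else 46.0
            resp = simulate_responses(
                PopulationParams(50.0, width), space, tgt, n, decoder, 4000, rng
            )
            sds.append(dispersion(space.signed_error(tgt, resp), space))
        assert sds[1] > sds[0]
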