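"""Predicted distributions, trial likelihood, grids, AIC and grid search."""

import numpy as np
import pandas as pd
import pytest

import popmem as pm
from popmem import _engine
from popmem.fitting import (
    TASKS,
    aic,
    default_grids,
    grid_search_fit,
    predict_distribution,
    task_defaults,
    trial_log_likelihood,
)

CIRC = pm.CircularSpace(180.0)
BOUND = pm.BoundedSpace(0.0, 100.0)


class TestPredictDistribution:
    @pytest.mark.parametrize(
        "space,width,decoder,n_bins",
        [(CIRC, 0.4, "ml", 40), (BOUND, 8.0, "posterior_sampling", 20)],
    )
    def test_probabilities_sum_to_one_with_floor(self, space, width, decoder, n_bins, rng):
        dist = predict_distribution(
            pm.PopulationParams(20.0, width), space, 46.0, 3, decoder, 2000, n_bins, rng
        )
        assert dist.probabilities.sum() == pytest.approx(1.0)
        assert dist.probabilities.min() >= 1.0 / (2000 + n_bins) - 1e-15

    def test_task_defaults_carry_published_settings(self):
        ori = task_defaults("orientation_sampling")
        assert ori["n_sim"] == 10_000 and ori["n_bins"] == 40
        expr = task_defaults("expression_sampling")
        assert expr["n_sim"] == 100_000 and expr["n_bins"] == 20


class TestDefaultGrids:
    def test_orientation_sampling_grids(self):
        gains, widths = default_grids("orientation_sampling")
        assert len(gains) == 50
        assert gains[0] == pytest.approx(0.1) and gains[-1] == pytest.approx(1000.0)
        assert len(widths) == 20
        assert widths[0] == pytest.approx(0.1) and widths[-1] == pytest.approx(1.0)

    def test_expression_sampling_grids(self):
        gains, widths = default_grids("expression_sampling")
        assert len(gains) == 50 and len(widths) == 50
        assert widths[0] == pytest.approx(0.01) and widths[-1] == pytest.approx(10.0)

    def test_orientation_ml_grids_span_two_decades_of_concentration(self):
        gains, widths = default_grids("orientation_ml")
        assert len(gains) == 60 and len(widths) == 60
        assert gains[0] == pytest.approx(1.0) and gains[-1] == pytest.approx(100.0)
        # widths expose kappa in [1, 100] as omega = 1/sqrt(kappa)
        kappas = np.sort(1.0 / widths**2)
        assert kappas[0] == pytest.approx(1.0) and kappas[-1] == pytest.approx(100.0)

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            default_grids("colour_ml")


class TestAic:
    def test_closed_form(self):
        assert aic(-100.0, 2) == pytest.approx(204.0)
        assert aic(0.0, 0) == 0.0

    def test_delta_antisymmetric(self):
        a, b = aic(-50.0), aic(-61.5)
        assert (a - b) == pytest.approx(-(b - a))


def _bounded_trials():
    return pd.DataFrame(
        {
            "target": [46.0, 46.0, 91.0],
            "response": [50.0, 39.0, 80.0],
            "set_size": [2, 2, 2],
        }
    )


class TestTrialLogLikelihood:
    def test_single_trial_is_log_bin_probability(self, rng):
        params = pm.PopulationParams(20.0, 8.0)
        trials = _bounded_trials().iloc[:1]
        ll = trial_log_likelihood(
            trials, params, BOUND, "posterior_sampling", 2000, 20, seed=5
        )
        sub_rng = np.random.default_rng(np.random.SeedSequence(5, spawn_key=(0,)))
        dist = predict_distribution(
            params, BOUND, 46.0, 2, "posterior_sampling", 2000, 20, sub_rng
        )
        assert ll == pytest.approx(float(dist.log_prob(46.0, 50.0)))

    def test_duplicated_trials_double_the_likelihood(self):
        params = pm.PopulationParams(20.0, 8.0)
        trials = _bounded_trials()
        ll1 = trial_log_likelihood(trials, params, BOUND, "posterior_sampling", 2000, 20, seed=5)
        ll2 = trial_log_likelihood(
            pd.concat([trials, trials], ignore_index=True),
            params, BOUND, "posterior_sampling", 2000, 20, seed=5,
        )
        assert ll2 == pytest.approx(2.0 * ll1)

    def test_matches_naive_per_trial_recomputation(self):
        # brute-force oracle without the unique-condition cache
        params = pm.PopulationParams(20.0, 8.0)
        trials = _bounded_trials()
        ll = trial_log_likelihood(trials, params, BOUND, "posterior_sampling", 2000, 20, seed=9)
        keys = sorted({(float(t), int(n)) for t, n in zip(trials["target"], trials["set_size"])})
        naive = 0.0
        for _, row in trials.iterrows():
            k_idx = keys.index((float(row["target"]), int(row["set_size"])))
            sub_rng = np.random.default_rng(np.random.SeedSequence(9, spawn_key=(k_idx,)))
            dist = predict_distribution(
                params, BOUND, float(row["target"]), int(row["set_size"]),
                "posterior_sampling", 2000, 20, sub_rng,
            )
            naive += float(dist.log_prob(row["target"], row["response"]))
        assert ll == pytest.approx(naive)

    def test_out_of_range_response_rejected(self):
        trials = _bounded_trials()
        trials.loc[0, "response"] = 120.0
        with pytest.raises(ValueError):
            trial_log_likelihood(
                trials, pm.PopulationParams(20.0, 8.0), BOUND,
                "posterior_sampling", 1000, 20, seed=0,
            )


def _synthetic_orientation_data(gain, width, n_per_set=150, seed=0):
    rng = np.random.default_rng(seed)
    design = pm.design_exp1b(1, rng, n_trials_per_set=n_per_set)
    model = pm.GeneratingModel(orientation_gain=gain, orientation_width=width)
    return pm.probed_trials(pm.generate_responses(design, model, rng))


class TestGridSearchFit:
    def test_best_parameters_attain_grid_maximum(self):
        data = _synthetic_orientation_data(6.0, 0.45, seed=1)
        fit = grid_search_fit(
            data, "orientation_ml",
            gain_grid=np.logspace(0.3, 1.3, 7), width_grid=np.logspace(-0.7, -0.1, 5),
            n_sim=1000, seed=2,
        )
        i = int(np.argmin(np.abs(fit.gain_grid - fit.best_gain)))
        j = int(np.argmin(np.abs(fit.width_grid - fit.best_width)))
        assert fit.grid_loglik[i, j] == fit.grid_loglik.max()
        assert fit.log_likelihood == fit.grid_loglik.max()
        assert fit.aic == pytest.approx(4.0 - 2.0 * fit.log_likelihood)

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            grid_search_fit(pd.DataFrame(columns=["target", "response", "set_size"]),
                            "orientation_ml")

    def test_stratified_and_direct_engines_agree(self):
        # same estimand: argmaxes land within one grid step of each other
        data = _synthetic_orientation_data(6.0, 0.45, n_per_set=250, seed=3)
        gains = np.logspace(0.4, 1.2, 6)
        widths = np.logspace(-0.6, -0.15, 5)
        fits = {
            engine: grid_search_fit(
                data, "orientation_ml", gain_grid=gains, width_grid=widths,
                n_sim=3000, seed=4, engine=engine,
            )
            for engine in ("stratified", "direct")
        }
        gi = {e: np.argmin(np.abs(gains - f.best_gain)) for e, f in fits.items()}
        wi = {e: np.argmin(np.abs(widths - f.best_width)) for e, f in fits.items()}
        assert abs(int(gi["stratified"]) - int(gi["direct"])) <= 1
        assert abs(int(wi["stratified"]) - int(wi["direct"])) <= 1

    def test_likelihood_higher_at_truth_than_far_away(self):
        data = _synthetic_orientation_data(8.0, 0.4, n_per_set=300, seed=5)
        gains = np.array([2.0, 8.0, 32.0])
        widths = np.array([0.4])
        fit = grid_search_fit(
            data, space=CIRC, decoder="ml", gain_grid=gains, width_grid=widths,
            n_sim=3000, n_bins=40, seed=6,
        )
        assert fit.grid_loglik[1, 0] > fit.grid_loglik[0, 0]
        assert fit.grid_loglik[1, 0] > fit.grid_loglik[2, 0]

    def test_grouped_fit_recovers_emotion_gain_ordering(self):
        rng = np.random.default_rng(8)
        design = pm.design_exp1a(1, rng)
        data = pm.probed_trials(pm.generate_responses(design, pm.GeneratingModel(), rng))
        data = data[data["emotion"].isin(["happy", "sad"])]
        table, fits = pm.fit_grouped(
            data, "expression_sampling", groupby=["emotion"], seed=9,
            gain_grid=np.logspace(-0.3, 1.8, 15), width_grid=np.logspace(0.3, 1.0, 8),
            n_sim=2000,
        )
        t = table.set_index("emotion")
        assert t.loc["happy", "gain"] > t.loc["sad", "gain"]
        assert ("happy",) in fits and ("sad",) in fits


class TestEngineConsistency:
    def test_sufficient_statistic_scores_match_generic_likelihood(self, rng):
        # the fast path's score vector differs from the generic Poisson
        # log-likelihood only by theta-independent terms
        for space, width in ((CIRC, 0.4), (BOUND, 7.0)):
            params = pm.PopulationParams(30.0, width, n_neurons=400)
            grid = pm.decoding_grid(space)
            spikes = pm.sample_spikes(pm.expected_rates(params, space, 60.0, 1), rng)
            ll = pm.log_likelihood_grid(spikes, params, space, 1, grid)
            centers = pm.preferred_values(space, 400)
            gf = _engine._grid_features(space, width, grid, 400)
            if isinstance(space, pm.CircularSpace):
                cv = space.to_doubled_radians(centers)
                stats = (np.array([np.sum(spikes * np.cos(cv))]),
                         np.array([np.sum(spikes * np.sin(cv))]))
            else:
                stats = (np.array([float(spikes.sum())]),
                         np.array([float(np.sum(spikes * centers))]))
            score = _engine._scores(space, width, stats, gf)[0]
            diff = ll - score
            assert np.ptp(diff) < 1e-6 * max(1.0, np.ptp(ll))

    def test_simulate_batch_matches_per_trial_decoding_distribution(self, rng):
        # batch sampler vs public per-pattern pipeline: same first two moments
        params = pm.PopulationParams(40.0, 8.0)
        grid = pm.decoding_grid(BOUND)
        batch = pm.simulate_responses(params, BOUND, 30.0, 1, "ml", 3000, rng)
        singles = []
        for _ in range(400):
            spikes = pm.sample_spikes(pm.expected_rates(params, BOUND, 30.0, 1), rng)
            singles.append(pm.decode_ml(spikes, params, BOUND, 1, grid))
        singles = np.array(singles)
        assert batch.mean() == pytest.approx(singles.mean(), abs=3 * singles.std() / 20 + 0.2)
        assert batch.std() == pytest.approx(singles.std(), rel=0.25)
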