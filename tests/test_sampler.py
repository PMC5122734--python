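"""MAP initialization and MCMC sampling contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hierddm import (CohortConfig, DDMParameters, build_spec, find_map,
                     generate_cohort, run_chains, simulate_trials)
from hierddm.model import PARAM_LOWER, Priors
from hierddm._kernels import run_mcmc_task

from conftest import make_trials


def _trials_from_sim(ts, subject="s1", group="young", task="letter"):
    ok = ts.boundary >= 0
    return make_trials([(subject, group, task, "target", bool(b == 1), rt * 1000)
                        for rt, b in zip(ts.rt[ok], ts.boundary[ok])])


class TestFindMap:
    def test_empty_data_returns_prior_mode(self):
        spec = build_spec(("letter",), ("young",))
        state = find_map(spec, make_trials([]))
        np.testing.assert_allclose(state.tasks["letter"].mu[0],
                                   Priors().loc, rtol=1e-12)

    def test_single_subject_recovery_within_ten_percent(self):
        truth = DDMParameters(t_nd=0.42, a=1.8, v=2.4)
        ts = simulate_trials(truth, 500, seed=17)
        spec = build_spec(("letter",), ("young",))
        state = find_map(spec, _trials_from_sim(ts))
        est = state.tasks["letter"].theta[0]
        np.testing.assert_allclose(est, [0.42, 1.8, 2.4], rtol=0.10)

    def test_stability_across_seeds(self):
        """Two optimizations from different seeds end at nearly the same
        posterior height."""
        from hierddm import log_posterior
        truth = DDMParameters(t_nd=0.42, a=1.8, v=2.4)
        trials = _trials_from_sim(simulate_trials(truth, 300, seed=23))
        spec = build_spec(("letter",), ("young",))
        lp = [log_posterior(spec, find_map(spec, trials, seed=s), trials)
              for s in (0, 99)]
        assert abs(lp[0] - lp[1]) < 0.1


class TestRunChains:
    @pytest.fixture(scope="class")
    def small_fit(self):
        cfg = CohortConfig(group_sizes={"young": 5}, tasks=("letter",),
                           group_params={"letter": {"young": (0.40, 1.7, 2.5)}},
                           seed=31)
        trials, _ = generate_cohort(cfg)
        trials = trials.dropna(subset=["rt_ms"])
        spec = build_spec(("letter",), ("young",))
        init = find_map(spec, trials)
        samples = run_chains(spec, trials, init, n_chains=3, n_iterations=600,
                             burn_in=200, seed=12)
        return spec, trials, init, samples

    def test_retained_count_is_exact(self, small_fit):
        _, _, _, samples = small_fit
        assert samples.n_retained == 3 * (600 - 200)
        assert samples.retained.shape[:2] == (3, 400)

    def test_draws_respect_domains(self, small_fit):
        _, _, _, samples = small_fit
        for name in samples.param_names:
            x = samples.get(name, retained=False)
            if name.startswith(("mu_t", "mu_a", "sigma_", "t[", "a[")):
                assert np.all(x > 0), name

    def test_identical_seed_is_bit_identical(self, small_fit):
        spec, trials, init, samples = small_fit
        again = run_chains(spec, trials, init, n_chains=3, n_iterations=600,
                           burn_in=200, seed=12)
        np.testing.assert_array_equal(samples.draws, again.draws)

    def test_acceptance_rates_in_working_range(self, small_fit):
        _, _, _, samples = small_fit
        assert np.all(samples.acceptance > 0.01)
        # scalar blocks should sit near the adaptation target
        assert 0.05 < np.median(samples.acceptance) < 0.7

    def test_single_chain_refused(self, small_fit):
        spec, trials, init, _ = small_fit
        with pytest.raises(ValueError, match="n_chains"):
            run_chains(spec, trials, init, n_chains=1)

    def test_burn_in_must_be_shorter_than_run(self, small_fit):
        spec, trials, init, _ = small_fit
        with pytest.raises(ValueError, match="burn_in"):
            run_chains(spec, trials, init, n_iterations=100, burn_in=100)


class TestSamplerCorrectness:
    """With no trial data the sampler must reproduce the prior exactly:
    individual parameters integrate out, leaving the group locations
    distributed as their (truncated) normal priors and the spreads as
    half-normals.  This validates every proposal type, including the
    translation, ridge-scaling and funnel moves."""

    @pytest.fixture(scope="class")
    def prior_draws(self):
        S, G = 4, 1
        draws, _ = run_mcmc_task(
            np.empty(0), np.empty(0, np.int8), np.zeros(S, np.int64),
            np.zeros(S, np.int64), np.zeros(S, np.int64), G,
            np.tile(np.array([0.4, 2.0, 2.0]), (S, 1)),
            np.array([[0.4, 2.0, 2.0]]), np.array([[0.5, 0.5, 0.5]]),
            *Priors().arrays(), PARAM_LOWER, 30000, 4000, 0.3, 123, 1e-7)
        return draws[4000:]

    @pytest.mark.parametrize("p", [0, 1, 2])
    def test_location_marginal_matches_prior(self, prior_draws, p):
        loc, scale, lower, _ = Priors().arrays()
        if np.isfinite(lower[p]):
            ref = stats.truncnorm((lower[p] - loc[p]) / scale[p], np.inf,
                                  loc=loc[p], scale=scale[p])
        else:
            ref = stats.norm(loc[p], scale[p])
        x = prior_draws[:, p]
        assert x.mean() == pytest.approx(ref.mean(), abs=0.06 * ref.std())
        assert x.std() == pytest.approx(ref.std(), rel=0.08)

    def test_spread_marginal_matches_half_normal(self, prior_draws):
        sg = prior_draws[:, 3:6]
        assert sg.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.05)

    def test_moments_tighten_with_chain_length(self):
        """Monte-Carlo error of the location mean shrinks roughly as 1/sqrt(n)."""
        loc, scale, lower, spread = Priors().arrays()
        S = 2

        def mean_err(n_iter, seed):
            draws, _ = run_mcmc_task(
                np.empty(0), np.empty(0, np.int8), np.zeros(S, np.int64),
                np.zeros(S, np.int64), np.zeros(S, np.int64), 1,
                np.tile(np.array([0.4, 2.0, 2.0]), (S, 1)),
                np.array([[0.4, 2.0, 2.0]]), np.array([[0.5, 0.5, 0.5]]),
                loc, scale, lower, spread, PARAM_LOWER,
                n_iter, 1000, 0.3, seed, 1e-7)
            return draws[1000:, 2].mean() - 2.0  # mu_v prior mean is 2

        short = [abs(mean_err(3000, s)) for s in range(41, 47)]
        long = [abs(mean_err(19000, s)) for s in range(41, 47)]
        assert np.median(long) < np.median(short)
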