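"""First-passage density, closed forms and simulator consistency."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from hierddm import (DDMParameters, mean_decision_time, prob_upper,
                     simulate_trials, wfpt_log_density)
from hierddm.wfpt import ParameterDomainError

# parameter corners spanning the fitted range of the four reading tasks
TASK_PARAMS = [
    (0.376, 1.62, 3.58),  # letter identification, young
    (0.426, 1.59, 2.52),  # lexical decision, young
    (0.537, 2.08, 1.29),  # phonological decision, young
    (0.641, 2.17, 1.10),  # phonological decision, low-performing older
    (0.453, 1.92, 3.18),  # letter identification, high-performing older
]


def _density(params, boundary):
    return lambda rt: math.exp(wfpt_log_density(rt, boundary, params))


class TestDensity:
    def test_zero_before_nondecision_time(self):
        p = DDMParameters(t_nd=0.376, a=1.62, v=3.58)
        for boundary in ("upper", "lower"):
            assert wfpt_log_density(0.3, boundary, p) == -np.inf
            assert wfpt_log_density(0.376, boundary, p) == -np.inf

    @pytest.mark.parametrize("t_nd,a,v", TASK_PARAMS)
    def test_total_mass_is_one(self, t_nd, a, v):
        """Upper plus lower defective densities integrate to 1."""
        p = DDMParameters(t_nd=t_nd, a=a, v=v)
        up, _ = quad(_density(p, "upper"), t_nd, t_nd + 30, limit=300)
        lo, _ = quad(_density(p, "lower"), t_nd, t_nd + 30, limit=300)
        assert up + lo == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("t_nd,a,v", TASK_PARAMS[:3])
    def test_upper_mass_matches_absorption_probability(self, t_nd, a, v):
        p = DDMParameters(t_nd=t_nd, a=a, v=v)
        up, _ = quad(_density(p, "upper"), t_nd, t_nd + 30, limit=300)
        assert up == pytest.approx(prob_upper(p), abs=1e-4)

    def test_reflection_symmetry(self):
        """With an unbiased start, swapping boundary and negating v is a no-op."""
        grid = np.linspace(0.05, 3.0, 40)
        p_pos = DDMParameters(t_nd=0.0, a=1.8, v=2.2)
        p_neg = DDMParameters(t_nd=0.0, a=1.8, v=-2.2)
        np.testing.assert_allclose(wfpt_log_density(grid, "upper", p_pos),
                                   wfpt_log_density(grid, "lower", p_neg),
                                   rtol=1e-9)

    def test_density_nonnegative_and_finite_on_grid(self):
        p = DDMParameters(t_nd=0.4, a=2.0, v=1.5)
        grid = np.linspace(0.401, 10.0, 200)
        ld = wfpt_log_density(grid, "upper", p)
        assert np.all(np.isfinite(ld) | (ld == -np.inf))
        assert np.all(np.exp(ld[np.isfinite(ld)]) >= 0)

    def test_invalid_tolerance_rejected(self):
        p = DDMParameters(t_nd=0.3, a=1.5, v=2.0)
        with pytest.raises(ValueError, match="tol"):
            wfpt_log_density(1.0, "upper", p, tol=0.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterDomainError):
            DDMParameters(t_nd=-0.1, a=1.5, v=2.0)
        with pytest.raises(ParameterDomainError):
            DDMParameters(t_nd=0.1, a=0.0, v=2.0)
        with pytest.raises(ParameterDomainError):
            DDMParameters(t_nd=0.1, a=1.5, v=2.0, z_rel=1.0)


class TestClosedForms:
    def test_prob_upper_unbiased_symmetry(self):
        assert prob_upper(DDMParameters(t_nd=0, a=2.0, v=0.0)) == pytest.approx(0.5)

    def test_prob_upper_letter_and_phonological_values(self):
        """1/(1+exp(-a v)) at the fitted young parameters."""
        assert prob_upper(DDMParameters(t_nd=0, a=1.62, v=3.58)) == pytest.approx(
            0.997, abs=5e-4)
        assert prob_upper(DDMParameters(t_nd=0, a=2.08, v=1.29)) == pytest.approx(
            0.936, abs=5e-4)

    def test_mean_decision_time_zero_drift_limit(self):
        assert mean_decision_time(DDMParameters(t_nd=0, a=2.0, v=0.0)) == pytest.approx(
            1.0, rel=1e-6)

    @pytest.mark.parametrize("t_nd,a,v,expected_ms", [
        (0.376, 1.62, 3.58, 601),   # letter identification mean RT
        (0.426, 1.59, 2.52, 730),   # lexical decision mean RT
    ])
    def test_mean_rt_matches_task_means(self, t_nd, a, v, expected_ms):
        p = DDMParameters(t_nd=t_nd, a=a, v=v)
        mean_rt = (mean_decision_time(p) + t_nd) * 1000
        assert mean_rt == pytest.approx(expected_ms, abs=1.0)

    def test_mean_decision_time_requires_unbiased_start(self):
        with pytest.raises(NotImplementedError):
            mean_decision_time(DDMParameters(t_nd=0, a=2.0, v=1.0, z_rel=0.4))


@pytest.fixture(scope="module")
def big_sim():
    p = DDMParameters(t_nd=0.376, a=1.62, v=3.58)
    return p, simulate_trials(p, 100_000, deadline=None, seed=42)


class TestSimulator:
    def test_choice_fraction_matches_closed_form(self, big_sim):
        p, ts = big_sim
        frac_up = np.mean(ts.boundary == 1)
        assert frac_up == pytest.approx(prob_upper(p), abs=0.005)

    def test_mean_decision_time_matches_closed_form(self, big_sim):
        p, ts = big_sim
        mean_dt = ts.rt.mean() - p.t_nd
        assert mean_dt == pytest.approx(mean_decision_time(p), rel=0.02)

    def test_rt_exceeds_nondecision_time(self, big_sim):
        p, ts = big_sim
        assert np.all(ts.rt > p.t_nd)

    def test_deadline_marks_nonresponses(self):
        p = DDMParameters(t_nd=0.537, a=2.08, v=1.29)  # slowest task params
        ts = simulate_trials(p, 20_000, deadline=3.0, seed=7)
        frac_none = np.mean(ts.boundary == -1)
        assert 0 < frac_none < 0.02
        assert np.all(np.isnan(ts.rt[ts.boundary == -1]))
        assert np.nanmax(ts.rt) <= 3.0 + 1e-3

    def test_seed_reproducibility(self):
        p = DDMParameters(t_nd=0.4, a=1.8, v=2.0)
        a = simulate_trials(p, 500, seed=3)
        b = simulate_trials(p, 500, seed=3)
        np.testing.assert_array_equal(a.rt, b.rt)
        np.testing.assert_array_equal(a.boundary, b.boundary)

    def test_rejects_bad_arguments(self):
        p = DDMParameters(t_nd=0.4, a=1.8, v=2.0)
        with pytest.raises(ValueError):
            simulate_trials(p, 0)
        with pytest.raises(ValueError, match="deadline"):
            simulate_trials(p, 10, deadline=0.3)
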