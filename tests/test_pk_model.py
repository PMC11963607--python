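"""Unit and property tests of the structural/stochastic PK model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from neopta import (
    CovariateTerm,
    DoseEvent,
    IndividualParameters,
    NeonateCovariates,
    PopulationParameters,
    assess_first_interval,
    auc_to,
    concentration,
    individual_parameters,
    simulate_observation,
)
from neopta.model import ConfigurationError, concentration_profile

COV = NeonateCovariates(ga_weeks=30, pna_days=5, bw_birth_g=1400, bw_current_g=1400)
IP2 = IndividualParameters(CL=0.05, V1=0.9, Q=0.01, V2=0.6)
DOSES = [DoseEvent(0.0, 16.0, 0.5)]


class TestIndividualParameters:
    def test_identity_without_covariates(self):
        pop = PopulationParameters(theta_CL=0.06, theta_V1=0.8, sigma_add=0.4)
        ip = individual_parameters(pop, COV, (0.0, 0.0))
        assert ip.CL == pytest.approx(0.06)
        assert ip.V1 == pytest.approx(0.8)

    def test_power_term_centered_at_reference(self):
        term = CovariateTerm("CL", "power", "bw_birth_g", coefficient=1.34, reference=1400.0)
        pop = PopulationParameters(theta_CL=0.06, theta_V1=0.8, covariate_terms=(term,), sigma_add=0.4)
        ip = individual_parameters(pop, COV, (0.25, 0.0))
        assert ip.CL == pytest.approx(0.06 * math.exp(0.25))

    def test_fractional_change_hand_computed(self):
        # coefficient -0.2 with the flag set scales CL by 0.8 exactly
        term = CovariateTerm("CL", "fractional_change", "ibuprofen", coefficient=-0.2)
        pop = PopulationParameters(theta_CL=0.06, theta_V1=0.8, covariate_terms=(term,), sigma_add=0.4)
        cov_ibu = NeonateCovariates(
            ga_weeks=30, pna_days=5, bw_birth_g=1400, bw_current_g=1400, ibuprofen=True
        )
        assert individual_parameters(pop, cov_ibu).CL == pytest.approx(0.06 * 0.8)
        assert individual_parameters(pop, COV).CL == pytest.approx(0.06)

    def test_unknown_covariate_is_configuration_error(self):
        term = CovariateTerm("CL", "power", "head_circumference", coefficient=1.0, reference=30.0)
        pop = PopulationParameters(theta_CL=0.06, theta_V1=0.8, covariate_terms=(term,), sigma_add=0.4)
        with pytest.raises(ConfigurationError):
            individual_parameters(pop, COV)


class TestConcentration:
    def test_zero_before_first_dose(self):
        assert concentration(0.0, [DoseEvent(5.0, 16.0, 0.5)], IP2) == 0.0

    def test_short_infusion_approaches_bolus_amount_over_v1(self):
        ip = IndividualParameters(CL=0.05, V1=0.9)
        short = DoseEvent(0.0, 16.0, 1e-6)
        assert concentration(1e-6, [short], ip) == pytest.approx(16.0 / 0.9, rel=1e-4)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            concentration(-1.0, DOSES, IP2)

    def test_two_compartment_matches_ode_integration(self):
        def rhs(t, y):
            a1, a2 = y
            rate = 16.0 / 0.5 if t < 0.5 else 0.0
            return [
                rate - (IP2.CL + IP2.Q) / IP2.V1 * a1 + IP2.Q / IP2.V2 * a2,
                IP2.Q / IP2.V1 * a1 - IP2.Q / IP2.V2 * a2,
            ]

        t_eval = [1.0, 24.0, 36.0]
        sol = solve_ivp(rhs, [0, 36], [0, 0], t_eval=t_eval, rtol=1e-10, atol=1e-12, max_step=0.25)
        ana = np.array([concentration(t, DOSES, IP2) for t in t_eval])
        assert np.allclose(ana, sol.y[0] / IP2.V1, rtol=1e-3)  # within 0.1%

    def test_one_compartment_limit_equals_closed_form(self):
        ip = IndividualParameters(CL=0.05, V1=0.9, Q=0.0, V2=0.0)
        k, rate, T = ip.CL / ip.V1, 16.0 / 0.5, 0.5
        t = np.array([0.2, 0.5, 3.0, 30.0])
        ref = np.where(
            t <= T,
            rate / ip.CL * (1 - np.exp(-k * t)),
            rate / ip.CL * (1 - np.exp(-k * T)) * np.exp(-k * (t - T)),
        )
        got = concentration_profile(t, DOSES, ip.CL, ip.V1, ip.Q, ip.V2)
        assert np.allclose(got, ref, rtol=1e-10)

    def test_superposition_and_dose_linearity(self):
        d1, d2 = DoseEvent(0, 16, 0.5), DoseEvent(36, 16, 0.5)
        t = np.array([1.0, 20.0, 37.0, 50.0])
        both = concentration_profile(t, [d1, d2], IP2.CL, IP2.V1, IP2.Q, IP2.V2)
        separate = concentration_profile(t, [d1], IP2.CL, IP2.V1, IP2.Q, IP2.V2) + \
            concentration_profile(t, [d2], IP2.CL, IP2.V1, IP2.Q, IP2.V2)
        assert np.allclose(both, separate, rtol=1e-12)
        scaled = [DoseEvent(0, 16 * 3.7, 0.5), DoseEvent(36, 16 * 3.7, 0.5)]
        assert np.allclose(
            concentration_profile(t, scaled, IP2.CL, IP2.V1, IP2.Q, IP2.V2), 3.7 * both, rtol=1e-12
        )


class TestAUC:
    def test_auc_infinity_equals_dose_over_clearance(self):
        assert auc_to(math.inf, DOSES, IP2) == pytest.approx(16.0 / IP2.CL, rel=1e-12)

    def test_finite_auc_strictly_below_total(self):
        assert auc_to(36.0, DOSES, IP2) < 16.0 / IP2.CL

    def test_auc_matches_fine_quadrature(self):
        ts = np.linspace(0.0, 36.0, 100_001)
        c = concentration_profile(ts, DOSES, IP2.CL, IP2.V1, IP2.Q, IP2.V2)
        quad = np.trapezoid(c, ts)
        assert auc_to(36.0, DOSES, IP2) == pytest.approx(quad, rel=1e-4)  # within 0.01%

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        cl=st.floats(0.01, 0.5),
        v1=st.floats(0.2, 2.0),
        q=st.floats(0.0, 0.3),
        v2=st.floats(0.05, 1.0),
        tau=st.floats(12.0, 48.0),
    )
    def test_auc_quadrature_property(self, cl, v1, q, v2, tau):
        ip = IndividualParameters(CL=cl, V1=v1, Q=q, V2=v2)
        ts = np.linspace(0.0, tau, 100_001)
        quad = np.trapezoid(concentration_profile(ts, DOSES, cl, v1, q, v2), ts)
        assert auc_to(tau, DOSES, ip) == pytest.approx(quad, rel=1e-4)


class TestAssessFirstInterval:
    def test_metrics_and_invariants(self):
        a = assess_first_interval(DOSES, IP2, tau=36.0)
        assert a.cmax_mg_L == pytest.approx(concentration(1.0, DOSES, IP2))
        assert a.cmin_mg_L == pytest.approx(concentration(36.0, DOSES, IP2))
        assert a.cmin_mg_L <= a.cmax_mg_L
        assert a.auc_0_tau_mg_h_L == pytest.approx(auc_to(36.0, DOSES, IP2))

    def test_second_dose_does_not_leak_into_first_interval(self):
        two = [DoseEvent(0, 16, 0.5), DoseEvent(36, 16, 0.5)]
        a1 = assess_first_interval(DOSES, IP2, tau=36.0)
        a2 = assess_first_interval(two, IP2, tau=36.0)
        assert a1 == a2

    def test_tau_shorter_than_infusion_rejected(self):
        with pytest.raises(ValueError):
            assess_first_interval(DOSES, IP2, tau=1.2)


class TestResidualError:
    def test_noise_free_passthrough_and_blq_boundary(self, pop):
        silent = pop.with_updates(sigma_prop=1e-12, sigma_add=0.0)
        rng = np.random.default_rng(0)
        y, blq = simulate_observation(0.79, silent, rng)
        assert y == pytest.approx(0.79) and blq
        y, blq = simulate_observation(0.81, silent, rng)
        assert y == pytest.approx(0.81) and not blq

    def test_zero_concentration_always_blq(self):
        # with assay-scale additive noise a true zero never quantifies
        pop = PopulationParameters(theta_CL=0.06, theta_V1=0.8, sigma_prop=0.1, sigma_add=0.2)
        rng = np.random.default_rng(1)
        y, blq = simulate_observation(np.zeros(500), pop, rng)
        assert blq.all() and (y >= 0).all()

    def test_mean_unbiased_over_many_draws(self):
        pop = PopulationParameters(theta_CL=0.06, theta_V1=0.8, sigma_prop=0.1, sigma_add=0.5)
        rng = np.random.default_rng(7)
        y, _ = simulate_observation(np.full(100_000, 20.0), pop, rng)
        se = math.sqrt(0.1**2 * 400 + 0.25) / math.sqrt(100_000)
        assert abs(y.mean() - 20.0) < 3 * se
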