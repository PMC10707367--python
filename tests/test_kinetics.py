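"""Analytic two-pool model: solution, closed-form FCR, fluxes, PR."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from hdlturnover import (DomainError, FluxSet, KineticRateSet,
                         PoolConcentrations, TurnoverSummary,
                         ValidationError, fcr_closed_form, mass_fluxes,
                         production_rate, solve_model)
from conftest import random_rate_sets


def _ode_oracle(rates, times):
    """Stiff ODE integration of the same system, independent of the
    eigen-decomposition route."""
    sol = solve_ivp(lambda t, q: rates.rate_matrix() @ q, (0, times[-1]),
                    [100.0, 0.0], t_eval=times, method="LSODA",
                    rtol=1e-12, atol=1e-12)
    return sol.y[0], sol.y[1]


class TestSolveModel:
    def test_closed_system_is_constant(self):
        curve = solve_model(KineticRateSet(0, 0, 0, 0), [0, 60, 300])
        assert np.array_equal(curve.hdl_activity, [100, 100, 100])
        assert np.array_equal(curve.vldl_activity, [0, 0, 0])

    def test_monoexponential_limit(self):
        curve = solve_model(KineticRateSet(0, 0, 0.01, 0), [0, 60])
        assert curve.hdl_activity[1] == pytest.approx(100 * math.exp(-0.6),
                                                      rel=1e-12)
        assert curve.vldl_activity[1] == 0.0

    def test_matches_ode_oracle_at_study_times(self, sham_rates,
                                               study_times):
        curve = solve_model(sham_rates, study_times)
        q1, q2 = _ode_oracle(sham_rates, study_times)
        np.testing.assert_allclose(curve.hdl_activity, q1, rtol=1e-8)
        np.testing.assert_allclose(curve.vldl_activity[1:], q2[1:],
                                   rtol=1e-8)

    @pytest.mark.parametrize("rates", random_rate_sets(20, seed=11),
                             ids=lambda r: f"{r.k_hdl_out:.2e}")
    def test_matches_ode_oracle_random(self, rates, study_times):
        curve = solve_model(rates, study_times)
        q1, q2 = _ode_oracle(rates, study_times)
        np.testing.assert_allclose(curve.hdl_activity, q1, rtol=1e-8,
                                   atol=1e-10)
        np.testing.assert_allclose(curve.vldl_activity, q2, rtol=1e-8,
                                   atol=1e-10)

    def test_repeated_eigenvalue_branch(self, study_times):
        # k_hdl_to_vldl = 0 with equal diagonal entries makes the rate
        # matrix's eigenvalue exactly double.
        rates = KineticRateSet(k_hdl_to_vldl=0.0, k_vldl_to_hdl=0.001,
                               k_hdl_out=0.004, k_vldl_out=0.003)
        m = rates.rate_matrix()
        assert m[0, 0] == m[1, 1] and m[1, 0] == 0.0
        curve = solve_model(rates, study_times)
        q1, q2 = _ode_oracle(rates, study_times)
        np.testing.assert_allclose(curve.hdl_activity, q1, rtol=1e-8)
        np.testing.assert_allclose(curve.vldl_activity, q2, rtol=1e-8,
                                   atol=1e-12)

    def test_conservation_of_dose(self, study_times):
        # q1 + q2 + cumulative removal must stay at 100% of the dose.
        for rates in random_rate_sets(10, seed=7):
            curve = solve_model(rates, study_times)

            def removal(t, r=rates):
                c = solve_model(r, [0.0, t] if t > 0 else [0.0])
                return (r.k_hdl_out * c.hdl_activity[-1]
                        + r.k_vldl_out * c.vldl_activity[-1])

            for i, t in enumerate(study_times[1:], start=1):
                removed, _ = quad(removal, 0, t, limit=200)
                total = (curve.hdl_activity[i] + curve.vldl_activity[i]
                         + removed)
                assert total == pytest.approx(100.0, abs=1e-6)

    def test_monotone_decay_without_backflow(self, study_times):
        rates = KineticRateSet(k_hdl_to_vldl=0.003, k_vldl_to_hdl=0.0,
                               k_hdl_out=0.002, k_vldl_out=0.001)
        curve = solve_model(rates, study_times)
        assert np.all(np.diff(curve.hdl_activity) < 0)

    def test_validation(self):
        with pytest.raises(ValidationError):
            KineticRateSet(-0.001, 0, 0, 0)
        with pytest.raises(ValidationError):
            solve_model(KineticRateSet(0, 0, 0.01, 0), [0, 60, 30])
        with pytest.raises(ValidationError):
            solve_model(KineticRateSet(0, 0, 0.01, 0), [5, 60])


class TestClosedFormFCR:
    def test_no_exchange_reduces_to_direct_removal(self):
        rates = KineticRateSet(0.0, 0.0, 0.004, 0.0)
        assert fcr_closed_form(rates) == pytest.approx(60 * 0.004)

    def test_sham_rate_set(self, sham_rates):
        assert fcr_closed_form(sham_rates) == pytest.approx(0.24, rel=1e-12)

    def test_ntx_rate_set(self, ntx_rates):
        assert fcr_closed_form(ntx_rates) == pytest.approx(0.14, rel=1e-12)

    def test_full_recycling_limit(self):
        # All tracer reaching VLDL/LDL returns, so only direct HDL removal
        # counts.
        rates = KineticRateSet(k_hdl_to_vldl=0.01, k_vldl_to_hdl=0.005,
                               k_hdl_out=0.003, k_vldl_out=0.0)
        assert fcr_closed_form(rates) == pytest.approx(60 * 0.003)

    def test_trapped_tracer_raises(self):
        # Transfer into VLDL/LDL with no exit from it: infinite residence.
        with pytest.raises(DomainError):
            fcr_closed_form(KineticRateSet(k_hdl_to_vldl=0.01,
                                           k_vldl_to_hdl=0.0,
                                           k_hdl_out=0.003,
                                           k_vldl_out=0.0))

    def test_closed_system_raises(self):
        with pytest.raises(DomainError):
            fcr_closed_form(KineticRateSet(0, 0, 0, 0))

    def test_equals_reciprocal_area_under_curve(self):
        # The defining property: FCR is 1/AUC of the normalized q1 curve.
        for rates in random_rate_sets(100, seed=13):
            def frac_remaining(t, r=rates):
                if t == 0:
                    return 1.0
                return solve_model(r, [0.0, t]).hdl_activity[-1] / 100.0

            auc_min, _ = quad(frac_remaining, 0, np.inf, limit=500)
            assert fcr_closed_form(rates) == pytest.approx(60.0 / auc_min,
                                                           rel=1e-6)


class TestMassFluxes:
    def test_sham_total_outflow_decomposition(self):
        fluxes = mass_fluxes(KineticRateSet(0, 0, 0.02, 0.01),
                             PoolConcentrations(590.0, 341.0))
        assert fluxes.flux_hdl_out == pytest.approx(11.80)
        assert fluxes.flux_vldl_out == pytest.approx(3.41)
        assert fluxes.total_outflow == pytest.approx(15.21)

    def test_ntx_total_outflow_decomposition(self):
        fluxes = mass_fluxes(KineticRateSet(0, 0, 0.01, 0.002),
                             PoolConcentrations(800.0, 560.0))
        assert fluxes.total_outflow == pytest.approx(9.12)

    def test_source_pool_convention(self):
        # Transfers out of HDL multiply the HDL pool, out of VLDL/LDL the
        # VLDL/LDL pool.
        fluxes = mass_fluxes(KineticRateSet(0.004, 0.003, 0.002, 0.001),
                             PoolConcentrations(1000.0, 200.0))
        assert fluxes.flux_hdl_to_vldl == pytest.approx(4.0)
        assert fluxes.flux_vldl_to_hdl == pytest.approx(0.6)
        assert fluxes.flux_hdl_out == pytest.approx(2.0)
        assert fluxes.flux_vldl_out == pytest.approx(0.2)

    def test_zero_pools_zero_fluxes(self, sham_rates):
        fluxes = mass_fluxes(sham_rates, PoolConcentrations(0.0, 0.0))
        assert fluxes.total_outflow == 0.0

    def test_total_outflow_identity_enforced(self):
        with pytest.raises(ValidationError):
            FluxSet(1.0, 1.0, 2.0, 1.0, total_outflow=4.0)


class TestProductionRate:
    def test_sham_worked_example(self):
        pr = production_rate(0.24, 698.7, body_weight_kg=3.2)
        assert pr == pytest.approx(5.50, abs=0.005)

    def test_zero_fcr(self):
        assert production_rate(0.0, 500.0, 3.0) == 0.0

    def test_direct_product_with_volume_constant(self):
        assert production_rate(1.0, 1000.0, 3.0) == pytest.approx(32.8)

    def test_body_weight_cancels(self):
        assert production_rate(0.2, 700.0, 3.0) == pytest.approx(
            production_rate(0.2, 700.0, 3.5))

    def test_invalid_weight(self):
        with pytest.raises(ValidationError):
            production_rate(0.2, 700.0, 0.0)

    def test_summary_consistency_enforced(self):
        TurnoverSummary(fcr_per_hour=0.24, ce_conc_mg_per_l=698.7,
                        body_weight_kg=3.2,
                        pr_mg_per_kg_per_hour=0.24 * 698.7 * 0.0328)
        with pytest.raises(ValidationError):
            TurnoverSummary(fcr_per_hour=0.24, ce_conc_mg_per_l=698.7,
                            body_weight_kg=3.2, pr_mg_per_kg_per_hour=9.99)
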