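"""Unit tests of the vector field building blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import sleepcortex as sc
from sleepcortex import model


class TestFiringRate:
    def test_midpoint_is_half_max(self, default_params):
        e = default_params.excitatory
        assert sc.firing_rate(e.theta, e) == pytest.approx(e.Qmax / 2)

    def test_saturation_limits(self, default_params):
        e = default_params.excitatory
        assert sc.firing_rate(e.theta + 1e3, e) == pytest.approx(e.Qmax)
        assert sc.firing_rate(e.theta - 1e3, e) == pytest.approx(0.0, abs=1e-12)

    def test_value_one_sigma_above_threshold(self, default_params):
        # hand evaluation of the logistic closed form at V = theta + sigma,
        # Qmax / (1 + exp(-pi/sqrt(3)))
        e = default_params.excitatory
        assert sc.firing_rate(e.theta + e.sigma, e) == pytest.approx(
            25.794613054388204, rel=1e-12)

    def test_rejects_non_finite_voltage(self, default_params):
        with pytest.raises(ValueError):
            sc.firing_rate(np.nan, default_params.excitatory)

    @settings(max_examples=50, deadline=None)
    @given(theta=st.floats(-80, -40), sigma=st.floats(1.0, 10.0),
           qmax=st.floats(10.0, 100.0))
    def test_bounded_and_monotone(self, theta, sigma, qmax):
        pop = sc.PopulationParameters(Qmax=qmax, theta=theta, sigma=sigma)
        # within +-8 sigma of threshold the logistic is strictly inside its
        # bounds even in double precision
        v = np.linspace(theta - 8 * sigma, theta + 8 * sigma, 201)
        q = sc.firing_rate(v, pop)
        assert np.all(q > 0) and np.all(q < qmax)
        assert np.all(np.diff(q) > 0)


class TestIKNa:
    def test_zero_at_reversal(self, default_params):
        a = default_params.adaptation
        assert sc.i_kna(a.E_K, 12.0, a) == 0.0

    def test_zero_conductance(self, default_params):
        a = sc.AdaptationParameters(g_KNa=0.0)
        for v, na in [(-80.0, 5.0), (-50.0, 20.0)]:
            assert sc.i_kna(v, na, a) == 0.0

    def test_value_at_pump_equilibrium(self):
        # g_KNa = 2 mS/cm^2 (deep-sleep regime), V = -60 mV, Na at the pump
        # equilibrium 9.5 mM: 2 * 0.37/(1+(38.7/9.5)^3.5) * 40
        a = sc.AdaptationParameters(g_KNa=2.0)
        assert sc.i_kna(-60.0, a.Na_eq, a) == pytest.approx(
            0.21535978970559866, rel=1e-12)

    def test_increasing_in_sodium_above_reversal(self, default_params):
        # self-inhibition: more sodium, more hyperpolarizing current
        a = default_params.adaptation
        na = np.linspace(5.0, 25.0, 50)
        cur = np.array([sc.i_kna(-55.0, x, a) for x in na])
        assert np.all(np.diff(cur) > 0)

    def test_rejects_non_positive_sodium(self, default_params):
        with pytest.raises(ValueError):
            sc.i_kna(-60.0, 0.0, default_params.adaptation)


class TestSodiumBalance:
    def test_pump_balance_at_equilibrium(self, default_params):
        a = default_params.adaptation
        assert sc.na_rate(a.Na_eq, 0.0, a) == pytest.approx(0.0, abs=1e-15)

    def test_pump_pulls_back_toward_equilibrium(self, default_params):
        a = default_params.adaptation
        assert sc.na_rate(a.Na_eq + 2.0, 0.0, a) < 0
        assert sc.na_rate(a.Na_eq - 2.0, 0.0, a) > 0

    def test_steady_state_against_root_find_oracle(self, default_params):
        # independent oracle: 1-D root finding on influx = pump efflux
        a = default_params.adaptation
        rate = 10.0  # s^-1
        oracle = brentq(lambda na: sc.na_rate(na, rate, a), 9.5, 30.0,
                        xtol=1e-12)
        assert oracle == pytest.approx(13.558502296690966, rel=1e-9)
        assert sc.na_equilibrium(rate, a) == pytest.approx(oracle, rel=1e-9)

    def test_rejects_negative_rate(self, default_params):
        with pytest.raises(ValueError):
            sc.na_rate(9.5, -1.0, default_params.adaptation)


class TestVectorField:
    def test_zero_at_solver_equilibrium(self, n2):
        eq = sc.find_equilibria(n2)[0]
        f = sc.vector_field(eq.state, n2)
        assert np.abs(f).max() < 1e-9

    def test_na_decouples_without_adaptation(self, n2):
        p = n2.with_overrides(**{"adaptation.g_KNa": 0.0})
        x = sc.default_state(p)
        base = sc.vector_field(x, p)
        x2 = x.copy()
        x2[10] += 5.0
        pert = sc.vector_field(x2, p)
        assert pert[0] == base[0]  # V_e equation independent of Na
        # Jacobian block structure: no Na influence on any other equation
        J = sc.jacobian(x, p)
        assert np.abs(J[:10, 10]).max() < 1e-9

    def test_drive_enters_only_background_pathway(self, n2):
        x = sc.default_state(n2)
        d1 = sc.vector_field(x, n2, drive=10.0)
        d2 = sc.vector_field(x, n2, drive=20.0)
        changed = np.flatnonzero(d1 != d2)
        assert set(changed) == {3, 5}  # s''_ee and s''_ei only

    def test_autonomous_field_is_state_only(self, n2):
        x = sc.default_state(n2)
        assert np.array_equal(sc.vector_field(x, n2, 5.0),
                              sc.vector_field(x, n2, 5.0))

    def test_dimension_and_finiteness_checks(self, n2):
        with pytest.raises(ValueError):
            sc.vector_field(np.zeros(5), n2)
        x = sc.default_state(n2)
        x[0] = np.inf
        with pytest.raises(ValueError):
            sc.vector_field(x, n2)

    def test_reduces_to_two_population_model_without_adaptation(self, n2):
        """With g_KNa = 0 and Na frozen, equilibria match an independent
        root-find on the reduced conductance-based two-population model."""
        p = n2.with_overrides(**{"adaptation.g_KNa": 0.0})
        s, e, i = p.synapses, p.excitatory, p.inhibitory

        def qe(v):
            return e.Qmax * 1e-3 / (1 + np.exp(-e.sigmoid_scale * (v - e.theta) / e.sigma))

        def qi(v):
            return i.Qmax * 1e-3 / (1 + np.exp(-i.sigmoid_scale * (v - i.theta) / i.sigma))

        def vi_of_ve(ve):
            return brentq(lambda vi: -(vi - i.E_leak) - s.N_ei * qe(ve) * vi
                          - s.N_ii * qi(vi) * (vi - s.E_gaba), -110, 10, xtol=1e-12)

        def F(ve):
            vi = vi_of_ve(ve)
            return (-(ve - e.E_leak) - s.N_ee * qe(ve) * ve
                    - s.N_ie * qi(vi) * (ve - s.E_gaba))

        grid = np.linspace(-90, -20, 400)
        vals = np.array([F(v) for v in grid])
        oracle_roots = [brentq(F, grid[k], grid[k + 1], xtol=1e-10)
                        for k in np.flatnonzero(vals[:-1] * vals[1:] < 0)]
        found = [eq.V_e for eq in sc.find_equilibria(p)]
        assert len(found) == len(oracle_roots)
        np.testing.assert_allclose(sorted(found), sorted(oracle_roots), atol=1e-6)
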