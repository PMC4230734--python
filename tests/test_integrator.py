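"""Integrator contracts: determinism, deterministic limit, noise statistics."""

import numpy as np
import pytest

import sleepcortex as sc
from sleepcortex.integrate import _mean_drives


def _noise_free(p):
    q = p.copy()
    q.noise.phi_sd = 0.0
    return q


class TestDeterministicLimit:
    def test_equilibrium_is_preserved_over_30s(self, n2):
        q = _noise_free(n2)
        eq = sc.depolarized_equilibrium(q)
        cfg = sc.SimulationConfig(duration=30.0, onset=0.0, seed=0,
                                  record_stride=100)
        tr = sc.integrate(q, cfg, eq.state)
        drift = np.abs(tr.V_e - eq.V_e).max()
        assert drift <= 1e-8

    def test_fourth_order_convergence(self, n2):
        """Halving dt shrinks the endpoint error ~16x on a smooth segment."""
        q = _noise_free(n2)
        x0 = sc.depolarized_equilibrium(q).state.copy()
        x0[0] += 2.0  # relax from a kicked state

        def endpoint(dt):
            cfg = sc.SimulationConfig(dt=dt, duration=0.5, onset=0.0, seed=0,
                                      record_stride=max(1, int(0.5 / dt)))
            return sc.integrate(q, cfg, x0).V_e[-1]

        ref = endpoint(0.0125)
        e1 = abs(endpoint(0.4) - ref)
        e2 = abs(endpoint(0.2) - ref)
        e3 = abs(endpoint(0.1) - ref)
        assert 8 < e1 / e2 < 40
        assert 8 < e2 / e3 < 40


class TestDeterminism:
    def test_same_seed_bit_identical(self, n2):
        cfg = sc.SimulationConfig(duration=3.0, onset=0.0, seed=42)
        a = sc.integrate(n2, cfg)
        b = sc.integrate(n2, cfg)
        assert np.array_equal(a.states, b.states)

    def test_record_stride_does_not_change_the_stream(self, n2):
        fine = sc.SimulationConfig(duration=2.0, onset=0.0, seed=7,
                                   record_stride=5)
        coarse = sc.SimulationConfig(duration=2.0, onset=0.0, seed=7,
                                     record_stride=10)
        a = sc.integrate(n2, fine)
        b = sc.integrate(n2, coarse)
        assert np.array_equal(a.states[::2], b.states)

    def test_different_seeds_differ(self, n2):
        cfg1 = sc.SimulationConfig(duration=2.0, onset=0.0, seed=1)
        cfg2 = sc.SimulationConfig(duration=2.0, onset=0.0, seed=2)
        assert not np.array_equal(sc.integrate(n2, cfg1).states,
                                  sc.integrate(n2, cfg2).states)


class TestOrnsteinUhlenbeckOracle:
    def test_stationary_variance_matches_closed_form(self):
        """Empirical stationary variance within 3 MC standard errors of
        sigma^2 * tau / 2."""
        tau, sigma, dt = 10.0, 0.5, 0.1
        target = sigma ** 2 * tau / 2.0
        estimates = []
        for seed in range(10):
            x = sc.ou_trajectory(tau, sigma, dt, duration_ms=40_000.0,
                                 seed=seed)
            estimates.append(np.var(x[int(5_000 / dt):]))
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - target) < 3 * se


class TestNoise:
    def test_noise_sd_scales_linearly_in_wake_regime(self, wake):
        def sd_of(phi_sd, seed):
            p = wake.copy()
            p.noise.phi_sd = phi_sd
            cfg = sc.SimulationConfig(duration=20.0, onset=2.0, seed=seed)
            return sc.integrate(p, cfg).post_onset().V_e.std()

        r = np.mean([sd_of(400.0, s) / sd_of(200.0, s) for s in range(3)])
        assert 1.7 < r < 2.4

    def test_trajectories_are_finite(self, n3):
        cfg = sc.SimulationConfig(duration=10.0, onset=0.0, seed=3)
        tr = sc.integrate(n3, cfg)
        assert np.isfinite(tr.states).all()

    def test_divergence_guard_reports_first_bad_step(self, n2):
        cfg = sc.SimulationConfig(duration=1.0, onset=0.0, seed=0,
                                  divergence_guard=40.0)
        with pytest.raises(sc.SimulationDiverged, match="step 0"):
            sc.integrate(n2, cfg)


class TestStimulus:
    def test_zero_offset_identical_to_unstimulated(self, n2):
        base = sc.SimulationConfig(duration=2.0, onset=0.0, seed=5)
        stim = sc.apply_stimulus(base, sc.StimulusProtocol(0.5, 50.0, 0.0))
        assert np.array_equal(sc.integrate(n2, base).states,
                              sc.integrate(n2, stim).states)

    def test_window_outside_interval_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sc.SimulationConfig(duration=2.0, onset=0.0,
                                stimuli=(sc.StimulusProtocol(1.99, 50.0, 10.0),))

    def test_disjoint_protocols_compose_additively(self, n2):
        cfg_a = sc.SimulationConfig(duration=3.0, onset=0.0,
                                    stimuli=(sc.StimulusProtocol(0.5, 50.0, 30.0),))
        cfg_b = sc.SimulationConfig(duration=3.0, onset=0.0,
                                    stimuli=(sc.StimulusProtocol(1.5, 50.0, 40.0),))
        cfg_ab = sc.apply_stimulus(cfg_a, cfg_b.stimuli[0])
        de_a, di_a = _mean_drives(n2, cfg_a)
        de_b, di_b = _mean_drives(n2, cfg_b)
        de_ab, di_ab = _mean_drives(n2, cfg_ab)
        np.testing.assert_allclose(de_ab, de_a + de_b)
        np.testing.assert_allclose(di_ab, di_a + di_b)

    def test_targets_select_population(self, n2):
        cfg = sc.SimulationConfig(duration=1.0, onset=0.0,
                                  stimuli=(sc.StimulusProtocol(0.2, 50.0, 30.0,
                                                               targets="e"),))
        de, di = _mean_drives(n2, cfg)
        assert de.max() > 0 and di.max() == 0

    def test_strong_n2_burst_evokes_large_deflection(self, n2):
        """A 50 ms burst beyond the canard threshold triggers a K-complex-
        sized excursion from the stable focus."""
        q = _noise_free(n2)
        eq = sc.depolarized_equilibrium(q)
        cfg = sc.SimulationConfig(duration=4.0, onset=0.0, seed=0,
                                  stimuli=(sc.StimulusProtocol(0.5, 50.0, 80.0),))
        tr = sc.integrate(q, cfg, eq.state)
        assert tr.V_e.min() < eq.V_e - 15.0  # deep trough well below baseline


class TestTrajectoryIO:
    def test_csv_round_trip(self, n2, tmp_path):
        cfg = sc.SimulationConfig(duration=1.0, onset=0.0, seed=0,
                                  record_stride=100)
        tr = sc.integrate(n2, cfg)
        path = tmp_path / "run.csv"
        tr.to_csv(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        np.testing.assert_allclose(data[:, 1], tr.V_e)

    def test_v_e_accessor_matches_states(self, n2):
        cfg = sc.SimulationConfig(duration=0.5, onset=0.0, seed=0)
        tr = sc.integrate(n2, cfg)
        assert np.array_equal(tr.V_e, tr.states[:, 0])
        assert len(tr.times) == len(tr.states)
        dt_s = np.diff(tr.times)
        np.testing.assert_allclose(dt_s, dt_s[0])
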