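"""Stochastic layer: steppers, trajectories, ensembles, convergence order."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import rnasilencing as rs
from rnasilencing.core import _drift_array

component = st.floats(min_value=0.0, max_value=2e4)
step = st.floats(min_value=1e-5, max_value=0.1)


class TestEulerStep:
    def test_hand_substitution(self, params, table_initial):
        s = rs.euler_step(table_initial, params, 0.001)
        assert (s.S, s.R, s.C, s.M) == (9.9, 0.5, 0.0, 1000.0)

    def test_fixed_point(self, params):
        xi0 = rs.equilibria(params).xi0
        for dt in (1e-4, 0.01, 1.0):
            assert rs.euler_step(xi0, params, dt) == xi0

    def test_interior_equilibrium_nearly_fixed(self, params):
        star = rs.equilibria(params).xi_star
        out = rs.euler_step(star, params, 0.001)
        assert np.max(np.abs(out.as_array() - star.as_array())) <= 1e-9

    def test_rejects_nonpositive_dt(self, params, table_initial):
        with pytest.raises(rs.UsageError):
            rs.euler_step(table_initial, params, 0.0)


class TestMilsteinStep:
    def test_literal_correction_with_zero_draws(self, params, table_initial):
        noise = rs.NoiseIntensities(sigma1=0.2)
        out = rs.milstein_step(table_initial, params, noise, 0.001,
                               rs.StepNoise(0, 0, 0, 0), "milstein_paper_literal")
        # tau = 0 leaves only the (tau^2 - 1) = -1 correction terms
        assert out.S == pytest.approx(9.9002, abs=1e-12)
        assert out.R == pytest.approx(0.495, abs=1e-12)
        assert (out.C, out.M) == (0.0, 1000.0)

    def test_literal_diffusion_with_unit_draw(self, params, table_initial):
        noise = rs.NoiseIntensities(sigma1=0.2)
        out = rs.milstein_step(table_initial, params, noise, 0.001,
                               rs.StepNoise(1, 0, 0, 0), "milstein_paper_literal")
        assert out.S == pytest.approx(9.9 - 0.2 * 10 * math.sqrt(0.001), rel=1e-12)

    def test_ito_correction_signs(self, params, table_initial):
        # conventional calculus: the S correction is +sigma1^2/2 S (tau^2-1) dt
        # and the R correction, through the S chain rule, is
        # -sigma1^2/2 n S (tau^2-1) dt; tau = 0 makes (tau^2-1) = -1
        noise = rs.NoiseIntensities(sigma1=0.2)
        out = rs.milstein_step(table_initial, params, noise, 0.001,
                               rs.StepNoise(0, 0, 0, 0), "milstein_ito")
        assert out.S == pytest.approx(9.9 + 0.5 * 0.04 * 10 * (-1) * 0.001, abs=1e-12)
        assert out.R == pytest.approx(0.5 - 0.5 * 0.04 * 5 * 10 * (-1) * 0.001, abs=1e-12)

    def test_invalid_mode_rejected(self, params, table_initial):
        noise = rs.NoiseIntensities(sigma1=0.2)
        with pytest.raises(rs.UsageError):
            rs.milstein_step(table_initial, params, noise, 0.001,
                             rs.StepNoise(0, 0, 0, 0), "heun")
        with pytest.raises(rs.UsageError):
            rs.milstein_step(table_initial, params, noise, 0.001,
                             rs.StepNoise(0, 0, 0, 0), "euler")

    @given(S=component, R=component, C=component, M=component, dt=step,
           t1=st.floats(-3, 3), t2=st.floats(-3, 3),
           t3=st.floats(-3, 3), t4=st.floats(-3, 3))
    def test_zero_noise_degenerates_to_euler_bitwise(self, S, R, C, M, dt,
                                                     t1, t2, t3, t4):
        p = rs.ModelParameters()
        state = rs.State(S, R, C, M)
        draws = rs.StepNoise(t1, t2, t3, t4)
        ref = rs.euler_step(state, p, dt)
        for mode in ("milstein_paper_literal", "milstein_ito"):
            out = rs.milstein_step(state, p, rs.NoiseIntensities(), dt, draws, mode)
            assert out == ref  # bitwise: exact dataclass equality


class TestSimulate:
    def test_grid_has_shortened_final_step(self, params, table_initial):
        sett = rs.IntegrationSettings(dt=0.4, t_end=1.0, seed=0)
        np.testing.assert_allclose(sett.grid(), [0.0, 0.4, 0.8, 1.0])

    def test_zero_t_end_rejected(self):
        with pytest.raises(rs.UsageError):
            rs.IntegrationSettings(dt=0.001, t_end=0.0)
        with pytest.raises(rs.UsageError):
            rs.IntegrationSettings(dt=2.0, t_end=1.0)

    def test_seed_determinism(self, params, table_initial):
        sett = rs.IntegrationSettings(dt=0.01, t_end=1.0, seed=123)
        noise = rs.NoiseIntensities(0.2, 0.2, 0.2, 0.2)
        a = rs.simulate(table_initial, params, noise, sett)
        b = rs.simulate(table_initial, params, noise, sett)
        assert np.array_equal(a.values, b.values)

    def test_changing_a_sigma_does_not_shift_the_stream(self, params, table_initial):
        # four draws are consumed per step in fixed channel order even for
        # silent channels: the first step's M update depends only on the
        # tau4 draw, so it must be identical whether or not channel 1 is on
        sett = rs.IntegrationSettings(dt=0.01, t_end=1.0, seed=5)
        a = rs.simulate(table_initial, params, rs.NoiseIntensities(sigma4=0.2), sett)
        b = rs.simulate(table_initial, params,
                        rs.NoiseIntensities(sigma1=0.2, sigma4=0.2), sett)
        assert a.values[1, 3] == b.values[1, 3]
        assert a.values[1, 3] != table_initial.M  # tau4 actually acted

    def test_deterministic_run_matches_ode_oracle(self, params, table_initial):
        sett = rs.IntegrationSettings(dt=0.001, t_end=50.0, seed=0)
        traj = rs.simulate(table_initial, params, rs.NoiseIntensities(), sett)
        sol = solve_ivp(lambda t, x: _drift_array(np.asarray(x), params),
                        (0.0, 50.0), table_initial.as_array(),
                        rtol=1e-10, atol=1e-10, method="LSODA")
        rel = np.abs(traj.values[-1] - sol.y[:, -1]) / np.abs(sol.y[:, -1])
        assert rel.max() < 2e-3

    def test_low_and_high_dose_silence_to_the_same_state(self, params):
        # dose independence of the final silencing level: both runs approach
        # the interior equilibrium and agree with each other
        sett = rs.IntegrationSettings(dt=0.001, t_end=50.0, seed=0)
        star = rs.equilibria(params).xi_star.as_array()
        finals = []
        for s0 in (10.0, 1000.0):
            traj = rs.simulate(rs.State(s0, 0, 0, 1000), params,
                               rs.NoiseIntensities(), sett)
            d0 = np.max(np.abs(traj.values[0] - star))
            dT = np.max(np.abs(traj.values[-1] - star))
            assert dT < 0.05 * d0
            finals.append(traj.values[-1])
        rel_gap = np.abs(finals[0] - finals[1]) / np.abs(star)
        assert rel_gap.max() < 0.02

    def test_overflow_carries_step_and_partial(self, params, table_initial):
        # a wildly unstable step size blows up the stiff components
        sett = rs.IntegrationSettings(dt=5.0, t_end=100.0, seed=0)
        with pytest.raises(rs.SimulationOverflowError) as err:
            rs.simulate(table_initial, params, rs.NoiseIntensities(), sett)
        assert err.value.step >= 1
        assert err.value.partial.shape[0] == err.value.step

    def test_clipping_counts_and_clips(self, params):
        noise = rs.NoiseIntensities(2.0, 2.0, 2.0, 2.0)
        sett = rs.IntegrationSettings(dt=0.05, t_end=20.0, seed=3,
                                      clip_at_zero=True)
        traj = rs.simulate(rs.State(10, 0, 0, 1000), params, noise, sett)
        assert traj.positivity_violations > 0
        assert traj.values.min() >= 0.0


class TestEnsemble:
    def test_single_replicate_equals_simulate_with_derived_seed(
            self, params, table_initial):
        noise = rs.NoiseIntensities(sigma1=0.2)
        sett = rs.IntegrationSettings(dt=0.01, t_end=1.0, seed=0)
        ens = rs.simulate_ensemble(table_initial, params, noise, sett, 1, 99)
        seed = rs.derive_replicate_seed(99, 0)
        solo = rs.simulate(table_initial, params, noise,
                           rs.IntegrationSettings(dt=0.01, t_end=1.0, seed=seed))
        assert np.array_equal(ens.replicates[0].values, solo.values)
        assert ens.seeds == (seed,)

    def test_zero_noise_replicates_identical(self, params, table_initial):
        sett = rs.IntegrationSettings(dt=0.01, t_end=1.0, seed=0)
        ens = rs.simulate_ensemble(table_initial, params,
                                   rs.NoiseIntensities(), sett, 3, 0)
        for rep in ens.replicates[1:]:
            assert np.array_equal(rep.values, ens.replicates[0].values)
        mom = rs.ensemble_moments(ens)
        assert mom.variance.max() == 0.0

    def test_noisy_replicates_differ(self, params, table_initial):
        sett = rs.IntegrationSettings(dt=0.01, t_end=1.0, seed=0)
        ens = rs.simulate_ensemble(table_initial, params,
                                   rs.NoiseIntensities(sigma1=0.2), sett, 2, 0)
        assert not np.array_equal(ens.replicates[0].values,
                                  ens.replicates[1].values)

    def test_single_replicate_moments(self, params, table_initial):
        sett = rs.IntegrationSettings(dt=0.01, t_end=1.0, seed=0)
        ens = rs.simulate_ensemble(table_initial, params,
                                   rs.NoiseIntensities(sigma1=0.2), sett, 1, 0)
        mom = rs.ensemble_moments(ens)
        np.testing.assert_array_equal(mom.mean, ens.replicates[0].values)
        assert mom.variance.max() == 0.0

    def test_mismatched_grids_rejected(self, params, table_initial):
        noise = rs.NoiseIntensities()
        a = rs.simulate(table_initial, params, noise,
                        rs.IntegrationSettings(dt=0.01, t_end=1.0, seed=1))
        b = rs.simulate(table_initial, params, noise,
                        rs.IntegrationSettings(dt=0.02, t_end=1.0, seed=2))
        with pytest.raises(rs.InvalidInputError):
            rs.Ensemble(replicates=(a, b), seeds=(1, 2))

    def test_positivity_violations_stay_bounded_under_moderate_noise(
            self, params, table_initial):
        # the exact solution is positive a.s.; the discretization's
        # excursions are monitored and remain rare at dt=0.001
        noise = rs.NoiseIntensities(0.2, 0.2, 0.2, 0.2)
        sett = rs.IntegrationSettings(dt=0.001, t_end=50.0, seed=0)
        ens = rs.simulate_ensemble(table_initial, params, noise, sett, 20, 17)
        counts = [r.positivity_violations for r in ens.replicates]
        assert max(counts) <= 100  # out of 50,000 grid points


class TestStrongOrder:
    def test_rejects_multi_channel_noise(self, params, table_initial):
        with pytest.raises(rs.UsageError):
            rs.strong_order_estimate(
                table_initial, params, rs.NoiseIntensities(0.2, 0.2, 0, 0),
                "milstein_ito", [2.0 ** -6], 2.0 ** -10, 4, 0)

    def test_rejects_non_nested_grids(self, params, table_initial):
        with pytest.raises(rs.UsageError):
            rs.strong_order_estimate(
                table_initial, params, rs.NoiseIntensities(sigma1=0.2),
                "milstein_ito", [0.3], 2.0 ** -10, 4, 0)

    def test_zero_noise_gives_first_order_ode_error(self, params, table_initial):
        est = rs.strong_order_estimate(
            table_initial, params, rs.NoiseIntensities(), "euler",
            [2.0 ** -k for k in range(6, 11)], 2.0 ** -14, 4, 0)
        assert 0.75 <= est.slope <= 1.25
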