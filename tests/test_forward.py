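"""Time integration: stability bound, logistic limit, conservation, coupling."""

import numpy as np
import pytest

from glioforecast.core import ImageGrid, TumorState
from glioforecast.errors import InstabilityError
from glioforecast.forward import (
    DomainContext,
    GrowthParams,
    SimulationSettings,
    simulate,
    stable_dt,
    step_single_species,
    step_two_species,
)
from glioforecast.mechanics import ElasticityParams
from glioforecast.therapy import TherapyParams, TreatmentSchedule, make_model_spec


def uniform_ctx(shape=(16, 16, 4), spacing=(1.0, 1.0, 5.0), er=None):
    grid = ImageGrid(shape=shape, spacing=spacing)
    mask = np.ones(shape, bool)
    labels = np.ones(shape, np.uint8)  # all white matter
    return DomainContext(
        grid=grid, brain_mask=mask, tissue_labels=labels,
        er_field=er if er is not None else np.ones(shape),
        elasticity=ElasticityParams(),
    )


class TestStableDt:
    def test_zero_diffusion_unbounded(self):
        grid = ImageGrid(shape=(4, 4, 4), spacing=(1, 1, 1))
        assert stable_dt(0.0, grid) == np.inf

    def test_inverse_proportionality(self):
        grid = ImageGrid(shape=(4, 4, 4), spacing=(1, 1, 1))
        assert stable_dt(0.2, grid) == pytest.approx(stable_dt(0.1, grid) / 2)

    def test_anisotropic_formula(self):
        grid = ImageGrid(shape=(4, 4, 4), spacing=(1.0, 1.0, 5.0))
        expected = 0.9 * 0.5 / (0.1 * (1 + 1 + 1 / 25))
        assert stable_dt(0.1, grid, safety=0.9) == pytest.approx(expected)


class TestSteps:
    def test_null_dynamics_freezes_state(self):
        grid = ImageGrid(shape=(6, 6, 2), spacing=(1, 1, 1))
        phi = np.random.default_rng(0).uniform(0, 0.5, grid.shape)
        out = step_single_species(phi, np.zeros(grid.shape), 0.0, 1.0, 0.5, grid)
        assert np.array_equal(out, phi)

    def test_zero_diffusion_matches_logistic_closed_form(self):
        # theta phi0 e^{kt} / (theta + phi0 (e^{kt} - 1)) after t=10 d
        grid = ImageGrid(shape=(1, 1, 1), spacing=(1, 1, 1))
        phi = np.array([[[0.1]]])
        k, theta, dt, t_end = 0.1, 1.0, 0.002, 10.0
        for _ in range(int(t_end / dt)):
            phi = step_single_species(phi, np.zeros_like(phi), k, theta, dt, grid)
        exact = theta * 0.1 * np.exp(k * t_end) / (theta + 0.1 * (np.exp(k * t_end) - 1))
        assert abs(phi[0, 0, 0] - exact) / exact <= 1e-4

    def test_mass_conserved_by_flux_form(self):
        grid = ImageGrid(shape=(12, 12, 4), spacing=(1, 1, 2))
        rng = np.random.default_rng(3)
        phi = rng.uniform(0, 0.5, grid.shape)
        d = np.full(grid.shape, 0.1)
        m0 = phi.sum() * grid.voxel_volume
        for i in range(50):
            phi = step_single_species(phi, d, 0.0, 1.0, 0.4, grid, i)
        m1 = phi.sum() * grid.voxel_volume
        assert abs(m1 - m0) / m0 <= 1e-10

    def test_two_species_reduces_to_single_when_decoupled(self):
        grid = ImageGrid(shape=(10, 10, 3), spacing=(1, 1, 2))
        rng = np.random.default_rng(4)
        phi_e = rng.uniform(0, 0.5, grid.shape)
        phi_n = np.zeros(grid.shape)
        d = np.full(grid.shape, 0.05)
        params = GrowthParams(
            d_e_w=0.05, k_p_e=0.1, theta_e=0.8, beta_ne=0.0, beta_en=0.0
        )
        phi_single = phi_e.copy()
        for i in range(20):
            phi_e, phi_n = step_two_species(phi_e, phi_n, d, d, params, 0.3, grid, i)
            phi_single = step_single_species(phi_single, d, 0.1, 0.8, 0.3, grid, i)
        assert np.allclose(phi_e, phi_single, atol=1e-12)
        assert not phi_n.any()

    def test_two_species_coupled_fixed_point(self):
        # where phi_E + beta_NE phi_N = theta_E the E growth term vanishes
        grid = ImageGrid(shape=(1, 1, 1), spacing=(1, 1, 1))
        params = GrowthParams(k_p_e=0.2, k_p_n=0.0, theta_e=0.8, beta_ne=4.0)
        phi_n = np.array([[[0.1]]])
        phi_e = np.array([[[0.8 - 4.0 * 0.1]]])
        e2, n2 = step_two_species(
            phi_e, phi_n, np.zeros_like(phi_e), np.zeros_like(phi_e), params, 0.5, grid
        )
        assert np.allclose(e2, phi_e)

    def test_extinction_absorbing(self):
        grid = ImageGrid(shape=(4, 4, 2), spacing=(1, 1, 1))
        z = np.zeros(grid.shape)
        params = GrowthParams(d_e_w=0.1, d_n_w=0.1, k_p_e=0.3, k_p_n=0.3)
        e2, n2 = step_two_species(z, z, z + 0.1, z + 0.1, params, 0.5, grid)
        assert not e2.any() and not n2.any()

    def test_non_finite_state_reported_with_step(self):
        grid = ImageGrid(shape=(4, 4, 2), spacing=(1, 1, 1))
        phi = np.zeros(grid.shape)
        phi[1, 1, 0] = np.nan
        with pytest.raises(InstabilityError, match="step 7"):
            step_single_species(phi, np.zeros(grid.shape), 0.1, 1.0, 0.5, grid, 7)


class TestGaussianSpread:
    def test_anisotropic_diffusion_matches_analytic_gaussian(self):
        """Second moments grow as sigma_a^2(t) = sigma^2 + 2 D t per axis."""
        grid = ImageGrid(shape=(64, 64, 8), spacing=(1.0, 1.0, 5.0))
        X, Y, Z = grid.coordinate_arrays()
        c = np.array(grid.shape) * np.array(grid.spacing) / 2
        sig0 = 4.0
        phi = 0.5 * np.exp(
            -((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) / (2 * sig0**2)
        )
        D = 0.5
        d_field = np.full(grid.shape, D)
        t_end = 10.0
        dt = stable_dt(D, grid, safety=0.9)
        n = int(np.ceil(t_end / dt))
        dt = t_end / n
        for i in range(n):
            phi = step_single_species(phi, d_field, 0.0, 1.0, dt, grid, i)
        mass = phi.sum()
        for axis, coord, cc in ((0, X, c[0]), (1, Y, c[1]), (2, Z, c[2])):
            var = ((coord - cc) ** 2 * phi).sum() / mass
            expected = sig0**2 + 2 * D * t_end
            assert abs(var - expected) / expected <= 0.02


class TestSimulate:
    def _initial(self, ctx, value=0.3):
        phi = np.zeros(ctx.grid.shape)
        phi[6:10, 6:10, 1:3] = value
        return TumorState("single", 0.0, phi_T=phi)

    def test_frozen_system_constant_trajectory(self):
        ctx = uniform_ctx()
        spec = make_model_spec("single", 10)  # C4/C4 coupling
        growth = GrowthParams()
        initial = self._initial(ctx)
        states = simulate(
            spec, growth, TherapyParams(), initial, None, None,
            [0.0, 5.0, 10.0], ctx, SimulationSettings(dt=1.0),
        )
        assert len(states) == 3
        for s in states:
            assert np.array_equal(s.phi_T, initial.phi_T)

    def test_single_rt_event_uniform_sf_halves_mass(self):
        ctx = uniform_ctx()
        spec = make_model_spec("single", 10)  # C4 for both therapies
        growth = GrowthParams()  # D = 0, k = 0
        initial = self._initial(ctx)
        rt = TreatmentSchedule(kind="RT", days=(3.0,))
        states = simulate(
            spec, growth, TherapyParams(sf_rt_min=0.5, sf_ct_min=1.0),
            initial, rt, None, [0.0, 10.0], ctx, SimulationSettings(dt=1.0),
        )
        before = states[0].phi_T.sum()
        after = states[1].phi_T.sum()
        assert after == pytest.approx(0.5 * before)

    def test_mechanical_damping_never_accelerates_growth(self):
        ctx = uniform_ctx()
        spec = make_model_spec("single", 10)
        initial = self._initial(ctx)
        times = [0.0, 10.0, 20.0]
        base = dict(d_t_w=0.1, k_p_t=0.05, theta_t=1.0)
        free = simulate(
            spec, GrowthParams(**base, lambda1=0.0), TherapyParams(), initial,
            None, None, times, ctx, SimulationSettings(dt=1.0),
        )
        damped = simulate(
            spec, GrowthParams(**base, lambda1=1e3), TherapyParams(), initial,
            None, None, times, ctx, SimulationSettings(dt=1.0),
        )
        thr = 0.05
        for s_free, s_damp in zip(free, damped):
            vol_free = (s_free.phi_T >= thr).sum()
            vol_damp = (s_damp.phi_T >= thr).sum()
            assert vol_damp <= vol_free

    def test_record_before_start_rejected(self):
        ctx = uniform_ctx()
        spec = make_model_spec("single", 10)
        initial = self._initial(ctx)
        initial.time = 5.0
        from glioforecast.errors import InvalidParameterError

        with pytest.raises(InvalidParameterError):
            simulate(spec, GrowthParams(), TherapyParams(), initial,
                     None, None, [0.0], ctx)

    def test_fractions_stay_within_carrying_capacity(self):
        ctx = uniform_ctx()
        spec = make_model_spec("two_species", 8)
        growth = GrowthParams(
            d_e_w=0.05, d_n_w=0.1, k_p_e=0.3, k_p_n=0.3, theta_e=0.7
        )
        phi_e = np.zeros(ctx.grid.shape)
        phi_e[6:10, 6:10, 1:3] = 0.6
        phi_n = np.zeros(ctx.grid.shape)
        phi_n[4:12, 4:12, 1:3] = 0.16
        phi_n[6:10, 6:10, 1:3] = 0.0
        initial = TumorState("two_species", 0.0, phi_E=phi_e, phi_N=phi_n)
        states = simulate(
            spec, growth, TherapyParams(), initial, None, None,
            [30.0], ctx, SimulationSettings(dt=1.0),
        )
        s = states[0]
        assert s.phi_E.max() <= 0.7 + 1e-12
        assert s.phi_N.max() <= 0.16 + 1e-12
        assert s.phi_E.min() >= 0.0 and s.phi_N.min() >= 0.0
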