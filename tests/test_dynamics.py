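"""Wave-model integrator, Balloon haemodynamics, BEI neural-mass dynamics."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import brainmodes as bm
from brainmodes.dynamics import (BalloonParams, BEIParams, StimulusSpec,
                                 WaveModelParams, balloon_bold, bei_fixed_point,
                                 bei_transfer, simulate_bei,
                                 simulate_wave_evoked, simulate_wave_resting,
                                 time_to_peak, wave_modal_transfer,
                                 default_rs_grid)


class TestModalOscillators:
    def closed_form_impulse(self, lam, params, t):
        g = params.gamma_s
        if lam == 0:
            return g ** 2 * t * np.exp(-g * t)
        om = g * params.r_s * np.sqrt(lam)
        return g ** 2 / om * np.exp(-g * t) * np.sin(om * t)

    @pytest.mark.parametrize("lam", [0.0, 1e-3, 0.02, 0.1])
    def test_impulse_response_matches_closed_form(self, lam):
        params = WaveModelParams(gamma_s=116.0, r_s=28.9)
        dt = 1e-4
        T = 1500
        init = np.array([[0.0], [params.gamma_s ** 2]])
        a = wave_modal_transfer(np.array([lam]), params, np.zeros((1, T)), dt,
                                initial_state=init)[0]
        t = dt * np.arange(1, T + 1)
        h = self.closed_form_impulse(lam, params, t)
        assert np.abs(a - h).max() / np.abs(h).max() < 1e-6

    def test_zero_input_zero_output(self):
        params = WaveModelParams()
        out = wave_modal_transfer(np.array([0.0, 0.1]), params,
                                  np.zeros((2, 100)), 1e-4)
        assert np.all(out == 0.0)

    def test_superposition_and_scaling(self, rng):
        params = WaveModelParams()
        q1 = rng.standard_normal((3, 200))
        q2 = rng.standard_normal((3, 200))
        lam = np.array([0.0, 0.01, 0.05])
        f = lambda q: wave_modal_transfer(lam, params, q, 1e-4)
        assert np.allclose(f(q1 + 2.5 * q2), f(q1) + 2.5 * f(q2), atol=1e-12)

    def test_step_size_guard(self):
        params = WaveModelParams(gamma_s=116.0)
        with pytest.raises(ValueError, match="dt"):
            wave_modal_transfer(np.array([0.0]), params, np.zeros((1, 10)), 0.01)

    def test_constant_input_steady_state(self):
        # steady state a = q / (1 + r_s^2 lambda)
        params = WaveModelParams(gamma_s=116.0, r_s=2.0)
        lam = np.array([0.0, 0.5, 2.0])
        out = wave_modal_transfer(lam, params, np.ones((3, 3000)), 5e-4)
        np.testing.assert_allclose(out[:, -1], 1.0 / (1 + params.r_s ** 2 * lam),
                                   rtol=1e-9)


@pytest.fixture(scope="module")
def sphere_setup():
    mesh = bm.make_icosphere(3, 50.0)
    basis = bm.solve_modes(bm.assemble_lbo(mesh), 100)
    cap = np.nonzero(mesh.vertices[:, 2] > 0.95 * 50)[0]
    ang = np.arccos(np.clip(mesh.vertices[:, 2] / 50, -1, 1))
    bands = bm.ParcellationLabels(
        np.clip((ang / np.pi * 12).astype(int), 0, 11) + 1).validate()
    return mesh, basis, cap, bands


class TestEvoked:
    def test_zero_magnitude_zero_field(self, sphere_setup):
        _, basis, cap, _ = sphere_setup
        stim = StimulusSpec(cap, magnitude=0.0)
        res = simulate_wave_evoked(basis, WaveModelParams(), stim)
        assert np.all(res.neural == 0.0)

    def test_linearity_in_magnitude(self, sphere_setup):
        _, basis, cap, _ = sphere_setup
        p = WaveModelParams()
        r1 = simulate_wave_evoked(basis, p, StimulusSpec(cap, magnitude=20.0))
        r2 = simulate_wave_evoked(basis, p, StimulusSpec(cap, magnitude=40.0))
        assert np.allclose(r2.neural, 2.0 * r1.neural, atol=1e-10)

    def test_time_to_peak_rank_invariant_to_amplitude(self, sphere_setup):
        _, basis, cap, bands = sphere_setup
        p = WaveModelParams(r_s=28.9)
        t1 = time_to_peak(simulate_wave_evoked(
            basis, p, StimulusSpec(cap, magnitude=20.0)), bands)
        t2 = time_to_peak(simulate_wave_evoked(
            basis, p, StimulusSpec(cap, magnitude=500.0)), bands)
        assert np.array_equal(np.argsort(t1), np.argsort(t2))

    def test_wavefront_marches_down_the_hierarchy(self, sphere_setup):
        _, basis, cap, bands = sphere_setup
        res = simulate_wave_evoked(basis, WaveModelParams(r_s=28.9),
                                   StimulusSpec(cap, magnitude=20.0))
        ttp = time_to_peak(res, bands)
        assert np.isfinite(ttp).all()
        assert ttp.max() <= 0.1
        assert ttp[0] == ttp.min()  # stimulated band peaks first
        rho = spearmanr(np.arange(len(ttp)), ttp).statistic
        assert rho > 0.9

    def test_stimulus_outside_window_rejected(self, sphere_setup):
        _, basis, cap, _ = sphere_setup
        stim = StimulusSpec(cap, onset=0.09, duration=0.02)
        with pytest.raises(ValueError, match="window"):
            simulate_wave_evoked(basis, WaveModelParams(), stim, duration=0.1)


class TestRestingWave:
    def test_seed_contract(self, sphere2_basis, sphere2_parc):
        p = WaveModelParams(r_s=30.0)
        kw = dict(n_frames=20, tr=0.72, dt=6e-4, burn=2.0 * 0.72 / 0.72, seed=5)
        r1 = simulate_wave_resting(sphere2_basis, p, sphere2_parc, **kw)
        r2 = simulate_wave_resting(sphere2_basis, p, sphere2_parc, **kw)
        r3 = simulate_wave_resting(sphere2_basis, p, sphere2_parc,
                                   **{**kw, "seed": 6})
        assert np.array_equal(r1.bold, r2.bold)  # bitwise reproducible
        assert not np.array_equal(r1.bold, r3.bold)

    def test_modal_variance_decreases_with_eigenvalue(self, sphere2_basis, rng):
        # white modal input: response variance ordered by transfer magnitude
        p = WaveModelParams(gamma_s=116.0, r_s=30.0)
        lam = sphere2_basis.eigenvalues
        q = rng.standard_normal((len(lam), 40000))
        a = wave_modal_transfer(lam, p, q, 6e-4)
        v = a[:, 2000:].var(axis=1)
        # compare group means (individual modes within a degenerate group tie)
        groups = [v[0], v[1:4].mean(), v[4:9].mean(), v[9:16].mean(), v[16:25].mean()]
        assert all(g2 < g1 for g1, g2 in zip(groups, groups[1:]))

    def test_spatial_correlation_decays_with_distance(self, sphere2, sphere2_basis, rng):
        # length scale comparable to the unit sphere radius, so the field is
        # smooth at the resolution the 40-mode basis resolves
        p = WaveModelParams(gamma_s=116.0, r_s=1.0)
        proj = sphere2_basis.project_matrix()
        noise = rng.standard_normal((sphere2.n_vertices, 60000))
        a = wave_modal_transfer(sphere2_basis.eigenvalues, p, proj @ noise, 6e-4)
        neural = sphere2_basis.modes @ a[:, 5000:]
        C = np.corrcoef(neural)
        D = bm.pairwise_distance(sphere2)
        iu = np.triu_indices(len(D), k=1)
        rho = spearmanr(C[iu], D[iu]).statistic
        assert rho < -0.8


class TestBalloon:
    def test_rest_is_stationary(self):
        y = balloon_bold(np.zeros((2, 200)), dt=0.01)
        assert np.all(y == 0.0)

    def test_boxcar_peak_then_undershoot(self):
        drive = np.zeros((1, 4000))
        drive[0, 500:1500] = 1.0
        y = balloon_bold(drive, dt=0.01)[0]
        peak = y.argmax()
        assert y[peak] > 0
        assert y[1500:].min() < 0  # post-stimulus undershoot
        assert y.argmin() > peak

    def test_standard_default_parameters(self):
        p = BalloonParams()
        assert (p.kappa, p.gamma_flow, p.tau_h) == (0.65, 0.41, 0.98)
        assert (p.alpha_grubb, p.rho, p.V0) == (0.32, 0.34, 0.02)
        assert (p.k1, p.k2, p.k3) == (3.72, 0.53, 0.53)

    def test_heun_matches_fine_step_reference(self):
        drive = np.zeros((1, 400))
        drive[0, 50:150] = 1.0
        y = balloon_bold(drive, dt=0.01)[0]
        fine = balloon_bold(np.repeat(drive, 10, axis=1), dt=0.001)[0][9::10]
        assert np.abs(y - fine).max() < 1e-4 * np.abs(fine).max() + 1e-7

    def test_bold_ode_variant_differs(self):
        drive = np.zeros((1, 500))
        drive[0, 50:100] = 1.0
        y_alg = balloon_bold(drive, dt=0.01)
        y_ode = balloon_bold(drive, dt=0.01, bold_as_ode=True)
        assert not np.allclose(y_alg, y_ode)

    def test_step_guard(self):
        with pytest.raises(ValueError, match="10 ms"):
            balloon_bold(np.zeros((1, 10)), dt=0.02)


class TestBEI:
    def test_sigmoid_limit_at_threshold(self):
        p = BEIParams()
        at = p.b_E / p.a_E
        assert bei_transfer(np.array([at]), p.a_E, p.b_E, p.d_E)[0] == \
            pytest.approx(1.0 / p.d_E, rel=1e-7)
        # continuity just off threshold
        eps = 1e-10
        lo = bei_transfer(np.array([at - eps]), p.a_E, p.b_E, p.d_E)[0]
        hi = bei_transfer(np.array([at + eps]), p.a_E, p.b_E, p.d_E)[0]
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_deterministic_convergence_to_fixed_point(self):
        p = BEIParams(sigma=0.0, G=0.0)
        SEf, SIf = bei_fixed_point(p)
        res = simulate_bei(p, duration=20.0, dt=1e-3, seed=0, n_regions=1)
        SE = res.neural[0, -1]
        assert abs(SE - SEf[0]) < 1e-10
        # residual derivative at the endpoint
        rE = bei_transfer(np.array([p.I_ext + p.W_E * p.I_0 + p.w_EE * SE
                                    - p.w_IE * SIf[0]]), p.a_E, p.b_E, p.d_E)
        dS = -SE / p.tau_E + (1 - SE) * p.gamma_kinetic * rE[0]
        assert abs(dS) < 1e-8

    @pytest.mark.parametrize("w_EE,w_IE", [(0.21, 1.0), (0.5, 0.7), (0.05, 1.5)])
    def test_gating_variable_confined_to_unit_interval(self, w_EE, w_IE, rng):
        p = BEIParams(sigma=0.0, G=0.0, w_EE=w_EE, w_IE=w_IE)
        init = (rng.uniform(0, 1, 3), rng.uniform(0, 1, 3))
        res = simulate_bei(p, duration=5.0, dt=1e-3, seed=0, n_regions=3,
                           initial=init)
        assert res.neural.min() >= 0.0
        assert res.neural.max() <= 1.0

    def test_coupled_regions_and_bold_output(self):
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = BEIParams(sigma=0.005, G=1.0, C=C)
        res = simulate_bei(p, duration=10.0, dt=1e-3, seed=3, tr=0.72)
        assert res.neural.shape[0] == 2
        assert res.bold is not None
        assert np.isfinite(res.bold).all()

    def test_step_guard(self):
        with pytest.raises(ValueError, match="1 ms"):
            simulate_bei(BEIParams(), duration=1.0, dt=0.01)


class TestRsGrid:
    def test_default_grid_matches_protocol(self):
        grid = default_rs_grid()
        assert len(grid) == 20
        assert grid[0] == 10.0
        assert grid[-1] == 100.0
        np.testing.assert_allclose(np.diff(grid), np.diff(grid)[0])
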