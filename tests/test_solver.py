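"""Flow solver: boundary conditions, conservation, degeneracies, convergence.

Heavy validation against the Poiseuille/Womersley oracles and the idealized
stenosis experiment lives in test_acceptance.py; the runs here are small.
"""

import numpy as np
import pytest

import hemoflow as hf
from hemoflow.solver import SimulationConfig


def small_tube(n_axial=60, L=0.012, resolution=12, wall_layers=4):
    geom = hf.straight_geometry(D=0.003, L=L, n_axial=n_axial)
    hf.generate_mesh(geom, resolution=resolution, wall_layers=wall_layers)
    return geom


class TestInletProfile:
    def test_no_slip_and_centerline(self):
        geom = small_tube()
        wf = hf.coronary_waveform()
        umean = wf.q(0.1) / (np.pi * 0.0015 ** 2)
        assert hf.inlet_profile(0.1, 0.0015, wf, geom) == pytest.approx(0.0)
        assert hf.inlet_profile(0.1, 0.0, wf, geom) == pytest.approx(2 * umean)

    def test_flux_quadrature(self):
        geom = small_tube()
        wf = hf.coronary_waveform()
        r = np.linspace(0, 0.0015, 20001)
        u = hf.inlet_profile(0.2, r, wf, geom)
        q = np.trapezoid(u * 2 * np.pi * r, r)
        assert q == pytest.approx(wf.q(0.2), rel=1e-7)

    def test_planar_centerline_factor(self):
        # planar mode carries the per-depth flow Q/D across height D
        geom = small_tube()
        wf = hf.coronary_waveform()
        umean = wf.q(0.0) / (0.003 ** 2)
        assert hf.inlet_profile(0.0, 0.0, wf, geom, mode="planar") == \
            pytest.approx(1.5 * umean)

    def test_outside_radius(self):
        geom = small_tube()
        with pytest.raises(ValueError):
            hf.inlet_profile(0.0, 0.002, hf.coronary_waveform(), geom)


class TestConfigValidation:
    def test_bad_values(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_cycles=0)
        with pytest.raises(ValueError):
            SimulationConfig(outputs_per_cycle=1)
        with pytest.raises(ValueError):
            SimulationConfig(mean_inlet_flow=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(mode="3d")
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.5)  # exceeds cycle_period / outputs

    def test_waveform_period_mismatch(self):
        geom = small_tube()
        cfg = SimulationConfig(cycle_period=0.8, resolution=12, wall_layers=4)
        wf = hf.coronary_waveform(T=0.9)
        with pytest.raises(ValueError, match="period"):
            hf.run_pulsatile_simulation(geom, hf.RheologyParams(), wf, cfg)


class TestConservationAndPeriodicity:
    def test_pulsatile_mass_balance_every_instant(self):
        geom = small_tube()
        cfg = SimulationConfig(n_cycles=2, outputs_per_cycle=16,
                               resolution=12, wall_layers=4)
        wf = hf.coronary_waveform()
        flow = hf.run_pulsatile_simulation(geom, hf.RheologyParams(), wf, cfg)
        rel = np.abs(flow.diagnostics["flux_in"] - flow.diagnostics["flux_out"]) / \
            np.abs(flow.diagnostics["flux_in"])
        assert np.all(rel < 1e-3)          # required bound
        assert np.all(rel < 1e-10)         # projection is exact to LU precision
        assert flow.n_times == 16
        # realized inlet flux equals the prescribed waveform
        assert np.allclose(flow.diagnostics["flux_in"],
                           wf.q(flow.times + wf.T * (cfg.n_cycles - 1)), rtol=1e-9)

    def test_cycle_periodicity_diagnostic(self):
        geom = small_tube()
        cfg = SimulationConfig(n_cycles=3, outputs_per_cycle=16,
                               resolution=12, wall_layers=4)
        flow = hf.run_pulsatile_simulation(geom, hf.RheologyParams(),
                                           hf.coronary_waveform(), cfg)
        assert flow.diagnostics["cycle_periodicity"] < 0.01


class TestDegeneraciesAndInvariance:
    def test_quemada_k0_eq_kinf_matches_newtonian(self):
        """Constant-k Quemada must reproduce a Newtonian run at the same mu."""
        mu_c = 0.0012 * (1 - 0.5 * 2.07 * 0.45) ** -2
        geom = small_tube()
        cfg = SimulationConfig(resolution=12, wall_layers=4)
        f_n = hf.run_steady_simulation(
            geom, hf.RheologyParams(model="newtonian", mu_newtonian=mu_c),
            Q=0.83e-6, config=cfg, t_max=1.5)
        f_q = hf.run_steady_simulation(
            geom, hf.RheologyParams(model="quemada", k0=2.07, k_inf=2.07),
            Q=0.83e-6, config=cfg, t_max=1.5)
        assert np.allclose(f_q.u[0], f_n.u[0], atol=5e-4 * np.max(np.abs(f_n.u)))
        assert np.allclose(hf.compute_ess(f_q), hf.compute_ess(f_n), rtol=5e-3)

    def test_steady_state_independent_of_initialization(self):
        geom = small_tube()
        cfg = SimulationConfig(resolution=12, wall_layers=4)
        rheo = hf.RheologyParams()
        f1 = hf.run_steady_simulation(geom, rheo, Q=0.83e-6, config=cfg,
                                      t_max=2.0, tol=1e-6)
        Nx, Ny = len(geom.grid.x_centers), len(geom.grid.eta_centers)
        u0 = np.full((Nx + 1, Ny), 0.15)
        v0 = np.zeros((Nx, Ny + 1))
        f2 = hf.run_steady_simulation(geom, rheo, Q=0.83e-6, config=cfg,
                                      t_max=2.0, tol=1e-6, initial=(u0, v0))
        assert np.allclose(f1.u[0], f2.u[0], atol=2e-3 * np.max(np.abs(f1.u)))

    def test_finite_fields_and_shapes(self):
        geom = small_tube()
        cfg = SimulationConfig(n_cycles=1, outputs_per_cycle=8,
                               resolution=12, wall_layers=4)
        flow = hf.run_pulsatile_simulation(geom, hf.RheologyParams(),
                                           hf.coronary_waveform(), cfg)
        flow.check_finite()
        assert flow.u.shape == (8, 60, 12)


class TestGridRefinement:
    def test_wall_shear_converged_on_default_case(self):
        """Doubling the grid changes probe wall shear by < 2% (steady)."""
        spec = hf.StenosisSpec(mld_convention="clinical")
        vals = {}
        for n_ax, res in ((160, 12), (320, 24)):
            geom = hf.build_geometry(spec, n_axial=n_ax)
            hf.generate_mesh(geom, resolution=res, wall_layers=8)
            cfg = SimulationConfig(mode="planar", resolution=res, wall_layers=8)
            flow = hf.run_steady_simulation(geom, hf.RheologyParams(),
                                            Q=0.83e-6, config=cfg, t_max=2.5)
            ess = hf.compute_ess(flow)[0]
            x = flow.x
            # probes: proximal healthy, post-stenotic recovery, distal healthy
            vals[n_ax] = [ess[np.argmin(np.abs(x - xp))]
                          for xp in (-0.008, 0.005, 0.015, 0.025)]
        coarse, fine = np.array(vals[160]), np.array(vals[320])
        assert np.all(np.abs(coarse - fine) / np.abs(fine) < 0.02)
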