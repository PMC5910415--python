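"""Finite-element diffusion solver: conservation, accuracy, ROI integration."""

import numpy as np
import pytest

from frapfit.fem import (
    SimulationConfig,
    assemble_fem_matrices,
    integrate_over_roi,
    interpolate_initial_condition,
    logarithmic_timesteps,
    roi_mean_curve,
    simulate_diffusion,
)
from frapfit.fitting import rescale_time
from frapfit.geometry import Disc
from frapfit.meshing import generate_mesh
from frapfit.rois import AnnulusROI, CircleROI


@pytest.fixture(scope="module")
def disc_mesh():
    return generate_mesh(Disc(radius=60, center=(60, 60)), v=3.0)


class TestTimesteps:
    def test_two_steps_is_endpoints(self):
        np.testing.assert_allclose(logarithmic_timesteps(100, 2, 0.1), [0, 100])

    def test_geometric_progression(self):
        t = logarithmic_timesteps(1680, 80, 0.1)
        assert t[0] == 0 and t[-1] == pytest.approx(1680)
        ratios = t[2:] / t[1:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_strictly_increasing_and_dense_near_zero(self):
        t = logarithmic_timesteps(1000, 50, 0.05)
        assert (np.diff(t) > 0).all()
        assert np.diff(t)[0] < np.diff(t)[-1]

    @pytest.mark.parametrize("bad", [dict(n_steps=1), dict(t_first=0), dict(t_first=2000)])
    def test_invalid_arguments(self, bad):
        kwargs = dict(t_end=1000.0, n_steps=50, t_first=0.1)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            logarithmic_timesteps(**kwargs)


class TestInitialCondition:
    def test_uniform_frame_and_rim(self, disc_mesh):
        frame = np.full((120, 120), 3.0)
        ic = interpolate_initial_condition(frame, disc_mesh, c_rim=3.0, omega1=None)
        np.testing.assert_allclose(ic, 3.0)

    def test_node_at_pixel_center(self):
        from frapfit.meshing import Mesh

        frame = np.arange(16.0).reshape(4, 4)
        nodes = np.array([[2.0, 1.0], [0.0, 0.0], [3.0, 3.0]])
        mesh = Mesh(nodes, np.array([[0, 1, 2]]), np.array([1.0]), 2)
        ic = interpolate_initial_condition(frame, mesh, c_rim=0.0, omega1=None)
        # pixel (row=1, col=2) has value 6
        assert ic[0] == pytest.approx(6.0)
        assert ic[1] == pytest.approx(0.0)
        assert ic[2] == pytest.approx(15.0)

    def test_midpoint_of_four_pixels(self):
        from frapfit.meshing import Mesh

        frame = np.array([[1.0, 2.0], [3.0, 4.0]])
        nodes = np.array([[0.5, 0.5]])
        mesh = Mesh(nodes, np.array([[0, 0, 0]]), np.array([1.0]), 2)
        ic = interpolate_initial_condition(frame, mesh, c_rim=0.0, omega1=None)
        assert ic[0] == pytest.approx(2.5)

    def test_outside_omega1_gets_rim_value(self, disc_mesh):
        frame = np.zeros((120, 120))
        omega1 = CircleROI("slice", (60, 60), 30)
        ic = interpolate_initial_condition(frame, disc_mesh, c_rim=7.0, omega1=omega1)
        r = np.hypot(disc_mesh.nodes[:, 0] - 60, disc_mesh.nodes[:, 1] - 60)
        np.testing.assert_allclose(ic[r > 30], 7.0)
        np.testing.assert_allclose(ic[r < 29], 0.0)


class TestDiffusion:
    def test_uniform_ic_is_steady_state(self, disc_mesh):
        cfg = SimulationConfig(t_end=100, n_steps=30)
        res = simulate_diffusion(disc_mesh, np.full(disc_mesh.n_nodes, 2.5), cfg)
        np.testing.assert_allclose(res.nodal_values, 2.5, rtol=1e-8)

    def test_mass_conserved_under_neumann(self, disc_mesh):
        rng = np.random.default_rng(0)
        ic = rng.uniform(0, 1, disc_mesh.n_nodes)
        cfg = SimulationConfig(t_end=500, n_steps=60)
        res = simulate_diffusion(disc_mesh, ic, cfg)
        _, m = assemble_fem_matrices(disc_mesh)
        mass = res.nodal_values @ m
        np.testing.assert_allclose(mass, mass[0], rtol=1e-3)

    def test_maximum_principle(self, disc_mesh):
        yy = disc_mesh.nodes[:, 1]
        ic = np.where(yy > 60, 1.0, 0.0)
        cfg = SimulationConfig(t_end=200, n_steps=50)
        res = simulate_diffusion(disc_mesh, ic, cfg)
        eps = 0.005  # 0.5% of the unit range
        assert res.nodal_values.min() >= -eps
        assert res.nodal_values.max() <= 1 + eps

    def test_long_time_limit_is_spatial_mean(self, disc_mesh):
        rng = np.random.default_rng(1)
        ic = rng.uniform(0, 1, disc_mesh.n_nodes)
        _, m = assemble_fem_matrices(disc_mesh)
        mean = (m * ic).sum() / m.sum()
        cfg = SimulationConfig(t_end=50_000, n_steps=80)
        res = simulate_diffusion(disc_mesh, ic, cfg)
        np.testing.assert_allclose(res.nodal_values[-1], mean, rtol=0.01)

    def test_gaussian_spreading_matches_closed_form(self):
        # second spatial moment grows as <r^2>(t) = <r^2>(0) + 4 D t in 2D
        mesh = generate_mesh(Disc(radius=60, center=(0, 0)), v=2.0)
        r2 = (mesh.nodes**2).sum(axis=1)
        sigma0 = 8.0
        ic = np.exp(-r2 / (2 * sigma0**2))
        D = 5.0
        cfg = SimulationConfig(D_ref=D, t_end=20.0, n_steps=120, t_first=0.01)
        res = simulate_diffusion(mesh, ic, cfg)
        _, m = assemble_fem_matrices(mesh)
        for t_idx in [len(res.times) // 2, -1]:
            c = res.nodal_values[t_idx]
            t = res.times[t_idx]
            second = (m * c * r2).sum() / (m * c).sum()
            expected = 2 * sigma0**2 + 4 * D * t
            assert second == pytest.approx(expected, rel=0.02)

    def test_nonfinite_ic_rejected(self, disc_mesh):
        ic = np.full(disc_mesh.n_nodes, np.nan)
        with pytest.raises(ValueError):
            simulate_diffusion(disc_mesh, ic, SimulationConfig(t_end=10, n_steps=5))

    def test_self_similarity_rescaling_vs_resimulation(self, disc_mesh):
        """A curve rescaled from D_ref must match direct re-simulation at 2 D_ref."""
        yy, xx = disc_mesh.nodes[:, 1], disc_mesh.nodes[:, 0]
        ic = 1.0 - 0.9 * np.exp(-((xx - 60) ** 2 + (yy - 60) ** 2) / (2 * 12.0**2))
        roi = CircleROI("bleached", (60, 60), 15)
        cfg_ref = SimulationConfig(D_ref=50.0, t_end=400.0, n_steps=100)
        cfg_2x = SimulationConfig(D_ref=100.0, t_end=200.0, n_steps=100)
        res_ref = simulate_diffusion(disc_mesh, ic, cfg_ref)
        res_2x = simulate_diffusion(disc_mesh, ic, cfg_2x)
        curve_ref = roi_mean_curve(res_ref, roi)
        curve_2x = roi_mean_curve(res_2x, roi)
        t_query = np.linspace(0.0, 150.0, 80)
        a = rescale_time(res_ref.times, curve_ref, 100.0, 50.0, t_query)
        b = np.interp(t_query, res_2x.times, curve_2x)
        span = curve_ref.max() - curve_ref.min()
        assert np.max(np.abs(a - b)) < 0.01 * span


class TestRoiIntegration:
    def test_uniform_concentration_gives_roi_volume(self, disc_mesh):
        cfg = SimulationConfig(t_end=10, n_steps=5)
        res = simulate_diffusion(disc_mesh, np.ones(disc_mesh.n_nodes), cfg)
        roi = CircleROI("c", (60, 60), 20)
        integral = integrate_over_roi(res, roi, t=5.0)
        assert integral == pytest.approx(np.pi * 20**2, rel=0.02)

    def test_additivity_over_disjoint_rois(self, disc_mesh):
        rng = np.random.default_rng(3)
        ic = rng.uniform(0, 1, disc_mesh.n_nodes)
        res = simulate_diffusion(disc_mesh, ic, SimulationConfig(t_end=10, n_steps=5))
        inner = CircleROI("inner", (60, 60), 15)
        ring = AnnulusROI("ring", (60, 60), 15, 30)
        union = CircleROI("union", (60, 60), 30)
        a = integrate_over_roi(res, inner)
        b = integrate_over_roi(res, ring)
        c = integrate_over_roi(res, union)
        np.testing.assert_allclose(a + b, c, rtol=1e-6)

    def test_matches_fine_quadrature_oracle(self):
        # smooth field: element-centroid quadrature vs dense pixel sum
        mesh = generate_mesh(Disc(radius=40, center=(40, 40)), v=1.0)
        xx, yy = mesh.nodes[:, 0], mesh.nodes[:, 1]
        field = 1 + 0.5 * np.sin(xx / 9.0) * np.cos(yy / 7.0)
        res_like = simulate_diffusion(mesh, field, SimulationConfig(t_end=1e-6, n_steps=2))
        roi = CircleROI("c", (40, 40), 25)
        integral = integrate_over_roi(res_like, roi, t=0.0)
        h = 0.25
        g = np.arange(15, 65, h)
        gx, gy = np.meshgrid(g, g)
        inside = (gx - 40) ** 2 + (gy - 40) ** 2 < 25**2
        dense = ((1 + 0.5 * np.sin(gx / 9.0) * np.cos(gy / 7.0))[inside]).sum() * h * h
        assert integral == pytest.approx(dense, rel=0.01)

    def test_empty_roi_raises(self, disc_mesh):
        res = simulate_diffusion(
            disc_mesh, np.ones(disc_mesh.n_nodes), SimulationConfig(t_end=10, n_steps=5)
        )
        with pytest.raises(ValueError, match="intersects no"):
            integrate_over_roi(res, CircleROI("far", (500, 500), 5))

    def test_time_outside_range_raises(self, disc_mesh):
        res = simulate_diffusion(
            disc_mesh, np.ones(disc_mesh.n_nodes), SimulationConfig(t_end=10, n_steps=5)
        )
        with pytest.raises(ValueError):
            res.sample_nodal(100.0)
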