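"""Synthetic-data oracles: exactness, independence, determinism."""

import numpy as np
import pytest
from scipy import special

from frapfit import synthetic as syn
from frapfit.geometry import Disc
from frapfit.rois import extract_curves


class TestDiscEigenOracle:
    def test_single_mode_decays_exactly(self):
        # an eigenfunction initial condition has a closed-form decay
        R, D = 40.0, 12.0
        oracle = syn.DiscEigenOracle(R, n_modes=60)
        alpha1 = special.jn_zeros(1, 1)[0]
        f = lambda r: special.j0(alpha1 * r / R)
        r = np.linspace(0, R, 50)
        times = np.array([0.0, 3.0, 10.0])
        out = oracle.solve_radial(f, times, D, r)
        for i, t in enumerate(times):
            expected = special.j0(alpha1 * r / R) * np.exp(-D * (alpha1 / R) ** 2 * t)
            np.testing.assert_allclose(out[i], expected, atol=5e-4)

    def test_mass_conservation_of_series(self):
        R = 50.0
        oracle = syn.DiscEigenOracle(R)
        prof = lambda r: syn.radial_bleach_profile(r, 15.0, 0.1, 3.0)
        times = np.array([0.0, 50.0, 5000.0])
        r = np.linspace(0, R, 2000)
        out = oracle.solve_radial(prof, times, 20.0, r)
        masses = [np.trapezoid(out[i] * r, r) for i in range(3)]
        np.testing.assert_allclose(masses, masses[0], rtol=1e-6)
        # long-time limit: uniform at the mass-weighted mean
        assert np.ptp(out[-1]) < 1e-6

    def test_fd_solver_cross_validates_eigen_solution(self):
        """The two independent forward routes agree on the disc."""
        R, D = 40.0, 25.0
        geom = Disc(radius=R, center=(41.5, 41.5))
        oracle = syn.DiscEigenOracle(R)
        prof = lambda r: syn.radial_bleach_profile(r, 14.0, 0.1, 3.0)
        coeffs = oracle.project(prof)
        fd = syn.MaskedGridFD(geom, h=1.0)
        c0 = fd.fill_initial(lambda p: prof(np.hypot(p[:, 0] - 41.5, p[:, 1] - 41.5)))
        times = np.array([0.0, 4.0, 12.0, 30.0])
        snaps = fd.solve(c0, D, times)
        mesh = np.meshgrid(*fd.axes[::-1], indexing="ij")
        rr = np.hypot(mesh[-1] - 41.5, mesh[-2] - 41.5)
        # field agreement away from the staircase boundary, relative to the
        # initial dynamic range
        mask = fd.mask & (rr < 0.8 * R)
        eig = oracle.evaluate(coeffs, rr[mask], times, D)
        span0 = np.ptp(eig[0])
        for i in range(1, len(times)):
            assert np.abs(snaps[i][mask] - eig[i]).max() < 0.011 * span0
        # recovery-curve agreement (what the pipeline consumes): ≤ 0.5%
        roi = fd.mask & (rr < 14.0)
        fd_curve = np.array([s[roi].mean() for s in snaps])
        eig_curve = oracle.evaluate(coeffs, rr[roi], times, D).mean(axis=1)
        assert np.abs(fd_curve - eig_curve).max() < 0.005 * np.ptp(eig_curve)

    def test_fd_substepping_respects_stability(self):
        geom = Disc(radius=15, center=(16, 16))
        fd = syn.MaskedGridFD(geom, h=1.0)
        c0 = fd.fill_initial(lambda p: (p[:, 0] > 16).astype(float))
        snaps = fd.solve(c0, 500.0, np.array([0.0, 1.0]))  # needs many substeps
        assert np.isfinite(snaps).all()
        assert snaps[1][fd.mask].min() >= -1e-9
        assert snaps[1][fd.mask].max() <= 1 + 1e-9


class TestGenerator:
    def test_uniform_unbleached_sample_is_static(self):
        truth = syn.SyntheticGroundTruth(D_true=50.0, bleach_depth=1.0, noise_sd=0.0)
        ds = syn.generate_frap_dataset(truth, n_frames=4)
        # identical up to the spectral truncation of the series solution
        # (largest wiggle sits at the disc centre)
        for j in range(1, 4):
            np.testing.assert_allclose(ds.stack.frames[j], ds.stack.frames[0], atol=5e-4)

    def test_same_seed_same_checksum(self):
        truth = syn.SyntheticGroundTruth(D_true=30.0, noise_sd=0.05, seed=11)
        a = syn.generate_frap_dataset(truth, n_frames=5)
        b = syn.generate_frap_dataset(truth, n_frames=5)
        assert a.manifest["checksum_sha256"] == b.manifest["checksum_sha256"]

    def test_different_seeds_differ(self):
        t1 = syn.SyntheticGroundTruth(D_true=30.0, noise_sd=0.05, seed=11)
        t2 = syn.SyntheticGroundTruth(D_true=30.0, noise_sd=0.05, seed=12)
        a = syn.generate_frap_dataset(t1, n_frames=5)
        b = syn.generate_frap_dataset(t2, n_frames=5)
        assert a.manifest["checksum_sha256"] != b.manifest["checksum_sha256"]

    def test_reaction_field_composition_matches_curve_kinetics(self, disc_truth, standard_rois):
        """Field-level production/degradation equals curve-level application."""
        from frapfit.fitting import apply_reaction_kinetics

        base = syn.generate_frap_dataset(disc_truth, n_frames=40)
        t_dpd = syn.SyntheticGroundTruth(D_true=disc_truth.D_true, k1_true=3e-3, k2_true=2e-3)
        ds = syn.generate_frap_dataset(t_dpd, n_frames=40)
        rois = [standard_rois["bleached"], standard_rois["slice"]]
        clean = extract_curves(base.stack, rois)
        reacted = extract_curves(ds.stack, rois)
        for name in ("bleached", "slice"):
            expected = apply_reaction_kinetics(
                clean[name].values, clean.times, 3e-3, 2e-3, "diffusion_production_degradation"
            )
            np.testing.assert_allclose(reacted[name].values, expected, rtol=1e-9)

    def test_noise_is_clipped_at_zero(self):
        truth = syn.SyntheticGroundTruth(D_true=30.0, noise_sd=0.5, seed=3)
        ds = syn.generate_frap_dataset(truth, n_frames=3)
        assert ds.stack.frames.min() >= 0.0

    def test_vignette_illumination_dims_corners(self):
        truth = syn.SyntheticGroundTruth(
            D_true=30.0, illumination={"kind": "vignette", "strength": 0.5}
        )
        ds = syn.generate_frap_dataset(truth, n_frames=2)
        plain = syn.generate_frap_dataset(syn.SyntheticGroundTruth(D_true=30.0), n_frames=2)
        ratio = ds.stack.frames[0] / np.maximum(plain.stack.frames[0], 1e-9)
        cy, cx = 100, 100
        assert ratio[cy, cx] > ratio[5, 5]


class TestBenchmarkSuite:
    def test_manifest_counts_and_determinism(self, tmp_path):
        datasets, manifest = syn.generate_benchmark_suite(
            out_dir=tmp_path, seed=5, include_reaction_grid=False,
            n_frames_2d=6, n_frames_3d=4, dome_scale=0.35, fd_spacing_3d=2.0,
        )
        assert len(manifest) == 18
        assert sorted(manifest["grid"].unique()) == ["geometry"]
        assert (tmp_path / "manifest.csv").exists()
        assert len(list(tmp_path.glob("*.tif"))) == 18
        _, manifest2 = syn.generate_benchmark_suite(
            seed=5, include_reaction_grid=False,
            n_frames_2d=6, n_frames_3d=4, dome_scale=0.35, fd_spacing_3d=2.0,
        )
        assert list(manifest["checksum_sha256"]) == list(manifest2["checksum_sha256"])

    def test_reaction_grid_has_24_members(self):
        truths = syn.reaction_grid_truths(0, n_rate_variants=2)
        assert len(truths) == 24
        models = {t.kinetic_model for t in truths}
        assert len(models) == 4


class TestHindrance:
    def test_unhindered(self):
        theta, lam = syn.hindrance_factor(24.0, 24.0)
        assert theta == 1.0 and lam == 1.0

    def test_bead_experiment_values(self):
        # 70 kDa dextran with and without beads: 14.9 vs 24.1 um^2/s
        theta, lam = syn.hindrance_factor(14.9, 24.1)
        assert theta == pytest.approx(0.618, abs=0.005)

    def test_theta_lambda_identity(self, rng):
        for _ in range(10):
            d_eff, d_free = rng.uniform(0.1, 100, 2)
            theta, lam = syn.hindrance_factor(d_eff, d_free)
            assert theta * lam**2 == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            syn.hindrance_factor(0.0, 10.0)


class TestTortuosityTrivial:
    def test_no_obstacles_gives_unit_hindrance(self):
        exp = syn.run_tortuosity_experiment(2, "packed", 0.999, seed=0, starts=3)
        assert exp.theta == pytest.approx(1.0, abs=0.05)
        assert exp.reduction_pct == pytest.approx(0.0, abs=5.0)
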