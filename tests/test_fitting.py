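"""Time rescaling, reaction kinetics, equalisation and model fitting."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from frapfit.fitting import (
    FRAPModel,
    ReferenceCurves,
    apply_reaction_kinetics,
    compute_ssd,
    equalise,
    rescale_time,
)
from frapfit.rois import RecoveryCurve


class TestRescaleTime:
    def setup_method(self):
        self.t_sim = np.concatenate([[0], np.geomspace(0.1, 1000, 200)])
        self.values = 1 - 0.9 * np.exp(-self.t_sim / 50.0)

    def test_identity_at_reference(self):
        t = np.linspace(0, 100, 50)
        out = rescale_time(self.t_sim, self.values, 50.0, 50.0, t)
        np.testing.assert_allclose(out, np.interp(t, self.t_sim, self.values))

    def test_factor_four_speedup(self):
        # curve at D = 4 D_ref and time t equals reference curve at 4t
        t = np.linspace(0, 200, 40)
        fast = rescale_time(self.t_sim, self.values, 200.0, 50.0, t)
        direct = np.interp(4 * t, self.t_sim, self.values)
        np.testing.assert_allclose(fast, direct)

    def test_horizon_exceeded_raises(self):
        with pytest.raises(ValueError, match="horizon"):
            rescale_time(self.t_sim, self.values, 500.0, 50.0, np.array([500.0]))

    def test_self_similarity_consistency(self):
        # rescale(D1) evaluated at (D2/D1) t equals rescale(D2) at t
        d1, d2 = 30.0, 90.0
        t = np.linspace(0, 100, 64)
        a = rescale_time(self.t_sim, self.values, d1, 50.0, (d2 / d1) * t)
        b = rescale_time(self.t_sim, self.values, d2, 50.0, t)
        np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_nonpositive_d_rejected(self):
        with pytest.raises(ValueError):
            rescale_time(self.t_sim, self.values, 0.0, 50.0, np.array([1.0]))


class TestKinetics:
    def setup_method(self):
        self.t = np.linspace(0, 300, 100)
        self.c = 1 - 0.8 * np.exp(-self.t / 40.0)

    @pytest.mark.parametrize(
        "model", ["diffusion", "diffusion_production", "diffusion_degradation", "diffusion_production_degradation"]
    )
    def test_zero_rates_identity(self, model):
        out = apply_reaction_kinetics(self.c, self.t, 0.0, 0.0, model)
        np.testing.assert_allclose(out, self.c)

    def test_degradation_decays_to_zero(self):
        t = np.linspace(0, 1e5, 200)
        out = apply_reaction_kinetics(np.ones_like(t), t, k1=0.01, model="diffusion_degradation")
        assert out[-1] == pytest.approx(0.0, abs=1e-12)

    def test_production_degradation_matches_ode_oracle(self):
        # dc/dt = k2 - k1 c with c(0)=0: compare to numerical integration
        k1, k2 = 0.013, 0.004
        t = np.linspace(0, 400, 60)
        out = apply_reaction_kinetics(
            np.zeros_like(t), t, k1=k1, k2=k2, model="diffusion_production_degradation"
        )
        sol = solve_ivp(lambda _, c: k2 - k1 * c, (0, 400), [0.0], t_eval=t, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(out, sol.y[0], rtol=1e-6)
        assert out[-1] == pytest.approx(k2 / k1, rel=0.01)

    def test_both_model_k1_zero_limit_is_production(self):
        t = np.linspace(0, 100, 20)
        out = apply_reaction_kinetics(self.c[:20], t, k1=0.0, k2=0.002, model="diffusion_production_degradation")
        np.testing.assert_allclose(out, self.c[:20] + 0.002 * t)

    def test_as_printed_variant_differs(self):
        t = np.linspace(1, 100, 20)
        default = apply_reaction_kinetics(self.c[:20], t, 0.01, 0.002, "diffusion_production_degradation")
        printed = apply_reaction_kinetics(
            self.c[:20], t, 0.01, 0.002, "diffusion_production_degradation", as_printed=True
        )
        assert not np.allclose(default, printed)
        # printed form does not satisfy the rate-equation steady state
        assert printed[0] > default[0]

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            apply_reaction_kinetics(self.c, self.t, k1=-1.0, model="diffusion_degradation")


class TestEqualise:
    def test_minimum_maps_to_zero(self):
        out = equalise(np.array([2.0, 5.0]), E=1.0, c_min=2.0, c_max=3.0)
        assert out[0] == 0.0

    def test_unit_scale_value(self):
        # value c_max + c_min maps to 1 at E=1
        out = equalise(np.array([5.0]), E=1.0, c_min=2.0, c_max=3.0)
        assert out[0] == pytest.approx(1.0)

    def test_doubling_factor_halves_curve(self):
        v = np.array([1.0, 2.0, 4.0])
        a = equalise(v, 1.0, 0.5, 2.0)
        b = equalise(v, 2.0, 0.5, 2.0)
        np.testing.assert_allclose(b, a / 2)

    def test_flat_signal_raises(self):
        with pytest.raises(ValueError, match="flat"):
            equalise(np.array([1.0]), 1.0, 2.0, 2.0)


class TestSSD:
    def test_identical_curves_zero(self):
        c = {"bleached": np.arange(5.0)}
        assert compute_ssd(c, c) == 0.0

    def test_unit_residuals(self):
        model = {"roi": np.array([1.0, 0.0])}
        data = {"roi": np.array([0.0, 1.0])}
        assert compute_ssd(model, data) == 2.0

    def test_bruteforce_oracle(self, rng):
        model = {"a": rng.normal(size=30), "b": rng.normal(size=30)}
        data = {"a": rng.normal(size=30), "b": rng.normal(size=30)}
        expected = sum(((model[k] - data[k]) ** 2).sum() for k in model)
        assert compute_ssd(model, data) == pytest.approx(expected)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="resampling"):
            compute_ssd({"a": np.zeros(5)}, {"a": np.zeros(6)})


def _toy_reference(D_ref=50.0, tau_scale=2000.0):
    """Analytic stand-in for a simulated recovery: exponential approach."""
    t = np.concatenate([[0], np.geomspace(0.05, 20000, 300)])
    bleached = 1 - 0.9 * np.exp(-D_ref * t / tau_scale)
    slc = 1 - 0.3 * np.exp(-D_ref * t / tau_scale)
    return ReferenceCurves(times=t, curves={"bleached": bleached, "slice": slc}, D_ref=D_ref)


def _toy_data(reference, D_true, times, k1=0.0, k2=0.0, model="diffusion"):
    curves = {}
    for name in ("bleached", "slice"):
        diff = rescale_time(reference.times, reference.curves[name], D_true, reference.D_ref, times)
        vals = apply_reaction_kinetics(diff, times, k1, k2, model)
        curves[name] = RecoveryCurve(name, times, vals)
    return curves


class TestFitModel:
    times = np.arange(0.0, 300.0)

    def test_pure_diffusion_recovery(self):
        ref = _toy_reference()
        data = _toy_data(ref, D_true=23.0, times=self.times)
        fit = FRAPModel(data, ref).fit(starts=5)
        assert fit.D == pytest.approx(23.0, rel=0.05)

    def test_production_model_recovery(self):
        ref = _toy_reference()
        data = _toy_data(ref, 40.0, self.times, k2=2e-3, model="diffusion_production")
        fit = FRAPModel(data, ref, kinetics="diffusion_production").fit(starts=5)
        assert fit.D == pytest.approx(40.0, rel=0.10)
        assert fit.k2 == pytest.approx(2e-3, rel=0.10)

    def test_fixed_rate_is_respected(self):
        ref = _toy_reference()
        data = _toy_data(ref, 40.0, self.times, k2=2e-3, model="diffusion_production")
        fit = FRAPModel(data, ref, kinetics="diffusion_production", fixed_k2=2e-3).fit(starts=3)
        assert fit.k2 == 2e-3
        assert fit.k_params == 1
        assert fit.D == pytest.approx(40.0, rel=0.05)

    def test_fit_never_worse_than_best_start(self):
        ref = _toy_reference()
        data = _toy_data(ref, 15.0, self.times)
        fit = FRAPModel(data, ref).fit(starts=5)
        assert fit.ssd <= fit.starts["ssd0"].min() + 1e-12

    def test_nested_model_dominance(self):
        ref = _toy_reference()
        data = _toy_data(ref, 30.0, self.times)
        noisy = {
            n: RecoveryCurve(n, self.times, c.values + np.random.default_rng(0).normal(0, 0.01, len(c.values)))
            for n, c in data.items()
        }
        ssd_d = FRAPModel(noisy, ref).fit(starts=5).ssd
        ssd_dp = FRAPModel(noisy, ref, kinetics="diffusion_production").fit(starts=5).ssd
        assert ssd_dp <= ssd_d * (1 + 1e-6)

    def test_nelder_mead_matches_bruteforce_grid(self):
        ref = _toy_reference()
        data = _toy_data(ref, 37.0, self.times)
        model = FRAPModel(data, ref)
        fit = model.fit(starts=5)
        grid = np.geomspace(fit.D / 10, fit.D * 10, 201)
        ssds = [model.ssd({"D": d}) for d in grid]
        d_grid = grid[int(np.argmin(ssds))]
        step = grid[1] / grid[0]
        assert fit.D / d_grid < step and d_grid / fit.D < step

    def test_equalised_fit_scale_invariance(self):
        ref = _toy_reference()
        data = _toy_data(ref, 25.0, self.times)
        scaled = {n: RecoveryCurve(n, self.times, 3.7 * c.values) for n, c in data.items()}
        fit = FRAPModel(scaled, ref, equalise=True).fit(starts=4)
        assert fit.D == pytest.approx(25.0, rel=0.05)
        assert fit.k_params == 3  # D + two equalisation factors

    def test_summary_mentions_model_and_estimates(self):
        ref = _toy_reference()
        data = _toy_data(ref, 23.0, self.times)
        fit = FRAPModel(data, ref).fit(starts=2)
        text = fit.summary()
        assert "diffusion" in text and "D " in text and "SSD" in text

    def test_end_to_end_pipeline_recovery(self, disc_truth, disc_curves, disc_reference):
        """Image series from the eigenfunction oracle, fitted through the
        full FEM/self-similarity pipeline."""
        fit = FRAPModel(disc_curves, disc_reference).fit(starts=3)
        assert fit.D == pytest.approx(disc_truth.D_true, rel=0.05)
        assert fit.r_squared()["mean"] > 0.999
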