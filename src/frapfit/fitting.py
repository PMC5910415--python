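"""Reaction-diffusion model fitting to FRAP recovery curves.

A single diffusion simulation at a reference diffusivity D_ref serves
every candidate D through the self-similarity of the diffusion equation:
the recovery at diffusivity D and time t equals the reference recovery at
time (D/D_ref)·t. Spatially uniform reaction kinetics enter analytically
on top of the rescaled diffusion curve:

* production:                c + k2·t
* degradation:               c·exp(−k1·t)
* production + degradation:  c·exp(−k1·t) + (1 − exp(−k1·t))·k2/k1

(the last expression is the closed-form response of dc/dt = k2 − k1·c and
reduces to k2·t as k1 → 0; ``as_printed=True`` switches the sign inside
the parenthesis to +, reproducing a published variant of the formula that
does not satisfy the rate equation).

Optional equalisation maps simulated and measured curves onto a common
[0, 1] scale — (value − c_min)/(c_max·E_i) with per-ROI factors E_i —
absorbing immobile fractions and out-of-plane intensity changes. The
objective is the sum of squared differences (SSD) over the bleached and
slice ROIs and all time points, minimised by Nelder–Mead in log-parameter
space (which enforces positivity) with multiple starts for D log-spaced
over two orders of magnitude around a half-recovery-time pilot estimate.

The public surface follows the statsmodels convention: build a
:class:`FRAPModel` from data plus a reference simulation, call ``fit()``,
and read estimates, diagnostics and ``summary()`` off the returned
:class:`FRAPFitResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .fem import SimulationResult, roi_mean_curve
from .rois import ROI, RecoveryCurveSet

__all__ = [
    "KINETIC_MODELS",
    "ReferenceCurves",
    "rescale_time",
    "apply_reaction_kinetics",
    "equalise",
    "compute_ssd",
    "FRAPModel",
    "FRAPFitResult",
    "fit_model",
]

#: kinetic model catalogue → rate parameters fitted on top of D
KINETIC_MODELS = {
    "diffusion": (),
    "diffusion_production": ("k2",),
    "diffusion_degradation": ("k1",),
    "diffusion_production_degradation": ("k1", "k2"),
}

MODEL_ALIASES = {
    "d": "diffusion",
    "dp": "diffusion_production",
    "dd": "diffusion_degradation",
    "dpd": "diffusion_production_degradation",
}


def canonical_model(name: str) -> str:
    name = MODEL_ALIASES.get(name, name)
    if name not in KINETIC_MODELS:
        raise ValueError(f"unknown kinetic model {name!r}")
    return name


@dataclass
class ReferenceCurves:
    """ROI-mean recovery curves of the reference simulation."""

    times: np.ndarray
    curves: dict[str, np.ndarray]
    D_ref: float

    @classmethod
    def from_simulation(cls, result: SimulationResult, rois: Sequence[ROI] | Mapping[str, ROI]) -> "ReferenceCurves":
        if isinstance(rois, Mapping):
            rois = list(rois.values())
        curves = {roi.name: roi_mean_curve(result, roi) for roi in rois}
        return cls(times=result.times.copy(), curves=curves, D_ref=result.D_ref)

    @property
    def horizon(self) -> float:
        return float(self.times[-1])


def rescale_time(
    sim_times: np.ndarray,
    sim_values: np.ndarray,
    D: float,
    D_ref: float,
    t_query: np.ndarray,
) -> np.ndarray:
    """Evaluate the reference-diffusivity curve at candidate diffusivity D:
    value(t; D) = value((D/D_ref)·t; D_ref), by monotone (linear)
    interpolation on the simulation grid."""
    if D <= 0:
        raise ValueError("D must be positive")
    t_query = np.asarray(t_query, dtype=float)
    t_sim = (D / D_ref) * t_query
    if t_sim.size and t_sim.max() > sim_times[-1] * (1 + 1e-9):
        raise ValueError(
            f"simulation horizon too short: need t={t_sim.max():.4g}, have {sim_times[-1]:.4g}"
        )
    return np.interp(t_sim, sim_times, sim_values)


def apply_reaction_kinetics(
    values: np.ndarray,
    times: np.ndarray,
    k1: float = 0.0,
    k2: float = 0.0,
    model: str = "diffusion",
    as_printed: bool = False,
) -> np.ndarray:
    """Superpose spatially uniform production/degradation on a diffusion
    recovery curve."""
    if k1 < 0 or k2 < 0:
        raise ValueError("rates must be non-negative")
    model = canonical_model(model)
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if model == "diffusion":
        return values
    if model == "diffusion_production":
        return values + k2 * times
    if model == "diffusion_degradation":
        return values * np.exp(-k1 * times)
    decay = np.exp(-k1 * times)
    if k1 == 0.0:
        return values + k2 * times  # k1→0 limit
    sign = +1.0 if as_printed else -1.0
    return values * decay + (1.0 + sign * decay) * (k2 / k1)


def equalise(values: np.ndarray, E: float, c_min: float, c_max: float) -> np.ndarray:
    """Map a curve onto the common [0, 1] recovery scale:
    (value − c_min)/(c_max·E)."""
    if c_max == c_min:
        raise ValueError("flat signal: c_max equals c_min")
    if E <= 0:
        raise ValueError("equalisation factors must be positive")
    return (np.asarray(values, dtype=float) - c_min) / (c_max * E)


def compute_ssd(
    model_curves: Mapping[str, np.ndarray],
    data_curves: Mapping[str, np.ndarray],
) -> float:
    """Sum of squared differences over ROIs and time points."""
    ssd = 0.0
    for name, d in data_curves.items():
        m = np.asarray(model_curves[name], dtype=float)
        d = np.asarray(d, dtype=float)
        if m.shape != d.shape:
            raise ValueError(f"time grids differ for ROI {name!r}; no implicit resampling")
        r = m - d
        ssd += float(r @ r)
    return ssd


def _half_time(times: np.ndarray, values: np.ndarray) -> float | None:
    """First crossing of the midpoint between the initial and final value."""
    v0, v1 = values[0], values[-1]
    if not np.isfinite(v0) or not np.isfinite(v1) or v1 == v0:
        return None
    half = 0.5 * (v0 + v1)
    rising = v1 > v0
    crossed = values >= half if rising else values <= half
    idx = np.argmax(crossed)
    if not crossed[idx] or idx == 0:
        return None
    t0, t1 = times[idx - 1], times[idx]
    w0, w1 = values[idx - 1], values[idx]
    if w1 == w0:
        return float(t1)
    return float(t0 + (half - w0) / (w1 - w0) * (t1 - t0))


BLEACHED = "bleached"
SLICE = "slice"


class FRAPModel:
    """Reaction-diffusion recovery model bound to one data set.

    Parameters
    ----------
    data : RecoveryCurveSet or mapping of ROI name → RecoveryCurve
        Measured mean-intensity curves; must contain the ``bleached`` and
        ``slice`` ROIs (the two fitted regions).
    reference : ReferenceCurves
        ROI-mean curves of the diffusion simulation at D_ref.
    kinetics : str
        One of ``diffusion``, ``diffusion_production``,
        ``diffusion_degradation``, ``diffusion_production_degradation``
        (aliases d/dp/dd/dpd).
    equalise : bool
        Fit per-ROI equalisation factors on the common [0, 1] scale.
    fixed_k1, fixed_k2 : float, optional
        Pin a rate to an externally measured value instead of fitting it.
    """

    def __init__(
        self,
        data,
        reference: ReferenceCurves,
        kinetics: str = "diffusion",
        equalise: bool = False,
        fixed_k1: float | None = None,
        fixed_k2: float | None = None,
        as_printed: bool = False,
        fit_rois: Sequence[str] = (BLEACHED, SLICE),
    ):
        if isinstance(data, RecoveryCurveSet):
            self.times = np.asarray(data.times, dtype=float)
            self.data = {name: np.asarray(data[name].values, dtype=float) for name in fit_rois}
        else:
            curves = dict(data)
            first = next(iter(curves.values()))
            self.times = np.asarray(first.times, dtype=float)
            self.data = {name: np.asarray(curves[name].values, dtype=float) for name in fit_rois}
        self.reference = reference
        self.kinetics = canonical_model(kinetics)
        self.equalise = bool(equalise)
        self.fixed_k1 = fixed_k1
        self.fixed_k2 = fixed_k2
        self.as_printed = bool(as_printed)
        self.fit_rois = tuple(fit_rois)
        for name in self.fit_rois:
            if name not in reference.curves:
                raise ValueError(f"reference simulation lacks ROI {name!r}")
        self._free_rates = [
            r
            for r in KINETIC_MODELS[self.kinetics]
            if (r == "k1" and fixed_k1 is None) or (r == "k2" and fixed_k2 is None)
        ]
        # parameter layout in log space: [D, free rates..., E_i...]
        self.param_names = ["D"] + list(self._free_rates)
        if self.equalise:
            self.param_names += [f"E_{name}" for name in self.fit_rois]

    # -- model evaluation --------------------------------------------------
    @property
    def nobs(self) -> int:
        return sum(len(v) for v in self.data.values())

    @property
    def k_params(self) -> int:
        """Fitted parameter count (D + free rates + equalisation factors)."""
        return len(self.param_names)

    def _rates(self, params: Mapping[str, float]) -> tuple[float, float]:
        k1 = params.get("k1", self.fixed_k1 if self.fixed_k1 is not None else 0.0)
        k2 = params.get("k2", self.fixed_k2 if self.fixed_k2 is not None else 0.0)
        return float(k1), float(k2)

    def predict(self, params: Mapping[str, float]) -> dict[str, np.ndarray]:
        """Model curves at the data times (equalised scale if enabled)."""
        D = float(params["D"])
        k1, k2 = self._rates(params)
        curves = {}
        for name in self.fit_rois:
            diff = rescale_time(
                self.reference.times, self.reference.curves[name], D, self.reference.D_ref, self.times
            )
            curves[name] = apply_reaction_kinetics(
                diff, self.times, k1=k1, k2=k2, model=self.kinetics, as_printed=self.as_printed
            )
        if self.equalise:
            c_min = curves[BLEACHED].min()
            c_max = curves[SLICE].max()
            curves = {
                name: equalise(curves[name], float(params.get(f"E_{name}", 1.0)), c_min, c_max)
                for name in curves
            }
        return curves

    def observed(self) -> dict[str, np.ndarray]:
        """Data curves on the scale the objective compares against."""
        if not self.equalise:
            return dict(self.data)
        d_min = self.data[BLEACHED].min()
        d_max = self.data[SLICE].max()
        return {name: equalise(v, 1.0, d_min, d_max) for name, v in self.data.items()}

    def ssd(self, params: Mapping[str, float]) -> float:
        try:
            model_curves = self.predict(params)
        except ValueError:
            return np.inf  # beyond the simulation horizon
        return compute_ssd(model_curves, self.observed())

    def _unpack(self, theta: np.ndarray) -> dict[str, float]:
        return {name: float(np.exp(t)) for name, t in zip(self.param_names, theta)}

    def _objective(self, theta: np.ndarray) -> float:
        val = self.ssd(self._unpack(theta))
        return val if np.isfinite(val) else 1e300

    # -- fitting -----------------------------------------------------------
    def pilot_diffusivity(self) -> float:
        """Half-recovery-time pilot estimate of D."""
        t_half_data = _half_time(self.times, self.data[BLEACHED])
        t_half_sim = _half_time(self.reference.times, self.reference.curves[BLEACHED])
        if t_half_data is None or t_half_sim is None or t_half_data <= 0:
            return self.reference.D_ref
        return float(self.reference.D_ref * t_half_sim / t_half_data)

    def _initial_guesses(self, starts: int) -> list[np.ndarray]:
        d_pilot = self.pilot_diffusivity()
        # the horizon caps the largest testable D
        d_cap = 0.95 * self.reference.D_ref * self.reference.horizon / max(self.times[-1], 1e-12)
        d_values = np.geomspace(d_pilot / 10.0, min(d_pilot * 10.0, d_cap), max(1, starts))
        span = self.data[SLICE].max() - self.data[BLEACHED].min()
        t_span = max(self.times[-1], 1e-12)
        guesses = []
        for d0 in d_values:
            g = {"D": min(d0, d_cap)}
            if "k1" in self._free_rates:
                g["k1"] = 1.0 / t_span
            if "k2" in self._free_rates:
                g["k2"] = max(0.1 * span / t_span, 1e-12)
            for name in self.fit_rois:
                if self.equalise:
                    g[f"E_{name}"] = 1.0
            guesses.append(np.log([g[p] for p in self.param_names]))
        return guesses

    def fit(
        self,
        starts: int = 5,
        maxiter: int = 2000,
        xtol: float = 1e-8,
        ftol: float = 1e-8,
    ) -> "FRAPFitResult":
        """Multi-start constrained Nelder–Mead minimisation of the SSD.

        Positivity is enforced by optimising in log-parameter space. The
        start yielding the minimum SSD wins; per-start outcomes are kept in
        the result's ``starts`` table.
        """
        rows = []
        best = None
        for i, theta0 in enumerate(self._initial_guesses(starts)):
            f0 = self._objective(theta0)
            res = minimize(
                self._objective,
                theta0,
                method="Nelder-Mead",
                options={
                    "maxiter": maxiter,
                    "xatol": xtol,
                    "fatol": ftol * max(f0, 1e-30),
                    "adaptive": len(theta0) > 2,
                },
            )
            rows.append(
                {
                    "start": i,
                    "D0": float(np.exp(theta0[0])),
                    "ssd0": f0,
                    "ssd": float(res.fun),
                    "converged": bool(res.success),
                    "n_iter": int(res.nit),
                }
            )
            if best is None or res.fun < best.fun:
                best = res
        starts_table = pd.DataFrame(rows)
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"all fit starts failed:\n{starts_table}")
        params = self._unpack(best.x)
        return FRAPFitResult(model=self, params=params, ssd=float(best.fun), starts=starts_table)


@dataclass
class FRAPFitResult:
    """Fit outcome: estimates, goodness of fit and per-start diagnostics."""

    model: FRAPModel
    params: dict[str, float]
    ssd: float
    starts: pd.DataFrame = field(repr=False)

    @property
    def D(self) -> float:
        return self.params["D"]

    @property
    def k1(self) -> float:
        return self.model._rates(self.params)[0]

    @property
    def k2(self) -> float:
        return self.model._rates(self.params)[1]

    @property
    def equalisation_factors(self) -> dict[str, float]:
        return {n: v for n, v in self.params.items() if n.startswith("E_")}

    @property
    def k_params(self) -> int:
        return self.model.k_params

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def n_starts_converged(self) -> int:
        return int(self.starts["converged"].sum())

    def D_physical(self, pixel_size_um: float) -> float:
        """Convert D from pixels²/s to μm²/s."""
        return self.D * pixel_size_um**2

    def fitted_curves(self) -> dict[str, np.ndarray]:
        return self.model.predict(self.params)

    def r_squared(self) -> dict[str, float]:
        """Per-ROI R² plus 'mean' and 'product' aggregates."""
        from .selection import r_squared

        fitted = self.fitted_curves()
        observed = self.model.observed()
        per_roi = {name: r_squared(fitted[name], observed[name]) for name in observed}
        vals = list(per_roi.values())
        per_roi["mean"] = float(np.mean(vals))
        per_roi["product"] = float(np.prod(vals))
        return per_roi

    def summary(self) -> str:
        lines = [
            "FRAP reaction-diffusion fit",
            "===========================",
            f"kinetic model:     {self.model.kinetics}",
            f"equalisation:      {'on' if self.model.equalise else 'off'}",
            f"n observations:    {self.nobs}  (ROIs: {', '.join(self.model.fit_rois)})",
            f"fitted parameters: {self.k_params}",
            f"starts converged:  {self.n_starts_converged}/{len(self.starts)}",
            "",
            f"D    = {self.D:.6g} px^2/s",
        ]
        if "k1" in KINETIC_MODELS[self.model.kinetics]:
            src = "fitted" if "k1" in self.params else "fixed"
            lines.append(f"k1   = {self.k1:.6g} 1/s ({src})")
        if "k2" in KINETIC_MODELS[self.model.kinetics]:
            src = "fitted" if "k2" in self.params else "fixed"
            lines.append(f"k2   = {self.k2:.6g} intensity/s ({src})")
        for name, val in self.equalisation_factors.items():
            lines.append(f"{name} = {val:.6g}")
        r2 = self.r_squared()
        lines += [
            f"SSD  = {self.ssd:.6g}",
            f"R^2  = " + ", ".join(f"{k}: {v:.4f}" for k, v in r2.items()),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model.kinetics,
            "equalise": self.model.equalise,
            "params": dict(self.params),
            "D": self.D,
            "k1": self.k1,
            "k2": self.k2,
            "ssd": self.ssd,
            "r2": self.r_squared(),
            "k_params": self.k_params,
            "nobs": self.nobs,
            "n_starts_converged": self.n_starts_converged,
        }


def fit_model(
    data,
    reference: ReferenceCurves,
    kinetics: str = "diffusion",
    starts: int = 5,
    **kwargs,
) -> FRAPFitResult:
    """Functional shorthand for ``FRAPModel(...).fit(...)``."""
    return FRAPModel(data, reference, kinetics=kinetics, **kwargs).fit(starts=starts)
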