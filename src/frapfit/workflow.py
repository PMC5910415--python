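"""End-to-end analysis glue: image series → reference simulation → fit.

The canonical pipeline is

1. (optional) preprocessing: background subtraction, flattening or
   pre-bleach normalisation, denoising;
2. ROI definition (:func:`frapfit.rois.make_standard_rois`) and
   recovery-curve extraction;
3. rim-concentration estimate from the first post-bleach frame;
4. mesh the experiment geometry, interpolate the first frame as initial
   condition, simulate diffusion once at D_ref;
5. build a :class:`~frapfit.fitting.FRAPModel` from the measured curves
   and the reference ROI curves, and fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .fem import (
    SimulationConfig,
    SimulationResult,
    interpolate_initial_condition,
    simulate_diffusion,
)
from .fitting import FRAPFitResult, FRAPModel, ReferenceCurves
from .geometry import Geometry
from .meshing import Mesh, MeshRefinement, generate_mesh
from .rois import (
    ROI,
    ImageStack,
    RecoveryCurveSet,
    estimate_rim_concentration,
    extract_curves,
)

__all__ = ["build_reference", "analyze_stack", "default_element_size"]


def default_element_size(dim: int) -> float:
    """Target element volume: fine triangles in 2D, the standard 25 px³
    tetrahedra in 3D unless overridden."""
    return 4.0 if dim == 2 else 25.0


def _slab_extent(mesh: Mesh) -> tuple[float, float]:
    """Depth window around the imaging plane for ROI integration of 3D
    simulations: a slab ~1.25 mean element edges thick either side."""
    h = float(np.mean(mesh.element_volumes) ** (1.0 / 3.0))
    return (-1.25 * h, 1.25 * h)


def build_reference(
    first_frame: np.ndarray,
    geometry: Geometry,
    rois: Mapping[str, ROI],
    sim_config: SimulationConfig | None = None,
    v: float | None = None,
    refinement: MeshRefinement | None = None,
    c_rim: float | None = None,
    omega1: ROI | None = None,
    mesh: Mesh | None = None,
    return_simulation: bool = False,
):
    """Run the reference diffusion simulation for one data set.

    ``rois`` must contain ``slice`` and ``bleached`` (and usually ``rim``).
    Ω₁ — the region whose pixels are trusted for the initial condition —
    defaults to the slice ROI; nodes outside it start at the rim
    concentration ``c_rim`` (estimated from the rim ROI if not given).
    """
    frame = np.asarray(first_frame, dtype=float)
    if sim_config is None:
        sim_config = SimulationConfig()
    if c_rim is None:
        if "rim" not in rois:
            raise ValueError("either pass c_rim or provide a 'rim' ROI")
        c_rim = estimate_rim_concentration(frame, rois["rim"])
    if omega1 is None:
        omega1 = rois["slice"]
    if mesh is None:
        mesh = generate_mesh(geometry, v=v if v is not None else default_element_size(geometry.dim), refinement=refinement)
    fit_rois = {"bleached": rois["bleached"], "slice": rois["slice"]}
    if mesh.dim == 3:
        z_lo, z_hi = _slab_extent(mesh)
        fit_rois = {name: roi.with_z_extent(z_lo, z_hi) for name, roi in fit_rois.items()}
    ic = interpolate_initial_condition(frame, mesh, c_rim, omega1)
    sim = simulate_diffusion(mesh, ic, sim_config)
    reference = ReferenceCurves.from_simulation(sim, fit_rois)
    if return_simulation:
        return reference, sim
    return reference


@dataclass
class AnalysisResult:
    curves: RecoveryCurveSet
    reference: ReferenceCurves
    fit: FRAPFitResult


def analyze_stack(
    stack: ImageStack,
    rois: Mapping[str, ROI],
    geometry: Geometry,
    kinetics: str = "diffusion",
    equalise: bool = False,
    starts: int = 5,
    sim_config: SimulationConfig | None = None,
    v: float | None = None,
    refinement: MeshRefinement | None = None,
    **fit_kwargs,
) -> AnalysisResult:
    """Full pipeline for a preprocessed image stack."""
    curves = extract_curves(stack, [rois["bleached"], rois["slice"]])
    reference = build_reference(
        stack.frames[0], geometry, rois, sim_config=sim_config, v=v, refinement=refinement
    )
    model = FRAPModel(curves, reference, kinetics=kinetics, equalise=equalise, **fit_kwargs)
    return AnalysisResult(curves=curves, reference=reference, fit=model.fit(starts=starts))
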