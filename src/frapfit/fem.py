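"""Finite-element diffusion simulation.

Solves ∂c/∂t = D ∇²c with zero-flux (Neumann) boundaries on a simplex
mesh, starting from a bilinear interpolation of the first post-bleach
image. Linear (P1) elements with a lumped mass matrix and implicit stepping on
a logarithmic time grid: steps are densest right after bleaching where
recovery is steepest, and the geometric grid makes curves at different
diffusivities interchangeable through the self-similarity rescaling used
by the fitting stage. The default integrator is Crank–Nicolson with a
short backward-Euler start-up (Rannacher smoothing), which damps
under-resolved initial modes while keeping second-order accuracy over
the transient; pure backward Euler is available via ``theta=1``.

Both schemes conserve total mass exactly (up to linear-solver residual)
because the stiffness matrix annihilates constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import splu

from .meshing import Mesh
from .rois import ROI

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "logarithmic_timesteps",
    "interpolate_initial_condition",
    "assemble_fem_matrices",
    "simulate_diffusion",
    "integrate_over_roi",
    "roi_mean_curve",
]

#: reference diffusivity used for the single stored simulation (px²/s)
D_REF_DEFAULT = 50.0
#: simulation horizon for 1 s frame-interval acquisitions (s)
T_END_DEFAULT = 1680.0


@dataclass
class SimulationConfig:
    D_ref: float = D_REF_DEFAULT
    t_end: float = T_END_DEFAULT
    n_steps: int = 80
    stepping: str = "logarithmic"
    t_first: float = 0.1  # Δt/10 for the default 1 s frame interval
    #: implicitness of the θ-scheme: 0.5 = Crank–Nicolson, 1 = backward Euler
    theta: float = 0.5
    #: initial fully implicit steps smoothing rough initial data
    rannacher_steps: int = 2

    def __post_init__(self):
        if self.D_ref <= 0 or self.t_end <= 0:
            raise ValueError("D_ref and t_end must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")
        if self.stepping not in ("logarithmic", "linear"):
            raise ValueError("stepping must be 'logarithmic' or 'linear'")


@dataclass
class SimulationResult:
    times: np.ndarray  # (n_t,)
    nodal_values: np.ndarray  # (n_t, n_nodes)
    mesh: Mesh
    D_ref: float

    def sample_nodal(self, t: float) -> np.ndarray:
        """Nodal concentrations at time t (linear interpolation in time)."""
        t = float(t)
        if t < self.times[0] - 1e-12 or t > self.times[-1] + 1e-12:
            raise ValueError(f"time {t} outside simulated range")
        i = np.searchsorted(self.times, t)
        if i == 0:
            return self.nodal_values[0]
        if i >= len(self.times):
            return self.nodal_values[-1]
        t0, t1 = self.times[i - 1], self.times[i]
        w = (t - t0) / (t1 - t0)
        return (1 - w) * self.nodal_values[i - 1] + w * self.nodal_values[i]

    def curves_frame(self, rois) -> pd.DataFrame:
        rows = []
        for roi in rois:
            vals = integrate_over_roi(self, roi, normalise=True)
            for t, v in zip(self.times, vals):
                rows.append({"roi": roi.name, "time_s": t, "mean_concentration": v})
        return pd.DataFrame(rows)

    def to_csv(self, path, rois) -> None:
        self.curves_frame(rois).to_csv(path, index=False)


def logarithmic_timesteps(t_end: float, n_steps: int, t_first: float) -> np.ndarray:
    """Time grid {0, t_first, t_first·r, …, t_end} with constant step
    ratio r; n_steps is the total number of grid points."""
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    if n_steps == 2:
        if t_end <= 0:
            raise ValueError("t_end must be positive")
        return np.array([0.0, float(t_end)])
    if not 0 < t_first < t_end:
        raise ValueError("need 0 < t_first < t_end")
    grid = np.geomspace(t_first, t_end, n_steps - 1)
    return np.concatenate([[0.0], grid])


def interpolate_initial_condition(
    first_frame: np.ndarray,
    mesh: Mesh,
    c_rim: float,
    omega1: ROI | None,
) -> np.ndarray:
    """Initial nodal concentrations from the first post-bleach frame.

    Nodes whose (x, y) falls inside the visible ROI Ω₁ (for every z — the
    bleach profile is taken as depth-invariant) get the bilinear
    interpolation of the four surrounding pixel intensities; all other
    nodes get the rim concentration. Pixel (row i, col j) sits at
    (x=j, y=i); interpolation never extrapolates beyond the frame.
    """
    frame = np.asarray(first_frame, dtype=float)
    n_y, n_x = frame.shape
    interp = RegularGridInterpolator(
        (np.arange(n_y), np.arange(n_x)), frame, method="linear", bounds_error=False, fill_value=None
    )
    xy = mesh.nodes[:, :2]
    x, y = xy[:, 0], xy[:, 1]
    if omega1 is not None:
        inside = omega1.contains(x, y)
    else:
        inside = np.ones(len(xy), dtype=bool)
    # a node outside the frame cannot be interpolated, rim value applies
    inside &= (x >= 0) & (x <= n_x - 1) & (y >= 0) & (y <= n_y - 1)
    ic = np.full(len(xy), float(c_rim))
    if inside.any():
        ic[inside] = interp(np.column_stack([y[inside], x[inside]]))
    return ic


def _element_gradients(nodes, elements):
    """Constant P1 shape-function gradients and volumes per element."""
    dim = nodes.shape[1]
    p0 = nodes[elements[:, 0]]
    edges = nodes[elements[:, 1:]] - p0[:, None, :]  # (m, dim, dim)
    det = np.linalg.det(edges)
    vols = np.abs(det) / (2.0 if dim == 2 else 6.0)
    inv = np.linalg.inv(edges)  # rows: gradients of barycentric coords 1..dim
    grads = np.empty((len(elements), dim + 1, dim))
    grads[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    return grads, vols


def assemble_fem_matrices(mesh: Mesh):
    """P1 stiffness matrix K and lumped mass vector m (diagonal of M)."""
    nodes, elements = mesh.nodes, mesh.elements
    grads, vols = _element_gradients(nodes, elements)
    n_loc = elements.shape[1]
    # K_ij^e = vol * grad_i . grad_j
    ke = np.einsum("eid,ejd,e->eij", grads, grads, vols)
    rows = np.repeat(elements, n_loc, axis=1).ravel()
    cols = np.tile(elements, (1, n_loc)).ravel()
    K = sparse.coo_matrix((ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)).tocsc()
    m_lumped = np.zeros(mesh.n_nodes)
    np.add.at(m_lumped, elements.ravel(), np.repeat(vols / n_loc, n_loc))
    return K, m_lumped


def simulate_diffusion(mesh: Mesh, ic: np.ndarray, config: SimulationConfig) -> SimulationResult:
    """Backward-Euler integration of the diffusion equation at the
    reference diffusivity, no-flux on every boundary (outer walls and
    obstacle surfaces alike)."""
    ic = np.asarray(ic, dtype=float)
    if ic.shape != (mesh.n_nodes,):
        raise ValueError("initial condition must be defined at every node")
    if not np.all(np.isfinite(ic)):
        raise ValueError("non-finite values in the initial condition")
    if config.stepping == "logarithmic":
        times = logarithmic_timesteps(config.t_end, config.n_steps, config.t_first)
    else:
        times = np.linspace(0.0, config.t_end, config.n_steps)
    K, m = assemble_fem_matrices(mesh)
    M = sparse.diags(m).tocsc()
    values = np.empty((len(times), mesh.n_nodes))
    values[0] = ic
    c = ic.copy()
    for step in range(1, len(times)):
        dt = times[step] - times[step - 1]
        theta = 1.0 if step <= config.rannacher_steps else config.theta
        A = (M + theta * dt * config.D_ref * K).tocsc()
        rhs = m * c - (1.0 - theta) * dt * config.D_ref * (K @ c)
        c = splu(A).solve(rhs)
        if not np.all(np.isfinite(c)):
            raise RuntimeError(f"non-finite solution at step {step} (t={times[step]:.4g})")
        resid = np.linalg.norm(A @ c - rhs) / max(np.linalg.norm(rhs), 1e-300)
        if resid > 1e-8:
            raise RuntimeError(f"linear solve failed at step {step}: relative residual {resid:.2e}")
        values[step] = c
    return SimulationResult(times=times, nodal_values=values, mesh=mesh, D_ref=config.D_ref)


def _roi_element_mask(mesh: Mesh, roi: ROI) -> np.ndarray:
    cent = mesh.centroids
    mask = roi.contains(cent[:, 0], cent[:, 1])
    if mesh.dim == 3 and roi.z_extent is not None:
        z_lo, z_hi = roi.z_extent
        mask &= (cent[:, 2] >= z_lo) & (cent[:, 2] <= z_hi)
    return mask


def integrate_over_roi(
    result: SimulationResult,
    roi: ROI,
    t: float | None = None,
    normalise: bool = False,
) -> np.ndarray | float:
    """Volume integral of the solution over a ROI (element-centroid
    membership, element volume × mean nodal value). ``normalise=True``
    divides by the ROI volume, giving the mean concentration comparable to
    a mean pixel intensity. Scalar for a single time, array over the
    simulation grid otherwise."""
    mesh = result.mesh
    mask = _roi_element_mask(mesh, roi)
    if not mask.any():
        raise ValueError(f"ROI {roi.name!r} intersects no mesh elements")
    elems = mesh.elements[mask]
    vols = mesh.element_volumes[mask]
    denom = vols.sum() if normalise else 1.0

    def integral(nodal):
        return float((vols * nodal[elems].mean(axis=1)).sum() / denom)

    if t is not None:
        return integral(result.sample_nodal(t))
    return np.array([integral(v) for v in result.nodal_values])


def roi_mean_curve(result: SimulationResult, roi: ROI) -> np.ndarray:
    """Mean concentration over the ROI for every simulation time."""
    return integrate_over_roi(result, roi, normalise=True)
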