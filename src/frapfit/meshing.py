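"""Simplex meshing of experiment geometries.

The mesher triangulates a graded point cloud with scipy's Delaunay
(Qhull) and keeps the simplices whose centroids lie inside the domain and
outside every obstacle. Points come from three sources: a coarse interior
lattice (hexagonal in 2D, cubic in 3D), an optional fine lattice inside
refinement regions (the imaging slice and a boundary-layer band around the
bleached-region boundary, where recovery gradients are steepest), and
explicit samples of every boundary curve/surface so the polygonal boundary
tracks the analytic one. Interior points that crowd a boundary sample are
dropped to avoid slivers.

Element "size" v follows the convention of the simulation defaults
(v = 25, v_BL = v_slice = 15, w_BL = 30, all in pixel units): it is the
target element volume (3D) or area (2D), converted internally to a lattice
spacing for a regular simplex of that volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .geometry import Geometry
from .rois import ROI

__all__ = ["Mesh", "MeshRefinement", "generate_mesh", "spacing_for_element_size"]

#: default global element size (pixels^dim), as used throughout the study
V_DEFAULT = 25.0
#: default boundary-layer thickness around the bleached region (pixels)
W_BL_DEFAULT = 30.0
#: default refined element size (pixels^dim)
V_FINE_DEFAULT = 15.0


@dataclass
class MeshRefinement:
    """Local refinement request: finer elements inside the slice ROI and in
    a band of width ``w_bl`` around the bleached-region boundary."""

    v_bl: float = V_FINE_DEFAULT
    w_bl: float = W_BL_DEFAULT
    v_slice: float = V_FINE_DEFAULT
    slice_roi: ROI | None = None
    bleach_roi: ROI | None = None


@dataclass
class Mesh:
    nodes: np.ndarray  # (n_nodes, dim)
    elements: np.ndarray  # (n_elem, dim+1) node indices
    element_volumes: np.ndarray
    dim: int
    geometry: Geometry | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def total_volume(self) -> float:
        return float(self.element_volumes.sum())

    def to_text(self, path) -> None:
        """Plain-text export: node coordinates then element connectivity."""
        with open(path, "w") as fh:
            fh.write(f"# frapfit mesh dim={self.dim} nodes={self.n_nodes} elements={self.n_elements}\n")
            fh.write("nodes\n")
            np.savetxt(fh, self.nodes, fmt="%.8g")
            fh.write("elements\n")
            np.savetxt(fh, self.elements, fmt="%d")

    @classmethod
    def from_text(cls, path) -> "Mesh":
        with open(path) as fh:
            header = fh.readline()
            dim = int(header.split("dim=")[1].split()[0])
            assert fh.readline().strip() == "nodes"
            lines = fh.read().split("elements\n")
        nodes = np.loadtxt(lines[0].strip().splitlines())
        elements = np.loadtxt(lines[1].strip().splitlines(), dtype=int)
        vols = simplex_volumes(nodes, np.atleast_2d(elements))
        return cls(nodes, np.atleast_2d(elements), vols, dim)


def spacing_for_element_size(v: float, dim: int) -> float:
    """Lattice spacing whose regular simplex has volume ≈ v."""
    if v <= 0:
        raise ValueError("element size must be positive")
    if dim == 2:
        return float(np.sqrt(4.0 * v / np.sqrt(3.0)))  # equilateral triangle
    return float((6.0 * np.sqrt(2.0) * v) ** (1.0 / 3.0))  # regular tetrahedron


def simplex_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    p0 = nodes[elements[:, 0]]
    edges = nodes[elements[:, 1:]] - p0[:, None, :]
    if nodes.shape[1] == 2:
        det = edges[:, 0, 0] * edges[:, 1, 1] - edges[:, 0, 1] * edges[:, 1, 0]
        return np.abs(det) / 2.0
    det = np.linalg.det(edges)
    return np.abs(det) / 6.0


def _hex_lattice_2d(spacing, lo, hi):
    dy = spacing * np.sqrt(3) / 2
    ys = np.arange(lo[1], hi[1] + dy, dy)
    pts = []
    for j, y in enumerate(ys):
        off = spacing / 2 if j % 2 else 0.0
        xs = np.arange(lo[0] + off, hi[0] + spacing, spacing)
        pts.append(np.column_stack([xs, np.full(len(xs), y)]))
    return np.vstack(pts)


def _lattice_3d(spacing, lo, hi):
    axes = [np.arange(lo[i], hi[i] + spacing, spacing) for i in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def _interior_lattice(geometry, spacing, lo, hi):
    if geometry.dim == 2:
        return _hex_lattice_2d(spacing, lo, hi)
    return _lattice_3d(spacing, lo, hi)


def _in_refined_region(points, refinement: MeshRefinement):
    mask = np.zeros(len(points), dtype=bool)
    if refinement.slice_roi is not None:
        mask |= refinement.slice_roi.contains(points[:, 0], points[:, 1])
    if refinement.bleach_roi is not None:
        w = refinement.w_bl
        inner = refinement.bleach_roi
        # band of width w around the bleach boundary: inside a grown copy
        # but outside a shrunk copy, approximated by radius/side offsets
        mask |= _near_roi_boundary(points, inner, w)
    return mask


def _near_roi_boundary(points, roi, w):
    from .rois import CircleROI, SquareROI

    x, y = points[:, 0], points[:, 1]
    if isinstance(roi, CircleROI):
        d = np.sqrt((x - roi.center[0]) ** 2 + (y - roi.center[1]) ** 2)
        return np.abs(d - roi.radius) < w
    if isinstance(roi, SquareROI):
        x0, y0 = roi.corner
        s = roi.side
        dx = np.maximum.reduce([x0 - x, x - (x0 + s), np.zeros_like(x)])
        dy = np.maximum.reduce([y0 - y, y - (y0 + s), np.zeros_like(y)])
        d_out = np.hypot(dx, dy)
        inside = (dx == 0) & (dy == 0)
        d_in = np.minimum(np.minimum(x - x0, x0 + s - x), np.minimum(y - y0, y0 + s - y))
        d = np.where(inside, d_in, -d_out)
        return np.abs(d) < w
    # generic fall-back: membership change within a probe of length w
    return np.zeros(len(points), dtype=bool)


def _obstacle_boundary_points(geometry, spacing):
    pts = []
    for ob in geometry.obstacles:
        if geometry.dim == 2:
            n = max(8, int(np.ceil(2 * np.pi * ob.radius / spacing)))
            theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
            p = np.column_stack(
                [ob.center[0] + ob.radius * np.cos(theta), ob.center[1] + ob.radius * np.sin(theta)]
            )
        else:
            n = max(16, int(np.ceil(4 * np.pi * ob.radius**2 / spacing**2)))
            # Fibonacci sphere
            i = np.arange(n) + 0.5
            phi = np.arccos(1 - 2 * i / n)
            golden = np.pi * (1 + np.sqrt(5))
            theta = golden * i
            p = ob.center + ob.radius * np.column_stack(
                [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
            )
        # keep only the part of the obstacle surface inside the domain
        keep = geometry.contains(p, margin=0.25 * spacing)
        pts.append(p[keep])
    return np.vstack(pts) if pts else np.empty((0, geometry.dim))


def _contact_zone_points(geometry, h_fine):
    """Extra points in the thin necks between nearly touching obstacles.

    Where the surface-to-surface gap is below ~2 lattice spacings the
    regular interior lattice leaves the neck empty and Delaunay would
    bridge it with oversized (effectively blocking) elements. A small
    cluster of mid-gap points per contact keeps the channel conductive:
    points on the mid-plane disc (3D) or mid-gap segment (2D) out to the
    neck half-width √(r·δ) where the channel roughly doubles.
    """
    obs = geometry.obstacles
    if len(obs) < 2:
        return np.empty((0, geometry.dim))
    centers = np.array([o.center for o in obs])
    radii = np.array([o.radius for o in obs])
    tree = cKDTree(centers)
    pairs = tree.query_pairs(float(2 * radii.max() + 3 * h_fine), output_type="ndarray")
    pts = []
    for i, j in pairs:
        d = centers[j] - centers[i]
        dist = np.linalg.norm(d)
        gap = dist - radii[i] - radii[j]
        if gap <= 0 or gap > 2.0 * h_fine:
            continue
        axis = d / dist
        mid = centers[i] + axis * (radii[i] + gap / 2.0)
        r_eff = 2.0 / (1.0 / radii[i] + 1.0 / radii[j])
        w = np.sqrt(r_eff * gap)  # neck half-width
        if geometry.dim == 2:
            tang = np.array([-axis[1], axis[0]])
            offs = np.concatenate([[0.0], np.linspace(0.4, 2.0, 5), -np.linspace(0.4, 2.0, 5)]) * w
            pts.append(mid[None] + offs[:, None] * tang[None])
        else:
            # orthonormal basis of the contact plane
            a = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
            u = np.cross(axis, a)
            u /= np.linalg.norm(u)
            v = np.cross(axis, u)
            ring_pts = [mid[None]]
            for rho in (0.5 * w, 1.0 * w, 1.6 * w):
                n = max(6, int(np.ceil(2 * np.pi * rho / max(0.6 * w, 1e-9))))
                th = np.linspace(0, 2 * np.pi, n, endpoint=False)
                ring_pts.append(mid + rho * (np.outer(np.cos(th), u) + np.outer(np.sin(th), v)))
            pts.append(np.vstack(ring_pts))
    if not pts:
        return np.empty((0, geometry.dim))
    out = np.vstack(pts)
    # keep only points in the free space of the domain
    keep = geometry.contains(out) & ~geometry.in_obstacle(out)
    return out[keep]


def generate_mesh(
    geometry: Geometry,
    v: float = V_DEFAULT,
    refinement: MeshRefinement | None = None,
    seed: int = 0,
) -> Mesh:
    """Mesh a geometry into triangles (2D) or tetrahedra (3D).

    ``v`` is the target element volume/area; refinement (optional) applies
    the finer ``v_bl``/``v_slice`` sizes in the boundary-layer band and the
    slice region. Obstacle interiors contain no elements.
    """
    dim = geometry.dim
    h = spacing_for_element_size(v, dim)
    lo, hi = geometry.bounding_box()
    lo = np.asarray(lo, dtype=float) - 0.25 * h
    hi = np.asarray(hi, dtype=float) + 0.25 * h

    coarse = _interior_lattice(geometry, h, lo, hi)
    points = [coarse]
    h_fine = h
    if refinement is not None:
        h_fine = spacing_for_element_size(min(refinement.v_bl, refinement.v_slice), dim)
        fine = _interior_lattice(geometry, h_fine, lo, hi)
        fine_mask = _in_refined_region(fine, refinement)
        fine = fine[fine_mask]
        coarse_mask = _in_refined_region(coarse, refinement)
        points = [coarse[~coarse_mask], fine]

    interior = np.vstack(points)
    interior = interior[geometry.contains(interior, margin=0.0)]

    h_bnd = h_fine if geometry.obstacles else h
    boundary = [geometry.boundary_points(h_bnd)]
    if geometry.obstacles:
        boundary.append(_obstacle_boundary_points(geometry, h_fine))
        boundary.append(_contact_zone_points(geometry, h_fine))
    boundary = np.vstack(boundary)

    # drop interior points crowding the boundary samples, and obstacle
    # interiors altogether
    if len(boundary):
        tree = cKDTree(boundary)
        d, _ = tree.query(interior, k=1)
        local_h = np.full(len(interior), h)
        if refinement is not None:
            local_h[_in_refined_region(interior, refinement)] = h_fine
        if geometry.obstacles:
            local_h[:] = np.minimum(local_h, h_fine)
        interior = interior[d > 0.55 * local_h]
    if geometry.obstacles and len(interior):
        interior = interior[~geometry.in_obstacle(interior)]

    # dedupe boundary points (ring/surface seams can coincide)
    if len(boundary):
        tree = cKDTree(boundary)
        pairs = tree.query_pairs(1e-6, output_type="ndarray")
        if len(pairs):
            drop = np.zeros(len(boundary), dtype=bool)
            drop[pairs[:, 1]] = True
            boundary = boundary[~drop]

    all_points = np.vstack([interior, boundary]) if len(boundary) else interior
    if len(all_points) < dim + 1:
        raise RuntimeError(
            f"meshing failed: only {len(all_points)} points generated for "
            f"{geometry.kind} geometry (element size {v})"
        )
    # deterministic micro-jitter guards Qhull against exactly degenerate
    # (cocircular/cospherical) lattice configurations
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-1e-4, 1e-4, size=all_points.shape) * h
    jitter[len(interior):] = 0.0  # keep boundary samples exact
    tri = Delaunay(all_points + jitter, qhull_options="Qbb Qc Qz Q12")

    cells = tri.simplices
    centroids = tri.points[cells].mean(axis=1)
    keep = geometry.contains(centroids)
    if geometry.obstacles:
        keep &= ~geometry.in_obstacle(centroids)
    cells = cells[keep]
    vols = simplex_volumes(tri.points, cells)
    good = vols > 1e-12 * h**dim
    cells, vols = cells[good], vols[good]
    if len(cells) == 0:
        raise RuntimeError(f"meshing failed: no admissible elements for {geometry.kind} geometry")

    # drop orphan nodes
    used = np.unique(cells)
    remap = -np.ones(len(tri.points), dtype=int)
    remap[used] = np.arange(len(used))
    return Mesh(
        nodes=tri.points[used],
        elements=remap[cells],
        element_volumes=vols,
        dim=dim,
        geometry=geometry,
    )
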