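"""Mechanical perturbations: ablation, laceration, plate compression.

Ablation/laceration removes turgor from the cut cells and softens their
walls; the surrounding stress field is then re-solved and scored with a
circumferential-alignment metric (1 = maximal stress perfectly tangent
to the wound, 0 = perfectly radial).  Compression presses a rigid
frictionless plane onto a pressurized cap while the enclosed volume is
held constant by adjusting the internal pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .fem import Displacements, FemSystem, Model, solve_equilibrium
from .meshing import SurfaceMesh
from .stress import StressField, principal_stress


@dataclass
class AblationSpec:
    """Cells to kill and how much their walls soften."""

    ablated_cells: frozenset | set | list | tuple
    stiffness_factor: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.stiffness_factor <= 1.0:
            raise ValueError("stiffness_factor must be in (0, 1]")
        self.ablated_cells = frozenset(self.ablated_cells)


def ablate(model: Model, spec: AblationSpec) -> Model:
    """Remove turgor from the ablated cells and soften their walls.

    Element and beam moduli of the ablated cells are multiplied by
    ``stiffness_factor``; wound-margin beams shared with a surviving
    cell keep the survivor's wall stiffness.  Everything else is
    untouched; an empty spec is the identity.
    """
    cells = set(spec.ablated_cells)
    if not cells:
        return model.copy()
    labels = set(np.unique(model.mesh.cell_label))
    missing = cells - labels
    if missing:
        raise ValueError(f"unknown cell labels: {sorted(missing)}")
    if cells >= labels:
        raise ValueError("cannot ablate every cell: no load would remain")

    out = model.copy()
    dead = np.isin(out.mesh.cell_label, list(cells))
    out.mesh.stiffness_scale = out.mesh.stiffness_scale * np.where(
        dead, spec.stiffness_factor, 1.0
    )
    out.loads.pressure = out.loads.pressure * np.where(dead, 0.0, 1.0)
    if len(out.mesh.beams) and out.mesh.boundary_edge_cells:
        soften = np.array(
            [
                len(cs) > 0 and all(c in cells for c in cs)
                for cs in out.mesh.boundary_edge_cells
            ]
        )
        out.mesh.beam_scale = out.mesh.beam_scale * np.where(
            soften, spec.stiffness_factor, 1.0
        )
    return out


def wound_boundary(
    mesh: SurfaceMesh, cells: set | frozenset, smooth_radius: float = 0.0
) -> Polygon:
    """Footprint polygon of the ablated region (union of its elements).

    ``smooth_radius`` applies a morphological closing (buffer out/in)
    so the scoring tangent follows the overall wound outline rather
    than each lobe of the dead cells' jigsaw margins.
    """
    tris = mesh.triangles[np.isin(mesh.cell_label, list(cells))]
    polys = [Polygon(mesh.vertices[t][:, :2]) for t in tris]
    merged = unary_union(polys)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    out = Polygon(merged.exterior)
    if smooth_radius > 0:
        smoothed = out.buffer(smooth_radius).buffer(-smooth_radius)
        if smoothed.geom_type == "MultiPolygon":
            smoothed = max(smoothed.geoms, key=lambda g: g.area)
        out = Polygon(smoothed.exterior).simplify(0.25 * smooth_radius)
    return out


def circumferential_alignment(
    stress: StressField,
    mesh: SurfaceMesh,
    wound: Polygon,
    annulus_width: float,
    include_interior: bool = False,
) -> float:
    """Area-weighted mean cos^2 of (sigma1 direction, wound tangent).

    Scored over elements whose centroid lies within ``annulus_width``
    outside the wound boundary; degenerate elements are excluded.
    Returns 1 for a perfectly circumferential field, 0 for radial, and
    0.5 in expectation for uniformly random in-plane directions.
    """
    import shapely

    boundary = wound.exterior
    cent = mesh.element_centroids()
    areas = mesh.element_areas()
    d1 = stress.dir1

    pts = shapely.points(cent[:, 0], cent[:, 1])
    inside = shapely.contains(wound, pts)
    dist = shapely.distance(boundary, pts)
    sel = ~stress.degenerate & (dist <= annulus_width)
    if not include_interior:
        sel &= ~inside
    if not sel.any():
        raise ValueError("no elements in the scoring annulus")

    # local wound tangent: perpendicular to the nearest-point direction
    arc = shapely.line_locate_point(boundary, pts[sel])
    q = shapely.get_coordinates(shapely.line_interpolate_point(boundary, arc))
    radial = cent[sel, :2] - q
    nr = np.hypot(radial[:, 0], radial[:, 1])
    ok = nr > 1e-9
    tang = np.column_stack([-radial[:, 1], radial[:, 0]]) / np.where(
        ok, nr, 1.0
    )[:, None]
    v = d1[sel, :2]
    nv = np.hypot(v[:, 0], v[:, 1])
    ok &= nv > 1e-9
    if not ok.any():
        raise ValueError("no scoreable elements in the annulus")
    cos2 = (np.einsum("ij,ij->i", v, tang) / np.where(ok, nv, 1.0)) ** 2
    return float(np.average(cos2[ok], weights=areas[sel][ok]))


@dataclass
class CompressionSpec:
    """Rigid-plate compression at constant enclosed volume."""

    plate_gap: float  # micrometre: plate height above the base plane
    friction: float = 0.0
    volume_constraint: bool = True
    volume_tol: float = 0.005  # relative
    contact_penalty: float | None = None

    def __post_init__(self) -> None:
        if self.plate_gap <= 0:
            raise ValueError("plate_gap must be positive")
        if self.friction != 0.0:
            raise ValueError("only frictionless contact is supported")


@dataclass
class CompressionResult:
    displacements: Displacements
    stress: StressField
    pressure: float  # MPa at equilibrium
    volume: float
    volume_initial: float
    contact_free: np.ndarray  # (m,) bool


def compress(model: Model, spec: CompressionSpec) -> CompressionResult:
    """Press a frictionless rigid plane down to ``plate_gap``.

    The model must be a pressurized surface enclosing a volume against
    the z = 0 base plane (a dome or cell cap).  The internal pressure is
    adjusted between Newton solves so the enclosed volume stays within
    ``volume_tol`` of its unconfined value; contact is a penalty on
    vertex penetration with zero tangential force.
    """
    mesh, mat, loads = model.mesh, model.material, model.loads
    fem = FemSystem(mesh, mat)
    disp0 = solve_equilibrium(mesh, mat, loads, system=fem)
    x0 = mesh.vertices + disp0.u
    V0 = fem.enclosed_volume(x0)
    if V0 <= 0:
        raise ValueError("model does not enclose a positive volume")
    apex = float(x0[:, 2].max())
    base_p = float(loads.pressure.max())
    if base_p <= 0:
        raise ValueError("compression requires a pressurized model")

    kc = spec.contact_penalty
    if kc is None:
        kc = 200.0 * mat.E_matrix * float(np.mean(mesh.thickness))

    if spec.plate_gap >= apex:
        # plate never touches: identical to the unconfined solve
        st = principal_stress(disp0, mesh, mat, system=fem)
        free = np.ones(mesh.n_elements, bool)
        return CompressionResult(disp0, st, base_p, V0, V0, free)

    def solve_at(p_scale: float, x_start: np.ndarray) -> tuple[Displacements, float]:
        lc = loads.copy()
        lc.pressure = loads.pressure * p_scale
        d = solve_equilibrium(
            mesh,
            mat,
            lc,
            system=fem,
            n_increments=2,
            contact_plane=(spec.plate_gap, kc),
            x0=x_start,
        )
        return d, fem.enclosed_volume(mesh.vertices + d.u)

    p_scale = 1.0
    disp, V = solve_at(p_scale, x0)
    if spec.volume_constraint:
        # secant iteration on log-pressure to restore the enclosed volume
        hist = [(p_scale, V)]
        for _ in range(25):
            if abs(V - V0) / V0 < spec.volume_tol:
                break
            if len(hist) >= 2 and abs(hist[-1][1] - hist[-2][1]) > 1e-12:
                (p1, v1), (p2, v2) = hist[-2], hist[-1]
                p_new = p2 + (V0 - v2) * (p2 - p1) / (v2 - v1)
                if not np.isfinite(p_new) or p_new <= 0:
                    p_new = p_scale * (V0 / V)
            else:
                p_new = p_scale * (V0 / V) ** 1.5
            p_scale = float(np.clip(p_new, 0.2 * p_scale, 5.0 * p_scale))
            disp, V = solve_at(p_scale, mesh.vertices + disp.u)
            hist.append((p_scale, V))
        else:
            raise RuntimeError("volume constraint not satisfied after 25 updates")

    st = principal_stress(disp, mesh, mat, system=fem)
    x = mesh.vertices + disp.u
    zmax_el = x[mesh.triangles][:, :, 2].max(axis=1)
    contact_free = zmax_el < spec.plate_gap - 1e-6 * max(apex, 1.0)
    return CompressionResult(
        displacements=disp,
        stress=st,
        pressure=base_p * p_scale,
        volume=V,
        volume_initial=V0,
        contact_free=contact_free,
    )
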