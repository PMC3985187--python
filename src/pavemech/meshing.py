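"""Surface meshing of cell complexes and reference shapes.

The mesher produces conforming triangle meshes in which every
cell-boundary polyline appears exactly as a chain of element edges, so
anticlinal beam elements and z-restrictions can be attached to it.
Triangulation is boundary-resampling + interior hexagonal seeding +
Delaunay with containment filtering, followed by a few Laplacian
smoothing passes of the interior points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from .cellcomplex import CellComplex
from .materials import MaterialParams


@dataclass
class SurfaceMesh:
    """Triangulated shell surface with per-element attributes.

    vertices are 3D micrometre coordinates; per-element arrays carry the
    owning cell label, wall thickness and (optionally) the unit fiber
    direction in the element tangent plane.  Beam elements (anticlinal
    walls) live on cell-boundary edges.
    """

    vertices: np.ndarray  # (n, 3)
    triangles: np.ndarray  # (m, 3)
    cell_label: np.ndarray  # (m,)
    thickness: np.ndarray  # (m,)
    fiber_dir: np.ndarray | None = None  # (m, 3) unit tangent
    beams: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    beam_modulus: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beam_thickness: np.ndarray = field(default_factory=lambda: np.zeros(0))
    boundary_edges: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    boundary_edge_cells: list = field(default_factory=list)  # incident cell labels per edge
    is_outer_vertex: np.ndarray | None = None  # (n,) bool
    is_wall_vertex: np.ndarray | None = None  # (n,) bool
    stiffness_scale: np.ndarray | None = None  # (m,) ablation softening
    beam_scale: np.ndarray | None = None  # (k,)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.triangles = np.asarray(self.triangles, int)
        if self.is_outer_vertex is None:
            self.is_outer_vertex = np.zeros(len(self.vertices), bool)
        if self.is_wall_vertex is None:
            self.is_wall_vertex = np.zeros(len(self.vertices), bool)
        if self.stiffness_scale is None:
            self.stiffness_scale = np.ones(len(self.triangles))
        if self.beam_scale is None:
            self.beam_scale = np.ones(len(self.beams))

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def element_areas(self, vertices: np.ndarray | None = None) -> np.ndarray:
        v = self.vertices if vertices is None else vertices
        p = v[self.triangles]
        cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def element_centroids(self, vertices: np.ndarray | None = None) -> np.ndarray:
        v = self.vertices if vertices is None else vertices
        return v[self.triangles].mean(axis=1)

    def edge_lengths(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        e = np.concatenate(
            [p[:, 1] - p[:, 0], p[:, 2] - p[:, 1], p[:, 0] - p[:, 2]]
        )
        return np.linalg.norm(e, axis=1)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            vertices=self.vertices.copy(),
            triangles=self.triangles.copy(),
            cell_label=self.cell_label.copy(),
            thickness=self.thickness.copy(),
            fiber_dir=None if self.fiber_dir is None else self.fiber_dir.copy(),
            beams=self.beams.copy(),
            beam_modulus=self.beam_modulus.copy(),
            beam_thickness=self.beam_thickness.copy(),
            boundary_edges=self.boundary_edges.copy(),
            boundary_edge_cells=list(self.boundary_edge_cells),
            is_outer_vertex=self.is_outer_vertex.copy(),
            is_wall_vertex=self.is_wall_vertex.copy(),
            stiffness_scale=self.stiffness_scale.copy(),
            beam_scale=self.beam_scale.copy(),
        )


def _subdivide_segment(p0: np.ndarray, p1: np.ndarray, h: float) -> np.ndarray:
    """Interior subdivision points of a segment at spacing <= h."""
    length = float(np.hypot(*(p1 - p0)))
    n = max(1, int(np.ceil(length / h)))
    t = np.linspace(0.0, 1.0, n + 1)[1:-1]
    return p0[None, :] + t[:, None] * (p1 - p0)[None, :]


def _hex_lattice(poly: Polygon, h: float, clearance: float) -> np.ndarray:
    """Hexagonal interior point lattice with a boundary clearance."""
    minx, miny, maxx, maxy = poly.bounds
    dy = h * np.sqrt(3.0) / 2.0
    ys = np.arange(miny + 0.5 * h, maxy, dy)
    pts = []
    for i, y in enumerate(ys):
        xoff = 0.25 * h if i % 2 else -0.25 * h
        xs = np.arange(minx + 0.5 * h + xoff, maxx, h)
        pts.append(np.column_stack([xs, np.full(len(xs), y)]))
    if not pts:
        return np.zeros((0, 2))
    cand = np.vstack(pts)
    shrunk = poly.buffer(-clearance)
    if shrunk.is_empty:
        return np.zeros((0, 2))
    keep = shapely.contains_xy(shrunk, cand[:, 0], cand[:, 1])
    return cand[keep]


def _delaunay_in_polygon(
    pts: np.ndarray, poly: Polygon, n_fixed: int, smooth_iters: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Delaunay-triangulate pts, keep triangles inside poly, smooth interior."""
    pts = pts.copy()
    for _ in range(smooth_iters + 1):
        tri = Delaunay(pts)
        simp = tri.simplices
        cent = pts[simp].mean(axis=1)
        keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        # drop degenerate slivers (near-collinear boundary samples)
        p3 = pts[simp]
        ar = 0.5 * np.abs(
            (p3[:, 1, 0] - p3[:, 0, 0]) * (p3[:, 2, 1] - p3[:, 0, 1])
            - (p3[:, 1, 1] - p3[:, 0, 1]) * (p3[:, 2, 0] - p3[:, 0, 0])
        )
        keep &= ar > 1e-8 * max(np.median(ar), 1e-30)
        simp = simp[keep]
        if smooth_iters == 0 or len(pts) == n_fixed:
            break
        # Laplacian smoothing of interior (movable) points
        nb: dict[int, set[int]] = {}
        for a, b, c in simp:
            for u, v in ((a, b), (b, c), (c, a)):
                nb.setdefault(u, set()).add(v)
                nb.setdefault(v, set()).add(u)
        moved = pts.copy()
        for i in range(n_fixed, len(pts)):
            if i in nb and nb[i]:
                moved[i] = pts[list(nb[i])].mean(axis=0)
        if np.allclose(moved, pts, atol=1e-12):
            break
        pts = moved
        smooth_iters -= 1
    # enforce CCW orientation
    p = pts[simp]
    cr = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = cr < 0
    simp[flip] = simp[flip][:, [0, 2, 1]]
    return pts, simp


def mesh_surface(
    complex_: CellComplex,
    target_h: float,
    thickness: float = 1.0,
    smooth_iters: int = 4,
) -> SurfaceMesh:
    """Triangulate a cell complex into a flat, conforming surface mesh.

    Every cell-boundary segment is resampled at spacing <= ``target_h``
    and appears as element edges; element cell labels come from
    containment.  The mesh starts flat (z = 0).
    """
    if target_h <= 0:
        raise ValueError("target_h must be positive")

    seg_lengths = [
        float(np.hypot(*(complex_.vertices[a] - complex_.vertices[b])))
        for (a, b) in complex_.segment_cells
    ]
    if seg_lengths and target_h > 3.0 * min(seg_lengths):
        warnings.warn(
            "target_h exceeds the smallest boundary feature; boundary "
            "segments are refined locally",
            stacklevel=2,
        )

    # global point table: complex vertices first, then subdivision points,
    # then per-cell interior points
    points: list[np.ndarray] = [complex_.vertices[i] for i in range(len(complex_.vertices))]
    seg_points: dict[tuple[int, int], list[int]] = {}
    for seg in complex_.segment_cells:
        a, b = seg
        sub = _subdivide_segment(complex_.vertices[a], complex_.vertices[b], target_h)
        ids = [a]
        for pt in sub:
            ids.append(len(points))
            points.append(pt)
        ids.append(b)
        seg_points[seg] = ids

    n_boundary_global = len(points)
    triangles: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for ci, ring in enumerate(complex_.cell_rings):
        poly = complex_.cell_polygon(ci)
        # ordered boundary loop of global point ids
        loop: list[int] = []
        for a, b in zip(ring, np.roll(ring, -1)):
            seg = (min(a, b), max(a, b))
            ids = seg_points[seg]
            ids = ids if ids[0] == a else ids[::-1]
            loop.extend(ids[:-1])
        bnd_ids = np.array(loop)
        bnd_xy = np.array([points[i] for i in bnd_ids])
        # hex spacing slightly under target_h keeps every element edge
        # comfortably below the 1.5 target_h contract after smoothing
        interior = _hex_lattice(poly, 0.92 * target_h, clearance=0.42 * target_h)
        local_pts = np.vstack([bnd_xy, interior]) if len(interior) else bnd_xy
        local_pts, simp = _delaunay_in_polygon(
            local_pts, poly, n_fixed=len(bnd_ids), smooth_iters=smooth_iters
        )
        # register smoothed interior points globally
        local_to_global = list(bnd_ids)
        for pt in local_pts[len(bnd_ids):]:
            local_to_global.append(len(points))
            points.append(pt)
        l2g = np.array(local_to_global)
        triangles.append(l2g[simp])
        labels.append(np.full(len(simp), ci))

    verts2 = np.array(points)
    vertices = np.column_stack([verts2, np.zeros(len(verts2))])
    tris = np.vstack(triangles)
    cell_label = np.concatenate(labels)

    # boundary edges: consecutive subdivision pairs per segment
    bedges = []
    bcells = []
    for seg, ids in seg_points.items():
        cells = complex_.segment_cells[seg]
        for a, b in zip(ids[:-1], ids[1:]):
            bedges.append((a, b))
            bcells.append(cells)
    bedges_arr = np.array(bedges, int) if bedges else np.zeros((0, 2), int)

    # verify conformity: every boundary edge must be an element edge
    edge_set = set()
    for a, b, c in tris:
        for u, v in ((a, b), (b, c), (c, a)):
            edge_set.add((min(u, v), max(u, v)))
    missing = [
        e for e in map(tuple, bedges_arr) if (min(e), max(e)) not in edge_set
    ]
    if missing:
        raise RuntimeError(
            f"{len(missing)} boundary edges not recovered by triangulation; "
            "decrease target_h"
        )

    is_wall = np.zeros(len(vertices), bool)
    is_outer = np.zeros(len(vertices), bool)
    for (a, b), cells in zip(bedges_arr, bcells):
        is_wall[[a, b]] = True
        if len(cells) == 1:
            is_outer[[a, b]] = True

    return SurfaceMesh(
        vertices=vertices,
        triangles=tris,
        cell_label=cell_label,
        thickness=np.full(len(tris), thickness),
        boundary_edges=bedges_arr,
        boundary_edge_cells=list(bcells),
        is_outer_vertex=is_outer,
        is_wall_vertex=is_wall,
    )


def add_anticlinal_beams(mesh: SurfaceMesh, material: MaterialParams) -> SurfaceMesh:
    """Place one beam per cell-boundary edge segment.

    Beams carry the matrix Young's modulus and a thickness of
    ``beam_fraction`` (default 1/5) of the wall thickness.
    """
    out = mesh.copy()
    out.thickness = np.full(mesh.n_elements, material.wall_thickness)
    out.beams = mesh.boundary_edges.copy()
    out.beam_modulus = np.full(len(out.beams), material.E_matrix)
    out.beam_thickness = np.full(len(out.beams), material.beam_thickness)
    out.beam_scale = np.ones(len(out.beams))
    return out


def project_to_heightmap(
    mesh: SurfaceMesh,
    heights: np.ndarray,
    origin: tuple[float, float] = (0.0, 0.0),
    spacing: tuple[float, float] = (1.0, 1.0),
) -> SurfaceMesh:
    """Set vertex z by bilinear interpolation of a height field.

    ``heights[i, j]`` is the height at ``(origin[0] + i*spacing[0],
    origin[1] + j*spacing[1])`` (x indexes the first axis).  x-y
    coordinates are unchanged.  Raises if the mesh footprint leaves the
    field.
    """
    heights = np.asarray(heights, float)
    xs = origin[0] + spacing[0] * np.arange(heights.shape[0])
    ys = origin[1] + spacing[1] * np.arange(heights.shape[1])
    xy = mesh.vertices[:, :2]
    eps = 1e-9 * max(xs[-1] - xs[0], ys[-1] - ys[0], 1.0)
    if (
        xy[:, 0].min() < xs[0] - eps
        or xy[:, 0].max() > xs[-1] + eps
        or xy[:, 1].min() < ys[0] - eps
        or xy[:, 1].max() > ys[-1] + eps
    ):
        raise ValueError("mesh footprint lies outside the height field")
    interp = RegularGridInterpolator((xs, ys), heights, method="linear")
    out = mesh.copy()
    out.vertices[:, 2] = interp(np.clip(xy, [xs[0], ys[0]], [xs[-1], ys[-1]]))
    return out


# ---------------------------------------------------------------------------
# reference shapes for verification against closed-form membrane solutions
# ---------------------------------------------------------------------------


def make_sphere(radius: float, refine: int = 3, thickness: float = 1.0) -> SurfaceMesh:
    """Closed sphere by octahedron subdivision (poles and axis points exact)."""
    verts = np.array(
        [
            [1, 0, 0], [-1, 0, 0],
            [0, 1, 0], [0, -1, 0],
            [0, 0, 1], [0, 0, -1],
        ],
        float,
    )
    faces = np.array(
        [
            [0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
            [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5],
        ]
    )
    verts_list = [v for v in verts]
    cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = verts_list[i] + verts_list[j]
            m = m / np.linalg.norm(m)
            cache[key] = len(verts_list)
            verts_list.append(m)
        return cache[key]

    for _ in range(refine):
        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        faces = np.array(new_faces)

    v = np.array(verts_list) * radius
    faces = _orient_outward(v, faces)
    m = len(faces)
    return SurfaceMesh(
        vertices=v,
        triangles=faces,
        cell_label=np.zeros(m, int),
        thickness=np.full(m, thickness),
    )


def _orient_outward(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    center = vertices.mean(axis=0)
    p = vertices[faces]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    outward = np.einsum("ij,ij->i", n, p.mean(axis=1) - center)
    faces = faces.copy()
    faces[outward < 0] = faces[outward < 0][:, [0, 2, 1]]
    return faces


def make_capsule(
    radius: float,
    length: float,
    n_theta: int = 32,
    n_axial: int = 12,
    n_cap: int = 8,
    thickness: float = 1.0,
) -> SurfaceMesh:
    """Closed capsule (cylinder of given length along z + hemispherical caps)."""
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    rows: list[np.ndarray] = []
    # bottom pole to bottom cap rim
    rows_z: list[float] = []
    phis = np.linspace(0.0, np.pi / 2, n_cap + 1)[1:]  # skip the pole itself
    bot_pole = np.array([[0.0, 0.0, -length / 2 - radius]])
    for phi in phis:
        r = radius * np.sin(phi)
        z = -length / 2 - radius * np.cos(phi)
        rows.append(np.column_stack([r * np.cos(theta), r * np.sin(theta), np.full(n_theta, z)]))
    for z in np.linspace(-length / 2, length / 2, n_axial + 1)[1:]:
        rows.append(np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.full(n_theta, z)]))
    for phi in phis[::-1][1:]:
        r = radius * np.sin(phi)
        z = length / 2 + radius * np.cos(phi)
        rows.append(np.column_stack([r * np.cos(theta), r * np.sin(theta), np.full(n_theta, z)]))
    top_pole = np.array([[0.0, 0.0, length / 2 + radius]])

    verts = np.vstack([bot_pole] + rows + [top_pole])
    faces = []
    # bottom fan
    first = 1
    for k in range(n_theta):
        faces.append([0, first + k, first + (k + 1) % n_theta])
    # strips
    nrows = len(rows)
    for r0 in range(nrows - 1):
        a0 = 1 + r0 * n_theta
        a1 = 1 + (r0 + 1) * n_theta
        for k in range(n_theta):
            k1 = (k + 1) % n_theta
            faces.append([a0 + k, a1 + k, a1 + k1])
            faces.append([a0 + k, a1 + k1, a0 + k1])
    # top fan
    top = len(verts) - 1
    last = 1 + (nrows - 1) * n_theta
    for k in range(n_theta):
        faces.append([top, last + (k + 1) % n_theta, last + k])
    faces = _orient_outward(verts, np.array(faces))
    m = len(faces)
    return SurfaceMesh(
        vertices=verts,
        triangles=faces,
        cell_label=np.zeros(m, int),
        thickness=np.full(m, thickness),
    )


def make_disk(radius: float, mesh_h: float, thickness: float = 1.0) -> SurfaceMesh:
    """Flat disk mesh with the rim resampled at spacing <= mesh_h."""
    n_rim = max(8, int(np.ceil(2 * np.pi * radius / mesh_h)))
    ang = np.linspace(0.0, 2 * np.pi, n_rim, endpoint=False)
    rim = np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])
    poly = Polygon(rim)
    interior = _hex_lattice(poly, mesh_h, clearance=0.55 * mesh_h)
    pts = np.vstack([rim, interior]) if len(interior) else rim
    pts, simp = _delaunay_in_polygon(pts, poly, n_fixed=n_rim, smooth_iters=4)
    verts = np.column_stack([pts, np.zeros(len(pts))])
    m = len(simp)
    is_outer = np.zeros(len(verts), bool)
    is_outer[:n_rim] = True
    return SurfaceMesh(
        vertices=verts,
        triangles=simp,
        cell_label=np.zeros(m, int),
        thickness=np.full(m, thickness),
        is_outer_vertex=is_outer,
        is_wall_vertex=is_outer.copy(),
    )
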