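"""Synthetic-input generators with known ground truth.

Everything the pipeline consumes can be generated here: jigsaw
pavement-cell templates (lobed Voronoi tessellations), oriented filament
textures with a prescribed 2D nematic order parameter, AFM force-curve
grids from known moduli, Poisson severing-event series, and a
guard-cell dome (bump-on-sheet) mesh.  All generators are
seed-deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon

from .cellcomplex import CellComplex, build_cell_complex
from .meshing import SurfaceMesh, _delaunay_in_polygon, _hex_lattice

log = logging.getLogger(__name__)

UNIT_NN = 1e-3  # MPa * nm^2 -> nN


# ---------------------------------------------------------------------------
# jigsaw pavement-cell geometry
# ---------------------------------------------------------------------------


@dataclass
class JigsawParams:
    """Lobed Voronoi tessellation parameters (micrometre)."""

    n_cells: int = 5
    domain_size: float = 60.0
    lobe_amplitude: float = 2.0
    lobe_wavelength: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.lobe_amplitude < 0:
            raise ValueError("lobe_amplitude must be >= 0")
        if self.lobe_amplitude >= self.lobe_wavelength:
            raise ValueError("lobe_amplitude must be smaller than lobe_wavelength")


@dataclass
class JigsawLandmarks:
    """Ground-truth neck/lobe landmarks from the generator.

    For every modulation extremum on a shared wall: the point, the unit
    in-plane normal pointing *into* the cell it indents, and the two
    incident cells (neck_cell is indented; lobe_cell bulges out there).
    """

    points: np.ndarray  # (k, 2)
    normals: np.ndarray  # (k, 2) unit, pointing into neck_cell
    neck_cell: np.ndarray  # (k,)
    lobe_cell: np.ndarray  # (k,)


def _poisson_disk_seeds(rng: np.random.Generator, n: int, size: float) -> np.ndarray:
    """Well-separated random seed points in the domain interior."""
    min_d = 0.45 * size / np.sqrt(n)
    margin = 0.15 * size
    pts: list[np.ndarray] = []
    for _ in range(20000):
        p = rng.uniform(margin, size - margin, 2)
        if all(np.hypot(*(p - q)) >= min_d for q in pts):
            pts.append(p)
            if len(pts) == n:
                break
    if len(pts) < n:
        raise RuntimeError("failed to place Voronoi seeds; lower n_cells")
    return np.array(pts)


def _voronoi_cells(seeds: np.ndarray, size: float) -> list[np.ndarray]:
    """Bounded Voronoi cells via mirrored seeds; exact shared edges.

    Vertices are snapped to a coarse grid so that micro-edges (from
    near-cocircular seed quadruples) collapse into clean junctions
    before the lobe modulation is applied.
    """
    mirrored = [seeds]
    for axis, bound in ((0, 0.0), (0, size), (1, 0.0), (1, size)):
        m = seeds.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    grid = 2.5e-3 * size
    cells = []
    for i in range(len(seeds)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise RuntimeError("unbounded Voronoi region despite mirroring")
        ring = np.round(vor.vertices[region] / grid) * grid
        keep = np.ones(len(ring), bool)
        keep[1:] = np.any(ring[1:] != ring[:-1], axis=1)
        if np.all(ring[0] == ring[-1]) and len(ring) > 1:
            keep[-1] = False
        ring = ring[keep]
        if len(ring) < 3:
            raise RuntimeError("degenerate Voronoi cell after snapping")
        cells.append(ring)
    return cells


def make_jigsaw_cells(
    params: JigsawParams, max_retries: int = 12
) -> tuple[CellComplex, JigsawLandmarks]:
    """Generate a jigsaw pavement-cell template.

    A Voronoi partition of the domain square is decorated with a
    sinusoidal displacement of every interior (cell-cell) wall: zero at
    the wall endpoints (vertex continuity), amplitude/wavelength from
    ``params``.  Each displaced wall is shared exactly by its two cells,
    so total area is conserved.  On self-intersection the amplitude is
    damped and the modulation retried.
    """
    rng = np.random.default_rng(params.seed)
    size = params.domain_size
    if params.n_cells == 1:
        square = np.array([[0.0, 0.0], [size, 0.0], [size, size], [0.0, size]])
        cx = build_cell_complex([square])
        return cx, JigsawLandmarks(
            np.zeros((0, 2)), np.zeros((0, 2)), np.zeros(0, int), np.zeros(0, int)
        )

    seeds = _poisson_disk_seeds(rng, params.n_cells, size)
    base_cells = _voronoi_cells(seeds, size)
    base_complex = build_cell_complex(base_cells)

    # random phase per shared wall, fixed across retries for determinism
    shared_segs = [
        (seg, cells)
        for seg, cells in base_complex.segment_cells.items()
        if len(cells) == 2
    ]
    phases = {seg: rng.uniform(0, 2 * np.pi) for seg, _ in shared_segs}

    amp = params.lobe_amplitude
    for attempt in range(max_retries):
        seg_polylines: dict[tuple[int, int], np.ndarray] = {}
        lm_pts, lm_nrm, lm_neck, lm_lobe = [], [], [], []
        for seg, cells in base_complex.segment_cells.items():
            p0 = base_complex.vertices[seg[0]]
            p1 = base_complex.vertices[seg[1]]
            L = float(np.hypot(*(p1 - p0)))
            if len(cells) == 1 or amp == 0.0 or L < 1e-9:
                seg_polylines[seg] = np.vstack([p0, p1])
                continue
            n_sub = max(8, int(np.ceil(L / (params.lobe_wavelength / 10.0))))
            t = np.linspace(0.0, 1.0, n_sub + 1)
            s = t * L
            tang = (p1 - p0) / L
            perp = np.array([-tang[1], tang[0]])
            envelope = np.sin(np.pi * t)
            wave = np.sin(2 * np.pi * s / params.lobe_wavelength + phases[seg])
            offset = amp * envelope * wave
            pts = p0[None, :] + s[:, None] * tang[None, :] + offset[:, None] * perp[None, :]
            pts[0], pts[-1] = p0, p1
            seg_polylines[seg] = pts
            # landmark extraction: local extrema of the offset
            interior = np.arange(1, n_sub)
            is_max = (np.abs(offset[interior]) > np.abs(offset[interior - 1])) & (
                np.abs(offset[interior]) >= np.abs(offset[interior + 1])
            )
            # which side `perp` points into: test from the straight wall
            mid = 0.5 * (p0 + p1) + 1e-3 * L * perp
            c_a, c_b = cells
            in_a = Polygon(base_cells[c_a]).contains(Point(mid))
            for k in interior[is_max]:
                if abs(offset[k]) < 0.5 * amp:
                    continue
                direction = perp if offset[k] > 0 else -perp
                into = (c_a if in_a else c_b) if offset[k] > 0 else (
                    c_b if in_a else c_a
                )
                other = c_b if into == c_a else c_a
                lm_pts.append(pts[k])
                lm_nrm.append(direction)
                lm_neck.append(into)
                lm_lobe.append(other)

        rings = []
        for ring_ids in base_complex.cell_rings:
            chain = []
            for a, b in zip(ring_ids, np.roll(ring_ids, -1)):
                seg = (min(a, b), max(a, b))
                poly = seg_polylines[seg]
                poly = poly if seg[0] == a else poly[::-1]
                chain.append(poly[:-1])
            rings.append(np.vstack(chain))
        valid = all(Polygon(r).is_valid for r in rings)
        if valid:
            try:
                cx = build_cell_complex(rings)
            except ValueError:
                valid = False
        if valid:
            if attempt > 0:
                log.warning(
                    "jigsaw modulation damped to amplitude %.3f after %d retries",
                    amp,
                    attempt,
                )
            lms = JigsawLandmarks(
                points=np.array(lm_pts) if lm_pts else np.zeros((0, 2)),
                normals=np.array(lm_nrm) if lm_nrm else np.zeros((0, 2)),
                neck_cell=np.array(lm_neck, int) if lm_neck else np.zeros(0, int),
                lobe_cell=np.array(lm_lobe, int) if lm_lobe else np.zeros(0, int),
            )
            return cx, lms
        amp *= 0.7
    raise RuntimeError(
        "could not generate a valid jigsaw template after amplitude damping"
    )


# ---------------------------------------------------------------------------
# filament textures with prescribed nematic order
# ---------------------------------------------------------------------------


@dataclass
class FilamentImageSpec:
    """Oriented filament texture with prescribed order parameter S.

    The empirical 2D nematic order parameter of the drawn angles,
    S_emp = |mean exp(2 i theta)|, converges to ``order_parameter_S``:
    angles are mean_angle + 0.5 * w where w is wrapped-normal with
    circular moment exp(-sigma^2/2) = S (exact analytic inversion).
    """

    width: int = 256
    height: int = 256
    n_filaments: int = 300
    order_parameter_S: float = 0.8
    mean_angle: float = 0.0  # degrees
    filament_width: float = 1.5  # pixels
    noise_sd: float = 0.0  # intensity units (image scaled to ~[0, 1])
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.order_parameter_S <= 1.0:
            raise ValueError("order_parameter_S must lie in [0, 1]")
        if self.width < 8 or self.height < 8:
            raise ValueError("image too small")


def sample_nematic_angles(
    rng: np.random.Generator, n: int, S: float, mean_deg: float
) -> np.ndarray:
    """Axial angles (radians, mod pi) with E|mean exp(2i theta)| -> S."""
    mu2 = 2.0 * np.radians(mean_deg)
    if S >= 1.0:
        two_theta = np.full(n, mu2)
    elif S <= 0.0:
        two_theta = rng.uniform(0.0, 2 * np.pi, n)
    else:
        sigma = np.sqrt(-2.0 * np.log(S))
        two_theta = mu2 + sigma * rng.normal(size=n)
    return (two_theta / 2.0) % np.pi


def make_filament_image(spec: FilamentImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render filaments as Gaussian ridges; returns (image, true angles).

    Each filament is an analytic Gaussian-profile ridge (continuous
    sub-pixel position and orientation -- no rasterization anisotropy),
    drawn as a full image chord so the orientation texture is
    endpoint-free; overlapping filaments add (bundling).  Angles are in
    radians mod pi, measured from the +x axis in image (x = column,
    y = row) axes.
    """
    rng = np.random.default_rng(spec.seed)
    angles = sample_nematic_angles(
        rng, spec.n_filaments, spec.order_parameter_S, spec.mean_angle
    )
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.zeros((h, w))
    ridge_sigma = max(spec.filament_width / 2.0, 0.5)
    for theta in angles:
        cx = rng.uniform(0, w - 1)
        cy = rng.uniform(0, h - 1)
        # perpendicular distance to the infinite line through (cx, cy)
        d = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        img += np.exp(-0.5 * (d / ridge_sigma) ** 2)
    peak = img.max()
    if peak > 0:
        img = img / peak
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return img, angles


def quantize_image(img: np.ndarray, bits: int = 8) -> np.ndarray:
    """Clip to [0, 1] and quantize to 8- or 16-bit (confocal-like range)."""
    if bits not in (8, 16):
        raise ValueError("bits must be 8 or 16")
    top = 2**bits - 1
    dtype = np.uint8 if bits == 8 else np.uint16
    return np.clip(np.round(np.clip(img, 0, 1) * top), 0, top).astype(dtype)


# ---------------------------------------------------------------------------
# AFM force-curve grids
# ---------------------------------------------------------------------------


@dataclass
class CurveGridSpec:
    """Grid of synthetic indentation force curves from a known modulus map."""

    modulus_map: np.ndarray = field(
        default_factory=lambda: np.full((16, 16), 4.0)
    )  # MPa
    model: str = "hertz_cone"  # or "dmt_sphere"
    tip_half_angle: float = 18.0  # degrees
    tip_radius: float = 6.0  # nm
    adhesion_force: float = 1.0  # nN (dmt_sphere only)
    noise_sd: float = 0.0  # nN additive
    poisson: float = 0.5
    max_indentation: float = 100.0  # nm
    approach_range: float = 150.0  # nm of pre-contact travel
    n_samples: int = 256
    topography: np.ndarray | None = None  # nm contact height per pixel
    seed: int = 0

    def __post_init__(self) -> None:
        self.modulus_map = np.asarray(self.modulus_map, float)
        if np.any(self.modulus_map <= 0):
            raise ValueError("moduli must be positive")
        if self.model not in ("hertz_cone", "dmt_sphere"):
            raise ValueError("model must be hertz_cone or dmt_sphere")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.modulus_map.shape


def hertz_cone_force(
    delta_nm: np.ndarray, E_mpa: float, half_angle_deg: float, poisson: float
) -> np.ndarray:
    """Sneddon rigid-cone force, nN: F = (2/pi) tan(a) E/(1-nu^2) d^2."""
    d = np.maximum(np.asarray(delta_nm, float), 0.0)
    coef = (2.0 / np.pi) * np.tan(np.radians(half_angle_deg)) * E_mpa / (
        1.0 - poisson**2
    )
    return coef * d**2 * UNIT_NN


def dmt_sphere_force(
    delta_nm: np.ndarray, E_mpa: float, radius_nm: float, poisson: float,
    adhesion_nN: float = 0.0,
) -> np.ndarray:
    """DMT rigid-sphere force, nN: F = (4/3) E* sqrt(R) d^{3/2} - F_adh.

    E* = E/(1-nu^2) is the reduced modulus.  Out of contact (d <= 0) the
    force is zero (jump-off from the adhesion well).
    """
    d = np.asarray(delta_nm, float)
    e_star = E_mpa / (1.0 - poisson**2)
    f = np.where(
        d > 0,
        (4.0 / 3.0) * e_star * np.sqrt(radius_nm) * np.maximum(d, 0) ** 1.5 * UNIT_NN
        - adhesion_nN,
        0.0,
    )
    return f


@dataclass
class ForceCurve:
    """A single indentation record (nm / nN), approach then retract."""

    separation: np.ndarray  # tip-sample separation, nm (contact at height h)
    force: np.ndarray  # nN
    segment: np.ndarray  # "approach" / "retract" labels
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.separation) == len(self.force) == len(self.segment)):
            raise ValueError("curve arrays must have equal length")

    def approach(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.segment == "approach"
        return self.separation[m], self.force[m]

    def retract(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.segment == "retract"
        return self.separation[m], self.force[m]


def make_force_curves(spec: CurveGridSpec) -> list[list[ForceCurve]]:
    """Generate a grid of force curves from the modulus map.

    Indentation at pixel (i, j) with contact height h_ij: the noiseless
    contact-region force follows the selected forward model exactly; the
    retract segment carries the adhesion well for ``dmt_sphere``.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.grid_shape
    topo = (
        np.zeros((ny, nx)) if spec.topography is None else np.asarray(spec.topography)
    )
    s = np.linspace(
        spec.approach_range, -spec.max_indentation, spec.n_samples
    )  # separation from the *nominal* (h = 0) contact
    grid: list[list[ForceCurve]] = []
    for i in range(ny):
        row = []
        for j in range(nx):
            E = spec.modulus_map[i, j]
            h = topo[i, j]
            delta = h - s  # indentation depth
            if spec.model == "hertz_cone":
                f_app = hertz_cone_force(delta, E, spec.tip_half_angle, spec.poisson)
                f_ret = f_app[::-1].copy()
            else:
                f_app = dmt_sphere_force(
                    delta, E, spec.tip_radius, spec.poisson, adhesion_nN=0.0
                )
                f_ret = dmt_sphere_force(
                    delta[::-1], E, spec.tip_radius, spec.poisson,
                    adhesion_nN=spec.adhesion_force,
                )
            if spec.noise_sd > 0:
                f_app = f_app + rng.normal(0, spec.noise_sd, f_app.shape)
                f_ret = f_ret + rng.normal(0, spec.noise_sd, f_ret.shape)
            sep = np.concatenate([s, s[::-1]])
            force = np.concatenate([f_app, f_ret])
            seg = np.array(["approach"] * len(s) + ["retract"] * len(s))
            row.append(
                ForceCurve(
                    separation=sep,
                    force=force,
                    segment=seg,
                    metadata={
                        "pixel": (i, j),
                        "true_modulus_MPa": float(E),
                        "contact_height_nm": float(h),
                    },
                )
            )
        grid.append(row)
    return grid


# ---------------------------------------------------------------------------
# Poisson severing-event series
# ---------------------------------------------------------------------------


@dataclass
class SeveringSimSpec:
    """Homogeneous Poisson severing events over cells of known area."""

    rate: float = 1e-3  # events / um^2 / min
    cell_areas: list = field(default_factory=lambda: [500.0] * 16)  # um^2
    duration: float = 10.0  # min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if any(a <= 0 for a in self.cell_areas):
            raise ValueError("cell areas must be positive")


def make_severing_series(spec: SeveringSimSpec) -> pd.DataFrame:
    """Event table (cell, x, y, t): counts ~ Poisson(rate * area * duration).

    Positions are uniform in a square patch of the cell's area; times
    uniform in [0, duration].
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cid, area in enumerate(spec.cell_areas):
        lam = spec.rate * area * spec.duration
        n = rng.poisson(lam) if lam > 0 else 0
        side = np.sqrt(area)
        for _ in range(n):
            rows.append(
                {
                    "cell": cid,
                    "x": rng.uniform(0, side),
                    "y": rng.uniform(0, side),
                    "t": rng.uniform(0, spec.duration),
                }
            )
    return pd.DataFrame(rows, columns=["cell", "x", "y", "t"])


# ---------------------------------------------------------------------------
# guard-cell dome (bump on a sheet) and pressurized cap
# ---------------------------------------------------------------------------


def make_guard_cell_dome(
    radius: float,
    height: float,
    mesh_h: float,
    domain_size: float | None = None,
    profile: str = "gaussian",
) -> SurfaceMesh:
    """Bump on a flat sheet: an elevated stoma surrogate.

    A centered circular region (the guard-cell pair, split into two cell
    labels by a diameter) is raised by ``height`` with a Gaussian or
    spherical-cap profile; the surrounding sheet is flat (label 0).  The
    circle and the splitting diameter are exact mesh polylines, so
    z-restrictions and beams can be attached to them.
    """
    if height < 0:
        raise ValueError("height must be >= 0")
    if mesh_h >= radius:
        raise ValueError("mesh_h must be smaller than radius")
    if profile not in ("gaussian", "spherical_cap"):
        raise ValueError("profile must be gaussian or spherical_cap")
    size = domain_size if domain_size is not None else 5.0 * radius
    half = size / 2.0

    n_ring = max(16, int(np.ceil(2 * np.pi * radius / mesh_h)))
    ang = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    ring = np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])
    n_diam = max(3, int(np.ceil(2 * radius / mesh_h)))
    xs = np.linspace(-radius, radius, n_diam + 1)[1:-1]
    diam = np.column_stack([xs, np.zeros(len(xs))])
    n_sq = max(4, int(np.ceil(size / mesh_h)))
    t = np.linspace(-half, half, n_sq + 1)[:-1]
    square = np.vstack(
        [
            np.column_stack([t, np.full(len(t), -half)]),
            np.column_stack([np.full(len(t), half), t]),
            np.column_stack([-t, np.full(len(t), half)]),
            np.column_stack([np.full(len(t), -half), -t]),
        ]
    )
    outer_poly = Polygon([(-half, -half), (half, -half), (half, half), (-half, half)])
    disk_poly = Polygon(ring)

    fixed = np.vstack([square, ring, diam])
    n_fixed = len(fixed)
    inner = _hex_lattice(disk_poly, mesh_h, clearance=0.5 * mesh_h)
    # keep hex points off the diameter line
    if len(inner):
        inner = inner[np.abs(inner[:, 1]) > 0.4 * mesh_h]
    sheet_region = outer_poly.difference(disk_poly)
    outer_pts = _hex_lattice(outer_poly, mesh_h, clearance=0.5 * mesh_h)
    if len(outer_pts):
        import shapely

        keep = shapely.contains_xy(
            sheet_region.buffer(-0.5 * mesh_h), outer_pts[:, 0], outer_pts[:, 1]
        )
        outer_pts = outer_pts[keep]
    pts = np.vstack([fixed, inner, outer_pts])
    pts, simp = _delaunay_in_polygon(pts, outer_poly, n_fixed=n_fixed, smooth_iters=3)

    cent = pts[simp].mean(axis=1)
    r_c = np.hypot(cent[:, 0], cent[:, 1])
    label = np.zeros(len(simp), int)
    in_disk = r_c < radius
    label[in_disk & (cent[:, 1] >= 0)] = 1
    label[in_disk & (cent[:, 1] < 0)] = 2

    z = np.zeros(len(pts))
    r = np.hypot(pts[:, 0], pts[:, 1])
    if height > 0:
        if profile == "gaussian":
            # unclipped Gaussian with sigma = radius: the guard-cell
            # ring sits elevated on the bump flank (z = 0.61 height)
            # and the topography decays smoothly into the sheet
            z = height * np.exp(-0.5 * (r / radius) ** 2)
        else:
            R_s = (radius**2 + height**2) / (2.0 * height)
            inside = r < radius
            z[inside] = np.sqrt(np.maximum(R_s**2 - r[inside] ** 2, 0.0)) - (
                R_s - height
            )
    verts = np.column_stack([pts, z])

    # boundary edges: ring + diameter (cell walls), square (outer)
    bedges, bcells = [], []
    ring_ids = np.arange(len(square), len(square) + n_ring)
    for a, b in zip(ring_ids, np.roll(ring_ids, -1)):
        mid = 0.5 * (pts[a] + pts[b])
        upper = mid[1] >= 0
        bedges.append((a, b))
        bcells.append((0, 1) if upper else (0, 2))
    diam_ids = np.concatenate(
        [
            [ring_ids[0]],  # (radius, 0) point on the ring
            np.arange(len(square) + n_ring, len(square) + n_ring + len(diam))[::-1],
            [ring_ids[n_ring // 2]],
        ]
    ) if len(diam) else np.array([ring_ids[0], ring_ids[n_ring // 2]])
    # order diameter chain by x
    dchain = sorted(diam_ids, key=lambda i: pts[i, 0])
    for a, b in zip(dchain[:-1], dchain[1:]):
        bedges.append((a, b))
        bcells.append((1, 2))
    sq_ids = np.arange(len(square))
    for a, b in zip(sq_ids, np.roll(sq_ids, -1)):
        bedges.append((a, b))
        bcells.append((0,))
    bedges_arr = np.array(bedges, int)

    is_wall = np.zeros(len(verts), bool)
    is_outer = np.zeros(len(verts), bool)
    for (a, b), cells in zip(bedges_arr, bcells):
        is_wall[[a, b]] = True
        if len(cells) == 1:
            is_outer[[a, b]] = True
    return SurfaceMesh(
        vertices=verts,
        triangles=simp,
        cell_label=label,
        thickness=np.ones(len(simp)),
        boundary_edges=bedges_arr,
        boundary_edge_cells=bcells,
        is_outer_vertex=is_outer,
        is_wall_vertex=is_wall,
    )


def make_pressurized_cap(radius: float, height: float, mesh_h: float) -> SurfaceMesh:
    """Spherical cap over a fixed base ring: the compression test body.

    Base circle of given ``radius`` at z = 0, apex at ``height``; the
    enclosed volume is the cap volume (the base plane closes it).
    """
    if height <= 0 or mesh_h >= radius:
        raise ValueError("need height > 0 and mesh_h < radius")
    from .meshing import make_disk

    disk = make_disk(radius, mesh_h)
    R_s = (radius**2 + height**2) / (2.0 * height)
    r = np.hypot(disk.vertices[:, 0], disk.vertices[:, 1])
    disk.vertices[:, 2] = np.sqrt(np.maximum(R_s**2 - r**2, 0.0)) - (R_s - height)
    rim = disk.is_outer_vertex
    disk.vertices[rim, 2] = 0.0
    return disk
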