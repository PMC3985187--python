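"""Planar cell complexes: polygonal cells with shared-edge adjacency.

A :class:`CellComplex` is the tissue template: a set of simple, closed,
counter-clockwise polygons (micrometre coordinates) that tile a region.
Edges shared between two cells must be geometrically identical vertex
chains in the two incident rings, which is what the constrained mesher
downstream relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon


def _ring_area(ring: np.ndarray) -> float:
    """Signed shoelace area of a closed ring given without repeat vertex."""
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _snap_key(pt: np.ndarray, tol: float) -> tuple[int, int]:
    return (int(round(pt[0] / tol)), int(round(pt[1] / tol)))


@dataclass
class CellComplex:
    """Cells as CCW rings plus shared-edge adjacency and outer boundary."""

    cells: list[np.ndarray]
    # (cell_i, cell_j) -> list of shared undirected segments (vertex index pairs
    # into the snapped global vertex table)
    adjacency: dict[tuple[int, int], list[tuple[int, int]]]
    outer_boundary: np.ndarray  # closed chain of vertices, (n, 2)
    vertices: np.ndarray  # snapped global vertex table, (nv, 2)
    # per cell: ring as indices into `vertices`
    cell_rings: list[np.ndarray]
    # undirected segment -> sorted tuple of incident cells
    segment_cells: dict[tuple[int, int], tuple[int, ...]] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_polygon(self, i: int) -> Polygon:
        return Polygon(self.cells[i])

    def cell_areas(self) -> np.ndarray:
        return np.array([_ring_area(c) for c in self.cells])

    def neighbors(self, i: int) -> set[int]:
        out: set[int] = set()
        for (a, b) in self.adjacency:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return out

    def outer_boundary_length(self) -> float:
        d = np.diff(np.vstack([self.outer_boundary, self.outer_boundary[:1]]), axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def build_cell_complex(
    polygons: list[np.ndarray] | list[list],
    snap_tol: float | None = None,
) -> CellComplex:
    """Assemble a :class:`CellComplex` from raw polygon rings.

    Parameters
    ----------
    polygons
        One ring per cell, each an (n, 2) array of xy micrometre
        coordinates without a repeated closing vertex.  Rings are
        re-oriented counter-clockwise.
    snap_tol
        Vertex snapping tolerance used to merge floating-point duplicate
        vertices between rings.  Defaults to 1e-6 times the template
        diameter.

    Raises
    ------
    ValueError
        On open/degenerate rings, self-intersecting rings, or cells with
        overlapping interiors (the offending pair is named).
    """
    rings = []
    for k, p in enumerate(polygons):
        r = np.asarray(p, dtype=float)
        if r.ndim != 2 or r.shape[1] != 2 or len(r) < 3:
            raise ValueError(f"cell {k}: ring must be an (n>=3, 2) array")
        if np.allclose(r[0], r[-1]):
            r = r[:-1]
        if len(r) < 3:
            raise ValueError(f"cell {k}: ring has fewer than 3 distinct vertices")
        poly = Polygon(r)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"cell {k}: ring is not a simple closed polygon")
        if _ring_area(r) < 0:
            r = r[::-1]
        rings.append(r)

    shapely_polys = [Polygon(r) for r in rings]
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            inter = shapely_polys[i].intersection(shapely_polys[j])
            if inter.area > 1e-9 * min(shapely_polys[i].area, shapely_polys[j].area):
                raise ValueError(f"cells {i} and {j} have overlapping interiors")

    allpts = np.vstack(rings)
    diam = float(np.max(np.ptp(allpts, axis=0)))
    tol = snap_tol if snap_tol is not None else max(1e-6 * diam, 1e-12)

    # snapped global vertex table
    key_to_id: dict[tuple[int, int], int] = {}
    verts: list[np.ndarray] = []
    cell_rings: list[np.ndarray] = []
    for r in rings:
        ids = []
        for pt in r:
            key = _snap_key(pt, tol)
            if key not in key_to_id:
                key_to_id[key] = len(verts)
                verts.append(pt.copy())
            ids.append(key_to_id[key])
        # drop consecutive duplicates created by snapping
        ids_arr = np.array(ids)
        keep = np.ones(len(ids_arr), bool)
        keep[1:] = ids_arr[1:] != ids_arr[:-1]
        if ids_arr[0] == ids_arr[-1] and len(ids_arr) > 1:
            keep[-1] = False
        cell_rings.append(ids_arr[keep])
    vertices = np.array(verts)

    # undirected segment -> incident cells
    seg_cells: dict[tuple[int, int], list[int]] = {}
    for ci, ring in enumerate(cell_rings):
        for a, b in zip(ring, np.roll(ring, -1)):
            key = (min(a, b), max(a, b))
            seg_cells.setdefault(key, []).append(ci)

    adjacency: dict[tuple[int, int], list[tuple[int, int]]] = {}
    boundary_segs: list[tuple[int, int]] = []
    for seg, cs in seg_cells.items():
        if len(cs) > 2:
            raise ValueError(f"segment {seg} shared by more than two cells")
        if len(cs) == 2:
            pair = (min(cs), max(cs))
            adjacency.setdefault(pair, []).append(seg)
        else:
            boundary_segs.append(seg)

    outer = _chain_segments(boundary_segs, vertices)
    return CellComplex(
        cells=[vertices[r] for r in cell_rings],
        adjacency=adjacency,
        outer_boundary=outer,
        vertices=vertices,
        cell_rings=cell_rings,
        segment_cells={s: tuple(sorted(c)) for s, c in seg_cells.items()},
    )


def _chain_segments(segs: list[tuple[int, int]], vertices: np.ndarray) -> np.ndarray:
    """Chain undirected segments into a single closed loop of coordinates."""
    if not segs:
        return np.zeros((0, 2))
    nbr: dict[int, list[int]] = {}
    for a, b in segs:
        nbr.setdefault(a, []).append(b)
        nbr.setdefault(b, []).append(a)
    for v, ns in nbr.items():
        if len(ns) != 2:
            raise ValueError("outer boundary is not a single closed loop")
    start = segs[0][0]
    chain = [start]
    prev, cur = None, start
    while True:
        a, b = nbr[cur]
        nxt = b if a == prev else a
        if nxt == start:
            break
        chain.append(nxt)
        prev, cur = cur, nxt
        if len(chain) > len(segs) + 1:
            raise ValueError("outer boundary failed to close")
    return vertices[np.array(chain)]
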