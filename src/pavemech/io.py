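"""Readers/writers and run configuration.

Formats: cell polygons as JSON (micrometre rings), meshes as legacy
ASCII VTK (with element data arrays) and Wavefront OBJ, images as TIFF,
tables as CSV, ImageJ ROI files (polygon types), and TOML/JSON run
configs with a manifest echo of the effective configuration.
"""

from __future__ import annotations

import json
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .materials import MaterialParams
from .meshing import SurfaceMesh

# ---------------------------------------------------------------------------
# polygons
# ---------------------------------------------------------------------------


def save_polygons(path: str | Path, polygons: list[np.ndarray], params: dict | None = None) -> None:
    payload = {
        "cells": [np.asarray(p, float).tolist() for p in polygons],
        "params": params or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_polygons(path: str | Path) -> tuple[list[np.ndarray], dict]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON at byte {exc.pos}: {exc.msg}") from exc
    if "cells" not in payload:
        raise ValueError(f"{path}: missing 'cells' key")
    return [np.asarray(c, float) for c in payload["cells"]], payload.get("params", {})


# ---------------------------------------------------------------------------
# meshes: legacy ASCII VTK + OBJ
# ---------------------------------------------------------------------------


def write_vtk(
    path: str | Path,
    mesh: SurfaceMesh,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Legacy ASCII VTK unstructured grid with per-element arrays.

    ``cell_data`` values may be (m,) scalars or (m, 3) vectors; the
    cell label and thickness are always included.
    """
    lines = [
        "# vtk DataFile Version 3.0",
        "pavemech surface mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_vertices} double",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}")
    m = mesh.n_elements
    lines.append(f"CELLS {m} {4 * m}")
    for t in mesh.triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["5"] * m)

    cdata = {"cell_label": mesh.cell_label.astype(float), "thickness": mesh.thickness}
    if mesh.fiber_dir is not None:
        cdata["fiber_dir"] = mesh.fiber_dir
    cdata.update(cell_data or {})
    lines.append(f"CELL_DATA {m}")
    for name, arr in cdata.items():
        arr = np.asarray(arr, float)
        if arr.ndim == 1:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{x:.12g}" for x in arr)
        else:
            lines.append(f"VECTORS {name} double")
            lines.extend(f"{r[0]:.12g} {r[1]:.12g} {r[2]:.12g}" for r in arr)
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{x:.12g}" for x in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{r[0]:.12g} {r[1]:.12g} {r[2]:.12g}" for r in arr)
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read back a legacy ASCII VTK triangle mesh (vertices, triangles, cell data)."""
    tokens: list[str] = []
    for ln, line in enumerate(Path(path).read_text().splitlines()):
        if ln in (0, 1) or line.strip() in ("ASCII",):
            continue
        tokens.extend(line.split())
    it = iter(range(len(tokens)))

    def expect(idx: int, word: str) -> int:
        if tokens[idx] != word:
            raise ValueError(f"{path}: expected '{word}' at token {idx}, got '{tokens[idx]}'")
        return idx + 1

    i = 0
    i = expect(i, "DATASET")
    i = expect(i, "UNSTRUCTURED_GRID")
    i = expect(i, "POINTS")
    npts = int(tokens[i]); i += 2  # count, dtype
    pts = np.array(tokens[i : i + 3 * npts], float).reshape(npts, 3)
    i += 3 * npts
    i = expect(i, "CELLS")
    ncell = int(tokens[i]); ntok = int(tokens[i + 1]); i += 2
    raw = np.array(tokens[i : i + ntok], int)
    i += ntok
    tris = raw.reshape(ncell, 4)[:, 1:]
    i = expect(i, "CELL_TYPES")
    i += 1 + ncell
    cdata: dict = {}
    while i < len(tokens):
        word = tokens[i]
        if word == "CELL_DATA":
            i += 2
            continue
        if word == "POINT_DATA":
            break
        if word == "SCALARS":
            name = tokens[i + 1]
            i += 4  # SCALARS name dtype ncomp
            i += 2  # LOOKUP_TABLE default
            cdata[name] = np.array(tokens[i : i + ncell], float)
            i += ncell
        elif word == "VECTORS":
            name = tokens[i + 1]
            i += 3
            cdata[name] = np.array(tokens[i : i + 3 * ncell], float).reshape(ncell, 3)
            i += 3 * ncell
        else:
            raise ValueError(f"{path}: unexpected token '{word}' at {i}")
    return pts, tris, cdata


def write_obj(path: str | Path, mesh: SurfaceMesh) -> None:
    lines = [f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in mesh.vertices]
    lines += [f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}" for t in mesh.triangles]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ImageJ polygon ROIs
# ---------------------------------------------------------------------------

_ROI_POLYGON_TYPES = {0: "polygon", 3: "freehand", 4: "traced"}


def decode_imagej_roi(data: bytes) -> np.ndarray:
    """Decode an ImageJ .roi byte blob (polygon family only) to (x, y) vertices."""
    if data[:4] != b"Iout":
        raise ValueError("not an ImageJ ROI (missing 'Iout' magic at byte 0)")
    roi_type = data[6]
    if roi_type not in _ROI_POLYGON_TYPES:
        raise ValueError(f"unsupported ROI type {roi_type}; only polygon ROIs")
    top, left, _bottom, _right = struct.unpack(">4h", data[8:16])
    n = struct.unpack(">h", data[16:18])[0]
    coords = struct.unpack(f">{2 * n}h", data[64 : 64 + 4 * n])
    xs = np.array(coords[:n]) + left
    ys = np.array(coords[n:]) + top
    return np.column_stack([xs, ys]).astype(float)


def encode_imagej_roi(vertices: np.ndarray) -> bytes:
    """Encode an (x, y) polygon as a minimal ImageJ .roi blob."""
    v = np.asarray(vertices)
    xs, ys = v[:, 0].astype(int), v[:, 1].astype(int)
    left, top = int(xs.min()), int(ys.min())
    right, bottom = int(xs.max()), int(ys.max())
    n = len(v)
    head = bytearray(64)
    head[0:4] = b"Iout"
    struct.pack_into(">h", head, 4, 227)  # version
    head[6] = 0  # polygon
    struct.pack_into(">4h", head, 8, top, left, bottom, right)
    struct.pack_into(">h", head, 16, n)
    body = struct.pack(f">{n}h", *(xs - left)) + struct.pack(f">{n}h", *(ys - top))
    return bytes(head) + body


def load_imagej_roi_zip(path: str | Path) -> dict[str, np.ndarray]:
    """Polygon ROIs from an ImageJ RoiSet zip, keyed by entry name."""
    out = {}
    with zipfile.ZipFile(path) as zf:
        for name in zf.namelist():
            if name.endswith(".roi"):
                out[name[:-4]] = decode_imagej_roi(zf.read(name))
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_RUN_KEYS = {"stage", "inputs", "output_dir", "seed", "tolerances", "material"}


@dataclass
class RunConfig:
    """Validated stage configuration with material defaults filled in."""

    stage: str = "simulate"
    inputs: dict = field(default_factory=dict)
    output_dir: str = "results"
    seed: int = 0
    tolerances: dict = field(default_factory=dict)
    material: MaterialParams = field(default_factory=MaterialParams)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "inputs": self.inputs,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "tolerances": self.tolerances,
            "material": self.material.to_dict(),
        }


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML (or JSON) run config, filling material defaults.

    Unknown top-level or material keys raise; so do invalid values
    (the error names the key).
    """
    text = Path(path).read_text()
    if str(path).endswith(".json") or text.lstrip().startswith("{"):
        raw = json.loads(text)
    else:
        import tomllib

        raw = tomllib.loads(text)
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    mat_raw = raw.pop("material", {})
    try:
        material = MaterialParams.from_dict(mat_raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"material config invalid: {exc}") from exc
    cfg = RunConfig(material=material, **{k: v for k, v in raw.items()})
    if not isinstance(cfg.seed, int):
        raise ValueError("seed: expected an integer")
    return cfg


def save_config(path: str | Path, cfg: RunConfig) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=1))


def write_manifest(path: str | Path, cfg: RunConfig | dict, extras: dict | None = None) -> None:
    """Echo the full effective configuration of a run as JSON."""
    payload = cfg.to_dict() if isinstance(cfg, RunConfig) else dict(cfg)
    if extras:
        payload = {**payload, **extras}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
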