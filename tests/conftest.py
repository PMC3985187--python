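"""Shared fixtures: expensive equilibrium solves are session-scoped."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import pavemech as pm


@dataclass
class TemplateSolution:
    params: pm.JigsawParams
    complex: pm.CellComplex
    landmarks: object
    mesh: pm.SurfaceMesh
    material: pm.MaterialParams
    loads: pm.LoadCase
    displacements: pm.Displacements
    stress: pm.StressField


def solve_template(params: pm.JigsawParams, target_h: float,
                   material: pm.MaterialParams | None = None) -> TemplateSolution:
    mat = material or pm.MaterialParams()
    cx, lm = pm.make_jigsaw_cells(params)
    mesh = pm.add_anticlinal_beams(pm.mesh_surface(cx, target_h), mat)
    loads = pm.apply_loads_and_bcs(mesh, mat)
    disp = pm.solve_equilibrium(mesh, mat, loads, n_increments=3)
    st = pm.principal_stress(disp, mesh, mat)
    return TemplateSolution(params, cx, lm, mesh, mat, loads, disp, st)


@pytest.fixture(scope="session")
def small_template() -> TemplateSolution:
    """12-cell 60 um jigsaw template, solved under default loading."""
    return solve_template(
        pm.JigsawParams(n_cells=12, domain_size=60.0, lobe_amplitude=2.0,
                        lobe_wavelength=8.0, seed=7),
        target_h=2.0,
    )


@pytest.fixture(scope="session")
def feedback_small(small_template: TemplateSolution) -> pm.FeedbackResult:
    """Stress->fiber feedback iteration on the small template."""
    return pm.feedback_align(
        small_template.mesh, small_template.material, small_template.loads,
        n_steps=10, solver_kwargs=dict(n_increments=2),
    )


def sphere_loads(mesh: pm.SurfaceMesh, pressure: float) -> pm.LoadCase:
    """Pressurize a closed surface; pin exactly the six rigid-body modes.

    Constraint points sit on the coordinate axes so a purely radial
    inflation satisfies them exactly.
    """
    v = mesh.vertices
    n = len(v)
    mask = np.zeros((n, 3), bool)

    def nearest(pt):
        return int(np.argmin(np.linalg.norm(v - np.asarray(pt), axis=1)))

    top = v[:, 2].max()
    bot = v[:, 2].min()
    rx = v[:, 0].max()
    mask[nearest([0, 0, top]), [0, 1]] = True
    mask[nearest([0, 0, bot]), [0, 1]] = True
    mask[nearest([rx, 0, 0]), [1, 2]] = True
    return pm.LoadCase(
        pressure=np.full(mesh.n_elements, pressure),
        fixed_mask=mask,
        fixed_target=v.copy(),
    )


@dataclass
class SphereSolution:
    mesh: pm.SurfaceMesh
    stress: pm.StressField
    radius_deformed: float


@pytest.fixture(scope="session")
def sphere_solutions() -> list[SphereSolution]:
    """Pressurized sphere (R=20, t=1, P=0.2) at three refinement levels."""
    mat = pm.MaterialParams()
    out = []
    for refine in (2, 3, 4):
        sph = pm.make_sphere(20.0, refine=refine)
        loads = sphere_loads(sph, mat.turgor_P)
        disp = pm.solve_equilibrium(sph, mat, loads, n_increments=2)
        st = pm.principal_stress(disp, sph, mat)
        rdef = float(np.linalg.norm(sph.vertices + disp.u, axis=1).mean())
        out.append(SphereSolution(sph, st, rdef))
    return out


@pytest.fixture(scope="session")
def capsule_solution() -> tuple[pm.SurfaceMesh, pm.StressField]:
    """Pressurized capped cylinder (hoop:axial oracle)."""
    mat = pm.MaterialParams()
    cap = pm.make_capsule(10.0, 40.0, n_theta=40, n_axial=20, n_cap=8)
    loads = sphere_loads(cap, mat.turgor_P)
    disp = pm.solve_equilibrium(cap, mat, loads, n_increments=2)
    return cap, pm.principal_stress(disp, cap, mat)


@dataclass
class PerturbationSetup:
    template: TemplateSolution
    single_cells: set
    lacer_cells: set
    scores: dict  # name -> (baseline score, perturbed score)
    annulus: float


@pytest.fixture(scope="session")
def perturbation_setup() -> PerturbationSetup:
    """36-cell template with a single-cell ablation and a multi-cell
    laceration, each scored for circumferential alignment around its
    wound (annulus one cell diameter, smoothed outline)."""
    base = solve_template(
        pm.JigsawParams(n_cells=36, domain_size=120.0, lobe_amplitude=2.0,
                        lobe_wavelength=8.0, seed=7),
        target_h=3.0,
    )
    centroids = [np.mean(c, axis=0) for c in base.complex.cells]
    ctr = np.array([60.0, 60.0])
    cid = int(np.argmin([np.linalg.norm(c - ctr) for c in centroids]))
    lac = {i for i, c in enumerate(centroids) if np.linalg.norm(c - ctr) < 26.0}
    lac.add(cid)
    annulus = 20.0  # approximately one cell diameter

    model = pm.Model(base.mesh, base.material, base.loads)
    scores = {}
    for name, cells in [("single", {cid}), ("laceration", lac)]:
        wound = pm.wound_boundary(base.mesh, cells, smooth_radius=4.0)
        mod = pm.ablate(model, pm.AblationSpec(cells))
        disp = pm.solve_equilibrium(mod.mesh, mod.material, mod.loads,
                                    n_increments=3)
        st = pm.principal_stress(disp, mod.mesh, mod.material)
        scores[name] = (
            pm.circumferential_alignment(base.stress, base.mesh, wound, annulus),
            pm.circumferential_alignment(st, mod.mesh, wound, annulus),
        )
    return PerturbationSetup(base, {cid}, lac, scores, annulus)


@pytest.fixture(scope="session")
def compression_results() -> list[pm.CompressionResult]:
    """Pressurized cap compressed at three decreasing plate gaps."""
    mat = pm.MaterialParams()
    cap = pm.make_pressurized_cap(radius=20.0, height=8.0, mesh_h=2.0)
    mask = np.zeros((cap.n_vertices, 3), bool)
    mask[cap.is_outer_vertex, :] = True
    loads = pm.LoadCase(np.full(cap.n_elements, mat.turgor_P), mask,
                        cap.vertices.copy())
    model = pm.Model(cap, mat, loads)
    fem = pm.FemSystem(cap, mat)
    disp0 = pm.solve_equilibrium(cap, mat, loads, system=fem)
    apex = float((cap.vertices + disp0.u)[:, 2].max())
    return [
        pm.compress(model, pm.CompressionSpec(plate_gap=f * apex))
        for f in (0.95, 0.90, 0.85)
    ]


@pytest.fixture(scope="session")
def bump_solution() -> tuple[pm.SurfaceMesh, pm.StressField]:
    """Elevated stoma surrogate: bump-on-sheet under tissue tension."""
    mat = pm.MaterialParams()
    dome = pm.make_guard_cell_dome(radius=8.0, height=8.0, mesh_h=1.6,
                                   domain_size=48.0, profile="gaussian")
    dome = pm.add_anticlinal_beams(dome, mat)
    loads = pm.apply_loads_and_bcs(dome, mat)
    disp = pm.solve_equilibrium(dome, mat, loads, n_increments=3)
    return dome, pm.principal_stress(disp, dome, mat)


@pytest.fixture(scope="session")
def aligned_image():
    """Perfectly aligned filament texture (S = 1, 30 deg, 500 chords)."""
    spec = pm.FilamentImageSpec(width=256, height=256, n_filaments=500,
                                order_parameter_S=1.0, mean_angle=30.0, seed=11)
    return pm.make_filament_image(spec)


@pytest.fixture(scope="session")
def orthogonal_pair_image():
    """Two equal orthogonal filament populations (isotropic tensor).

    The second population is the exact 90-degree rotation (transpose)
    of the first, so the two sets have identical number and intensity.
    """
    a, _ = pm.make_filament_image(pm.FilamentImageSpec(
        width=256, height=256, n_filaments=250, order_parameter_S=1.0,
        mean_angle=0.0, seed=21))
    return a + a.T
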