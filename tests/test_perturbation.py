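"""Ablation, laceration, circumferential scoring, plate compression."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

import pavemech as pm


def synthetic_field(mesh, kind, center=(0.0, 0.0), seed=0):
    """StressField with prescribed in-plane directions for metric tests."""
    cent = mesh.element_centroids()[:, :2] - np.asarray(center)
    r = np.maximum(np.hypot(cent[:, 0], cent[:, 1]), 1e-9)
    radial = cent / r[:, None]
    if kind == "tangential":
        d = np.column_stack([-radial[:, 1], radial[:, 0]])
    elif kind == "radial":
        d = radial
    else:
        rng = np.random.default_rng(seed)
        ang = rng.uniform(0, np.pi, len(cent))
        d = np.column_stack([np.cos(ang), np.sin(ang)])
    m = len(cent)
    d3 = np.column_stack([d, np.zeros(m)])
    return pm.StressField(
        sigma1=np.ones(m), sigma2=np.zeros(m), dir1=d3,
        dir2=np.column_stack([-d[:, 1], d[:, 0], np.zeros(m)]),
        degenerate=np.zeros(m, bool),
    )


@pytest.fixture(scope="module")
def disk_with_hole():
    dome = pm.make_guard_cell_dome(radius=6.0, height=0.0, mesh_h=1.2,
                                   domain_size=40.0)
    hole = Polygon([(6 * np.cos(a), 6 * np.sin(a))
                    for a in np.linspace(0, 2 * np.pi, 64)])
    return dome, hole


def test_tangential_field_scores_one(disk_with_hole):
    mesh, hole = disk_with_hole
    s = pm.circumferential_alignment(synthetic_field(mesh, "tangential"),
                                     mesh, hole, annulus_width=10.0)
    # tolerance reflects the 64-gon discretization of the wound circle
    assert s == pytest.approx(1.0, abs=2e-3)


def test_radial_field_scores_zero(disk_with_hole):
    mesh, hole = disk_with_hole
    s = pm.circumferential_alignment(synthetic_field(mesh, "radial"),
                                     mesh, hole, annulus_width=10.0)
    assert s == pytest.approx(0.0, abs=2e-3)


def test_random_field_scores_half(disk_with_hole):
    """E[cos^2] = 1/2 under uniform axial angles (Monte-Carlo bound)."""
    mesh, hole = disk_with_hole
    vals = [
        pm.circumferential_alignment(synthetic_field(mesh, "random", seed=s),
                                     mesh, hole, annulus_width=10.0)
        for s in range(5)
    ]
    assert np.mean(vals) == pytest.approx(0.5, abs=0.05)


def test_score_rotation_invariant(disk_with_hole):
    """Rotating directions and wound together leaves the score alone."""
    mesh, hole = disk_with_hole
    field = synthetic_field(mesh, "random", seed=3)
    s0 = pm.circumferential_alignment(field, mesh, hole, annulus_width=10.0)
    ang = np.radians(63.0)
    R = np.array([[np.cos(ang), -np.sin(ang), 0],
                  [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
    mesh_r = mesh.copy()
    mesh_r.vertices = mesh.vertices @ R.T
    field_r = pm.StressField(field.sigma1, field.sigma2, field.dir1 @ R.T,
                             field.dir2 @ R.T, field.degenerate)
    s1 = pm.circumferential_alignment(field_r, mesh_r, hole,
                                      annulus_width=10.0)
    # the wound polygon is a 64-gon, so rotation symmetry is approximate
    assert s1 == pytest.approx(s0, abs=2e-3)
    # reversing the wound polyline orientation changes nothing either
    hole_rev = Polygon(np.asarray(hole.exterior.coords)[::-1])
    s2 = pm.circumferential_alignment(field, mesh, hole_rev, annulus_width=10.0)
    assert s2 == pytest.approx(s0, abs=1e-9)


def test_empty_annulus_rejected(disk_with_hole):
    mesh, _ = disk_with_hole
    far = Polygon([(500, 500), (501, 500), (501, 501), (500, 501)])
    with pytest.raises(ValueError, match="annulus"):
        pm.circumferential_alignment(synthetic_field(mesh, "radial"),
                                     mesh, far, annulus_width=0.5)


def test_ablate_empty_set_is_identity(small_template):
    model = pm.Model(small_template.mesh, small_template.material,
                     small_template.loads)
    out = pm.ablate(model, pm.AblationSpec(set()))
    assert np.allclose(out.mesh.stiffness_scale, 1.0)
    assert np.allclose(out.loads.pressure, small_template.loads.pressure)


def test_ablate_modifies_only_target_cells(small_template):
    model = pm.Model(small_template.mesh, small_template.material,
                     small_template.loads)
    out = pm.ablate(model, pm.AblationSpec({0}, stiffness_factor=0.1))
    dead = out.mesh.cell_label == 0
    assert np.allclose(out.mesh.stiffness_scale[dead], 0.1)
    assert np.allclose(out.mesh.stiffness_scale[~dead], 1.0)
    assert np.all(out.loads.pressure[dead] == 0.0)
    assert np.all(out.loads.pressure[~dead] ==
                  small_template.loads.pressure[~dead])
    # input model untouched
    assert np.allclose(small_template.mesh.stiffness_scale, 1.0)


def test_ablate_all_cells_rejected(small_template):
    model = pm.Model(small_template.mesh, small_template.material,
                     small_template.loads)
    with pytest.raises(ValueError, match="every cell"):
        pm.ablate(model, pm.AblationSpec(set(range(12))))
    with pytest.raises(ValueError, match="unknown"):
        pm.ablate(model, pm.AblationSpec({99}))


def test_wound_ordering_large_cut_over_single_over_baseline(perturbation_setup):
    """Circumferential alignment: laceration > single ablation > baseline
    on the same template and annulus width."""
    sc = perturbation_setup.scores
    base = max(sc["single"][0], sc["laceration"][0])
    assert sc["laceration"][1] > sc["single"][1] > base


def test_single_ablation_effect_is_local(perturbation_setup):
    """The single-cell response is strongest adjacent to the wound."""
    setup = perturbation_setup
    base = setup.template
    model = pm.Model(base.mesh, base.material, base.loads)
    mod = pm.ablate(model, pm.AblationSpec(setup.single_cells))
    disp = pm.solve_equilibrium(mod.mesh, mod.material, mod.loads,
                                n_increments=3)
    st = pm.principal_stress(disp, mod.mesh, mod.material)
    wound = pm.wound_boundary(base.mesh, setup.single_cells, smooth_radius=4.0)
    near = pm.circumferential_alignment(st, mod.mesh, wound, 10.0)
    b = wound.exterior
    cent = mod.mesh.element_centroids()
    import shapely

    pts = shapely.points(cent[:, 0], cent[:, 1])
    dist = shapely.distance(b, pts)
    far_sel = (dist > 25.0) & ~shapely.contains(wound, pts)
    # compare near-annulus alignment against the far field
    far_d1 = st.dir1[far_sel & ~st.degenerate]
    arc = shapely.line_locate_point(b, pts[far_sel & ~st.degenerate])
    q = shapely.get_coordinates(shapely.line_interpolate_point(b, arc))
    radial = cent[far_sel & ~st.degenerate, :2] - q
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    tang = np.column_stack([-radial[:, 1], radial[:, 0]])
    far = np.mean(np.einsum("ij,ij->i", far_d1[:, :2], tang) ** 2)
    assert near > far


def test_compression_specs_validated():
    with pytest.raises(ValueError):
        pm.CompressionSpec(plate_gap=0.0)
    with pytest.raises(ValueError, match="frictionless"):
        pm.CompressionSpec(plate_gap=1.0, friction=0.3)


def test_compression_volume_conserved(compression_results):
    for res in compression_results:
        assert abs(res.volume - res.volume_initial) / res.volume_initial < 0.01


def test_compression_stress_increases_as_gap_closes(compression_results):
    means = [np.mean(r.stress.sigma1[r.contact_free])
             for r in compression_results]
    assert means[0] < means[1] < means[2]
    pressures = [r.pressure for r in compression_results]
    assert pressures[0] < pressures[1] < pressures[2]


def test_compression_wide_gap_is_unconfined():
    mat = pm.MaterialParams()
    cap = pm.make_pressurized_cap(radius=15.0, height=6.0, mesh_h=2.5)
    mask = np.zeros((cap.n_vertices, 3), bool)
    mask[cap.is_outer_vertex, :] = True
    loads = pm.LoadCase(np.full(cap.n_elements, mat.turgor_P), mask,
                        cap.vertices.copy())
    res = pm.compress(pm.Model(cap, mat, loads),
                      pm.CompressionSpec(plate_gap=100.0))
    assert res.pressure == pytest.approx(mat.turgor_P)
    assert res.volume == pytest.approx(res.volume_initial)
    assert res.contact_free.all()


def test_stomata_bump_stress_is_circumferential(bump_solution):
    """Tension over an elevated bump: sigma1 wraps the bump ring."""
    dome, st = bump_solution
    ring = Polygon([(8 * np.cos(a), 8 * np.sin(a))
                    for a in np.linspace(0, 2 * np.pi, 64)])
    score = pm.circumferential_alignment(st, dome, ring, annulus_width=8.0)
    assert score > 0.7
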