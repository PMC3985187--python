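"""Element-level mechanics: kinematics, constitutive law, consistency.

The load-bearing checks are the finite-difference oracles: the 2nd
Piola-Kirchhoff stress must be the exact gradient of the energy
density, the assembled internal force the exact gradient of the total
elastic energy, and the fiber term must deliver the calibrated
along:cross stiffness ratio.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pavemech as pm
from pavemech.fem import FemSystem


def test_strain_identity_is_zero():
    assert np.allclose(pm.strain(np.eye(2)), 0.0)
    assert np.allclose(pm.strain(np.eye(3)[:, :2]), 0.0)


def test_strain_uniaxial_closed_form():
    F = np.diag([1.1, 1.0])
    e = pm.strain(F)
    assert e[0, 0] == pytest.approx((1.1**2 - 1) / 2)  # 0.105
    assert e[1, 1] == pytest.approx(0.0)


def test_strain_simple_shear_by_hand():
    F = np.array([[1.0, 0.2], [0.0, 1.0]])
    e = pm.strain(F)
    assert np.allclose(e, [[0.0, 0.1], [0.1, 0.02]])


def test_strain_rejects_nonfinite():
    with pytest.raises(ValueError):
        pm.strain(np.array([[np.nan, 0], [0, 1]]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_strain_symmetric_for_random_gradients(seed):
    rng = np.random.default_rng(seed)
    F = np.eye(2) + 0.3 * rng.normal(size=(2, 2))
    if np.linalg.det(F) <= 0.05:
        return
    e = pm.strain(F)
    assert np.allclose(e, e.T)


def test_svk_zero_strain_zero_energy():
    mat = pm.MaterialParams()
    W, S = pm.svk_energy(np.zeros((2, 2)), mat)
    assert W == 0.0 and np.allclose(S, 0.0)


def test_svk_stress_is_energy_gradient():
    """Central finite differences on random small strains."""
    mat = pm.MaterialParams()
    rng = np.random.default_rng(0)
    h = 1e-7
    for _ in range(10):
        e = 0.05 * rng.normal(size=(2, 2))
        e = 0.5 * (e + e.T)
        _, S = pm.svk_energy(e, mat)
        for i in range(2):
            for j in range(2):
                de = np.zeros((2, 2))
                de[i, j] += 0.5 * h
                de[j, i] += 0.5 * h
                Wp, _ = pm.svk_energy(e + de, mat)
                Wm, _ = pm.svk_energy(e - de, mat)
                fd = (Wp - Wm) / (2 * h)
                ref = S[i, j] if i == j else 0.5 * (S[i, j] + S[j, i])
                assert fd == pytest.approx(ref, rel=1e-5, abs=1e-8)


def test_svk_equibiaxial_closed_form():
    mat = pm.MaterialParams()
    lam, mu = mat.lame_plane_stress()
    e = 0.01 * np.eye(2)
    _, S = pm.svk_energy(e, mat)
    assert S[0, 0] == pytest.approx((2 * lam + 2 * mu) * 0.01)
    assert S[0, 0] == pytest.approx(S[1, 1])
    assert S[0, 1] == pytest.approx(0.0)


def test_fiber_energy_orthogonal_strain_is_zero():
    mat = pm.MaterialParams()
    e = np.array([[0.0, 0.0], [0.0, 0.05]])  # strain only across the fiber
    W, S = pm.fiber_energy(e, np.array([1.0, 0.0]), mat)
    assert W == 0.0 and np.allclose(S, 0.0)


def test_fiber_ratio_one_reduces_to_isotropic():
    mat = pm.MaterialParams(fiber_ratio=1.0)
    e = np.array([[0.03, 0.01], [0.01, -0.02]])
    W, S = pm.fiber_energy(e, np.array([1.0, 0.0]), mat)
    assert W == 0.0 and np.allclose(S, 0.0)


def test_fiber_stiffness_ratio_is_five():
    """FD second derivative of total W along vs across the fiber."""
    mat = pm.MaterialParams()  # fiber_ratio 5
    a = np.array([1.0, 0.0])
    h = 1e-5

    def total_W(e):
        Wm, _ = pm.svk_energy(e, mat)
        Wf, _ = pm.fiber_energy(e, a, mat)
        return Wm + Wf

    def second_derivative(direction):
        e = np.zeros((2, 2))
        de = np.zeros((2, 2))
        de[direction, direction] = h
        return (total_W(e + de) - 2 * total_W(e) + total_W(e - de)) / h**2

    along = second_derivative(0)
    across = second_derivative(1)
    assert along / across == pytest.approx(5.0, rel=1e-4)


def test_fiber_nonunit_direction_normalized_with_warning():
    mat = pm.MaterialParams()
    e = 0.02 * np.eye(2)
    with pytest.warns(UserWarning, match="normaliz"):
        W2, _ = pm.fiber_energy(e, np.array([2.0, 0.0]), mat)
    W1, _ = pm.fiber_energy(e, np.array([1.0, 0.0]), mat)
    assert W2 == pytest.approx(W1)


@pytest.fixture(scope="module")
def random_patch():
    """Perturbed sphere patch with fibers and beams, plus a random state."""
    rng = np.random.default_rng(3)
    mesh = pm.make_sphere(5.0, refine=1)
    fd = rng.normal(size=(mesh.n_elements, 3))
    p = mesh.vertices[mesh.triangles]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    n /= np.linalg.norm(n, axis=1)[:, None]
    fd -= np.einsum("ij,ij->i", fd, n)[:, None] * n
    mesh.fiber_dir = fd / np.linalg.norm(fd, axis=1)[:, None]
    mesh.beams = mesh.triangles[:12, :2].copy()
    mesh.beam_modulus = np.full(12, 40.0)
    mesh.beam_thickness = np.full(12, 0.2)
    mesh.beam_scale = np.ones(12)
    x = mesh.vertices + 0.01 * rng.normal(size=mesh.vertices.shape)
    return mesh, x


def test_internal_force_is_energy_gradient(random_patch):
    mesh, x = random_patch
    fem = FemSystem(mesh, pm.MaterialParams())
    f = fem.internal_force(x).ravel()
    rng = np.random.default_rng(1)
    h = 1e-6
    for k in rng.choice(3 * len(x), 30, replace=False):
        xp, xm = x.ravel().copy(), x.ravel().copy()
        xp[k] += h
        xm[k] -= h
        fd = (fem.elastic_energy(xp.reshape(-1, 3))
              - fem.elastic_energy(xm.reshape(-1, 3))) / (2 * h)
        assert fd == pytest.approx(f[k], rel=1e-5, abs=1e-7)


def test_stiffness_is_force_jacobian(random_patch):
    mesh, x = random_patch
    fem = FemSystem(mesh, pm.MaterialParams())
    K = fem.stiffness_blocks(x).toarray()
    assert np.abs(K - K.T).max() < 1e-10 * np.abs(K).max()
    rng = np.random.default_rng(2)
    h = 1e-6
    scale = np.abs(K).max()
    for k in rng.choice(3 * len(x), 8, replace=False):
        xp, xm = x.ravel().copy(), x.ravel().copy()
        xp[k] += h
        xm[k] -= h
        col = (fem.internal_force(xp.reshape(-1, 3))
               - fem.internal_force(xm.reshape(-1, 3))).ravel() / (2 * h)
        assert np.abs(col - K[:, k]).max() < 1e-5 * scale


def test_pressure_stiffness_is_load_jacobian(random_patch):
    mesh, x = random_patch
    fem = FemSystem(mesh, pm.MaterialParams())
    pres = np.full(mesh.n_elements, 0.2)
    Kp = fem.pressure_stiffness(x, pres).toarray()
    rng = np.random.default_rng(4)
    h = 1e-6
    scale = max(np.abs(Kp).max(), 1e-12)
    for k in rng.choice(3 * len(x), 8, replace=False):
        xp, xm = x.ravel().copy(), x.ravel().copy()
        xp[k] += h
        xm[k] -= h
        col = (fem.pressure_force(xp.reshape(-1, 3), pres)
               - fem.pressure_force(xm.reshape(-1, 3), pres)).ravel() / (2 * h)
        assert np.abs(col - Kp[:, k]).max() < 1e-5 * scale


def test_zero_loads_zero_displacement():
    mat = pm.MaterialParams(turgor_P=0.0, boundary_expansion=0.0)
    square = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
    cx = pm.build_cell_complex([square])
    mesh = pm.add_anticlinal_beams(pm.mesh_surface(cx, target_h=2.0), mat)
    loads = pm.apply_loads_and_bcs(mesh, mat)
    assert np.all(loads.pressure == 0.0)
    disp = pm.solve_equilibrium(mesh, mat, loads)
    assert disp.converged and disp.n_iter <= 1
    assert np.abs(disp.u).max() < 1e-10


def test_outer_expansion_prescribes_radial_positions():
    mat = pm.MaterialParams(boundary_expansion=0.01)
    square = np.array([[-10.0, -10.0], [10.0, -10.0], [10.0, 10.0], [-10.0, 10.0]])
    cx = pm.build_cell_complex([square])
    mesh = pm.mesh_surface(cx, target_h=2.0)
    loads = pm.apply_loads_and_bcs(mesh, mat)
    outer = mesh.is_outer_vertex
    assert np.all(loads.fixed_mask[outer])
    # vertex at (10, 0): expansion about the centroid (origin) -> (10.1, 0)
    k = np.argmin(np.linalg.norm(mesh.vertices[:, :2] - [10, 0], axis=1))
    assert np.allclose(loads.fixed_target[k, :2], [10.1, 0.0], atol=1e-9)
    # every wall vertex carries a z-constraint
    assert np.all(loads.fixed_mask[mesh.is_wall_vertex, 2])


def test_frame_invariance_at_37_degrees(small_template):
    """Rigid rotation of the template rotates d1 and leaves sigma alone."""
    base = small_template
    ang = np.radians(37.0)
    R = np.array([[np.cos(ang), -np.sin(ang), 0],
                  [np.sin(ang), np.cos(ang), 0],
                  [0, 0, 1.0]])
    mesh_r = base.mesh.copy()
    mesh_r.vertices = base.mesh.vertices @ R.T
    loads_r = pm.LoadCase(
        pressure=base.loads.pressure.copy(),
        fixed_mask=base.loads.fixed_mask.copy(),
        fixed_target=base.loads.fixed_target @ R.T,
    )
    disp_r = pm.solve_equilibrium(mesh_r, base.material, loads_r, n_increments=3)
    st_r = pm.principal_stress(disp_r, mesh_r, base.material)
    assert np.allclose(st_r.sigma1, base.stress.sigma1, rtol=1e-4, atol=1e-6)
    assert np.allclose(st_r.sigma2, base.stress.sigma2, rtol=1e-4, atol=1e-6)
    d1_rot = base.stress.dir1 @ R.T
    align = np.abs(np.einsum("ij,ij->i", d1_rot, st_r.dir1))
    keep = ~(st_r.degenerate | base.stress.degenerate)
    assert np.median(align[keep]) > 1 - 1e-6
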