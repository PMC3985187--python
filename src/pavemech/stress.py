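"""Principal membrane stresses and the stress -> fiber feedback loop.

The observable validated throughout is the per-element Cauchy membrane
stress: second Piola-Kirchhoff stress pushed forward to the deformed
tangent plane and normalized by the area change (wall thickness taken as
unchanged), eigen-decomposed into tension-positive principal values
sigma1 >= sigma2 with orthogonal tangent-plane directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fem import Displacements, FemSystem, LoadCase, solve_equilibrium
from .materials import MaterialParams
from .meshing import SurfaceMesh


@dataclass
class StressField:
    """Per-element principal membrane stresses (MPa, tension positive)."""

    sigma1: np.ndarray  # (m,)
    sigma2: np.ndarray  # (m,)
    dir1: np.ndarray  # (m, 3) unit, current tangent plane
    dir2: np.ndarray  # (m, 3)
    degenerate: np.ndarray  # (m,) bool, |s1 - s2| below tolerance

    def __len__(self) -> int:
        return len(self.sigma1)


def principal_stress(
    displacements: Displacements,
    mesh: SurfaceMesh,
    material: MaterialParams,
    system: FemSystem | None = None,
    degeneracy_tol: float = 1e-6,
) -> StressField:
    """Cauchy membrane principal stresses from a converged solution."""
    if not displacements.converged:
        raise ValueError("principal_stress requires a converged solution")
    fem = system if system is not None else FemSystem(mesh, material)
    x = mesh.vertices + displacements.u
    _, F, _, S, _ = fem._membrane_state(x)

    f0, f1 = F[:, :, 0], F[:, :, 1]
    e1 = f0 / np.linalg.norm(f0, axis=1)[:, None]
    nrm = np.cross(f0, f1)
    nrm = nrm / np.linalg.norm(nrm, axis=1)[:, None]
    e2 = np.cross(nrm, e1)
    F2 = np.empty((len(F), 2, 2))
    F2[:, 0, 0] = np.einsum("ij,ij->i", e1, f0)
    F2[:, 0, 1] = np.einsum("ij,ij->i", e1, f1)
    F2[:, 1, 0] = np.einsum("ij,ij->i", e2, f0)
    F2[:, 1, 1] = np.einsum("ij,ij->i", e2, f1)
    J = np.linalg.det(F2)
    cauchy = np.einsum("eab,ebc,edc->ead", F2, S, F2) / J[:, None, None]

    a, b, c = cauchy[:, 0, 0], cauchy[:, 1, 1], cauchy[:, 0, 1]
    avg = 0.5 * (a + b)
    rad = np.sqrt((0.5 * (a - b)) ** 2 + c**2)
    s1, s2 = avg + rad, avg - rad
    theta = 0.5 * np.arctan2(2.0 * c, a - b)
    d1 = np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2
    d2 = -np.sin(theta)[:, None] * e1 + np.cos(theta)[:, None] * e2
    degenerate = (s1 - s2) < degeneracy_tol * np.maximum(np.abs(s1), 1e-12)
    return StressField(sigma1=s1, sigma2=s2, dir1=d1, dir2=d2, degenerate=degenerate)


def _pull_back_directions(
    fem: FemSystem, x: np.ndarray, d1: np.ndarray
) -> np.ndarray:
    """Map current principal directions to unit reference tangent vectors."""
    _, F, _, _, _ = fem._membrane_state(x)
    C = np.einsum("eia,eib->eab", F, F)
    rhs = np.einsum("eia,ei->ea", F, d1)
    a_loc = np.linalg.solve(C, rhs[..., None])[..., 0]
    n = np.linalg.norm(a_loc, axis=1)
    n = np.where(n < 1e-12, 1.0, n)
    a_loc = a_loc / n[:, None]
    return a_loc[:, 0:1] * fem.E1 + a_loc[:, 1:2] * fem.E2


def _axial_angle_change(a_old: np.ndarray, a_new: np.ndarray) -> np.ndarray:
    """Headless (nematic) angle between direction fields, degrees."""
    dot = np.abs(np.einsum("ij,ij->i", a_old, a_new))
    return np.degrees(np.arccos(np.clip(dot, -1.0, 1.0)))


@dataclass
class FeedbackResult:
    """Outcome of the stress/fiber alignment iteration."""

    mesh: SurfaceMesh  # fibers updated in place on a copy
    stress: StressField
    stress_baseline: StressField
    displacements: Displacements
    cos_map: np.ndarray  # |cos| between baseline and feedback sigma1 directions
    median_changes: list[float] = field(default_factory=list)
    converged: bool = True


def feedback_align(
    mesh: SurfaceMesh,
    material: MaterialParams,
    loads: LoadCase,
    n_steps: int = 15,
    tol_deg: float = 1.0,
    solver_kwargs: dict | None = None,
) -> FeedbackResult:
    """Iterate {solve, align fibers with the maximal-stress direction}.

    Starts from the isotropic (fiber-free) solution, then repeatedly
    re-solves with the material anisotropy axis set to the previous
    step's first-principal-stress direction, until the median angular
    fiber change drops below ``tol_deg`` (or ``n_steps`` is reached).
    Degenerate (near-isotropic stress) elements keep their previous
    fiber to avoid noise-driven flips.  Returns the per-element
    |cos(angle)| map comparing feedback and isotropic sigma1 directions.
    """
    kw = dict(solver_kwargs or {})
    iso_mesh = mesh.copy()
    iso_mesh.fiber_dir = None
    sys_iso = FemSystem(iso_mesh, material)
    disp0 = solve_equilibrium(iso_mesh, material, loads, system=sys_iso, **kw)
    stress0 = principal_stress(disp0, iso_mesh, material, system=sys_iso)

    work = mesh.copy()
    x = mesh.vertices + disp0.u
    sys_fb = FemSystem(work, material)
    fiber = _pull_back_directions(sys_fb, x, stress0.dir1)
    median_changes: list[float] = []
    disp, stress = disp0, stress0
    best = (np.inf, fiber, disp0, stress0)
    converged = False
    for _ in range(n_steps):
        sys_fb.set_fiber(fiber)
        work.fiber_dir = fiber
        disp = solve_equilibrium(
            work, material, loads, system=sys_fb, x0=work.vertices + disp.u, **kw
        )
        stress = principal_stress(disp, work, material, system=sys_fb)
        x = work.vertices + disp.u
        new_fiber = _pull_back_directions(sys_fb, x, stress.dir1)
        keep = stress.degenerate
        new_fiber[keep] = fiber[keep]
        change = _axial_angle_change(fiber, new_fiber)
        med = float(np.median(change)) if len(change) else 0.0
        median_changes.append(med)
        fiber = new_fiber
        if med < best[0]:
            best = (med, fiber, disp, stress)
        if med < tol_deg:
            converged = True
            break
        if len(median_changes) >= 5 and all(
            median_changes[-k] >= median_changes[-k - 1] - 1e-9 for k in range(1, 5)
        ):
            warnings.warn(
                "fiber feedback oscillating; returning best iterate", stacklevel=2
            )
            _, fiber, disp, stress = best
            break
    work.fiber_dir = fiber
    cos_map = np.abs(np.einsum("ij,ij->i", stress0.dir1, stress.dir1))
    return FeedbackResult(
        mesh=work,
        stress=stress,
        stress_baseline=stress0,
        displacements=disp,
        cos_map=cos_map,
        median_changes=median_changes,
        converged=converged,
    )
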