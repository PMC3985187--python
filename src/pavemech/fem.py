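"""Nonlinear membrane finite elements for the turgid cell wall.

Constant-strain triangles in a total-Lagrangian setting: Green-Lagrange
strain from the tangent-plane deformation gradient, Saint
Venant-Kirchhoff matrix energy plus a quadratic transversely isotropic
fiber invariant, axial (Green-strain) bars for the anticlinal walls, and
turgor as a follower pressure normal to the deformed surface.
Equilibrium is found by Newton-Raphson with backtracking line search and
incremental loading; the follower-pressure load stiffness is assembled
exactly (unsymmetric).

Unit system: micrometre / MPa, hence forces in microNewton.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import MaterialParams
from .meshing import SurfaceMesh

_I2 = np.eye(2)
# maps element columns g = [x1-x0, x2-x0] onto the 3 nodes
_T = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the residual-norm trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def strain(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain 0.5 (F^T F - I) of a deformation gradient.

    ``F`` may be 2x2 (in-plane) or 3x2 (tangent-plane columns in 3D), or
    a stack of either.
    """
    F = np.asarray(F, float)
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite deformation gradient")
    C = np.swapaxes(F, -1, -2) @ F
    return 0.5 * (C - np.eye(C.shape[-1]))


def svk_energy(
    eps: np.ndarray, material: MaterialParams
) -> tuple[np.ndarray, np.ndarray]:
    """SVK energy density W and 2nd Piola-Kirchhoff stress S (plane stress).

    W = 0.5 lambda tr(e)^2 + mu tr(e^2);  S = lambda tr(e) I + 2 mu e.
    """
    lam, mu = material.lame_plane_stress()
    eps = np.asarray(eps, float)
    tr = np.trace(eps, axis1=-2, axis2=-1)
    W = 0.5 * lam * tr**2 + mu * np.einsum("...ij,...ij->...", eps, eps)
    S = lam * tr[..., None, None] * np.eye(eps.shape[-1]) + 2.0 * mu * eps
    return W, S


def fiber_energy(
    eps: np.ndarray, a: np.ndarray, material: MaterialParams
) -> tuple[np.ndarray, np.ndarray]:
    """Transversely isotropic augmentation W_f = 0.5 zeta (a.e.a)^2.

    ``a`` is the unit fiber direction in the same frame as ``eps``;
    non-unit input is normalized with a warning.  Returns (W_f, S_f)
    with S_f = zeta (a.e.a) a x a.
    """
    a = np.asarray(a, float)
    norms = np.linalg.norm(a, axis=-1, keepdims=True)
    if not np.allclose(norms, 1.0, atol=1e-8):
        import warnings

        warnings.warn("fiber direction not unit length; normalizing", stacklevel=2)
        a = a / norms
    zeta = material.fiber_zeta
    aea = np.einsum("...i,...ij,...j->...", a, eps, a)
    W = 0.5 * zeta * aea**2
    S = zeta * aea[..., None, None] * np.einsum("...i,...j->...ij", a, a)
    return W, S


@dataclass
class LoadCase:
    """Loads and constraints: per-element pressure and prescribed DOFs."""

    pressure: np.ndarray  # (m,) MPa
    fixed_mask: np.ndarray  # (n, 3) bool, True = DOF prescribed
    fixed_target: np.ndarray  # (n, 3) prescribed positions at full load

    def copy(self) -> "LoadCase":
        return LoadCase(
            self.pressure.copy(), self.fixed_mask.copy(), self.fixed_target.copy()
        )


@dataclass
class Displacements:
    """Solution record of a Newton solve."""

    u: np.ndarray  # (n, 3) displacement, micrometre
    converged: bool
    residual_norm: float
    n_iter: int
    trace: list[float] = field(default_factory=list)


def apply_loads_and_bcs(mesh: SurfaceMesh, material: MaterialParams) -> LoadCase:
    """Standard pavement-cell loading.

    Outer-boundary vertices: prescribed in-plane radial expansion by
    ``boundary_expansion`` about the template centroid, z fixed.  All
    cell-boundary (anticlinal projection) vertices: z-displacement fixed.
    Uniform follower pressure ``turgor_P`` on every element.
    """
    n = mesh.n_vertices
    fixed_mask = np.zeros((n, 3), bool)
    fixed_target = mesh.vertices.copy()

    wall = mesh.is_wall_vertex
    outer = mesh.is_outer_vertex
    fixed_mask[wall, 2] = True  # z restriction along anticlinal walls
    if outer.any():
        centroid = mesh.vertices[outer, :2].mean(axis=0)
        fixed_mask[outer, :] = True
        fixed_target[outer, :2] = centroid + (1.0 + material.boundary_expansion) * (
            mesh.vertices[outer, :2] - centroid
        )
        chain = _boundary_chain_closed(mesh)
        if not chain:
            raise ValueError("outer boundary is not closed")
    pressure = np.full(mesh.n_elements, material.turgor_P)
    return LoadCase(pressure=pressure, fixed_mask=fixed_mask, fixed_target=fixed_target)


def _boundary_chain_closed(mesh: SurfaceMesh) -> bool:
    """True if the outer-boundary edge set forms closed loops."""
    deg: dict[int, int] = {}
    for (a, b), cells in zip(mesh.boundary_edges, mesh.boundary_edge_cells):
        if len(cells) == 1:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
    if not deg:
        return True  # closed surface, no outer boundary
    return all(v == 2 for v in deg.values())


@dataclass
class Model:
    """A solvable bundle: mesh + material + loads."""

    mesh: SurfaceMesh
    material: MaterialParams
    loads: LoadCase

    def copy(self) -> "Model":
        return Model(self.mesh.copy(), self.material, self.loads.copy())


def build_model(mesh: SurfaceMesh, material: MaterialParams) -> Model:
    return Model(mesh, material, apply_loads_and_bcs(mesh, material))


# ---------------------------------------------------------------------------
# element precomputation and assembly
# ---------------------------------------------------------------------------


class FemSystem:
    """Precomputed element data + assembly of residual and tangent."""

    def __init__(self, mesh: SurfaceMesh, material: MaterialParams):
        self.mesh = mesh
        self.material = material
        X = mesh.vertices
        tri = mesh.triangles
        g1 = X[tri[:, 1]] - X[tri[:, 0]]
        g2 = X[tri[:, 2]] - X[tri[:, 0]]
        nrm = np.cross(g1, g2)
        n_len = np.linalg.norm(nrm, axis=1)
        if np.any(n_len <= 0):
            raise ValueError("degenerate reference triangle")
        self.normal0 = nrm / n_len[:, None]
        E1 = g1 / np.linalg.norm(g1, axis=1)[:, None]
        E2 = np.cross(self.normal0, E1)
        self.E1, self.E2 = E1, E2
        # reference in-plane edge matrix and its inverse
        Ghat = np.empty((len(tri), 2, 2))
        Ghat[:, 0, 0] = np.einsum("ij,ij->i", g1, E1)
        Ghat[:, 0, 1] = np.einsum("ij,ij->i", g2, E1)
        Ghat[:, 1, 0] = np.einsum("ij,ij->i", g1, E2)
        Ghat[:, 1, 1] = np.einsum("ij,ij->i", g2, E2)
        self.D = np.linalg.inv(Ghat)
        self.area0 = 0.5 * np.abs(np.linalg.det(Ghat))
        self.vol0 = self.area0 * mesh.thickness

        lam, mu = material.lame_plane_stress()
        s = mesh.stiffness_scale
        self.lam_e = lam * s
        self.mu_e = mu * s
        self.zeta_e = material.fiber_zeta * s
        self.set_fiber(mesh.fiber_dir)

        # beams
        self.beams = mesh.beams
        if len(self.beams):
            d0 = X[self.beams[:, 1]] - X[self.beams[:, 0]]
            self.beam_L0 = np.linalg.norm(d0, axis=1)
            area = mesh.beam_thickness * material.wall_thickness
            self.beam_EA = mesh.beam_modulus * mesh.beam_scale * area
        else:
            self.beam_L0 = np.zeros(0)
            self.beam_EA = np.zeros(0)

        self.ndof = 3 * mesh.n_vertices
        self._tri_rows, self._tri_cols = self._block_indices(tri, 3)
        if len(self.beams):
            self._beam_rows, self._beam_cols = self._block_indices(self.beams, 2)

    @staticmethod
    def _block_indices(conn: np.ndarray, nn: int) -> tuple[np.ndarray, np.ndarray]:
        dof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(
            len(conn), 3 * nn
        )
        rows = np.repeat(dof, 3 * nn, axis=1).ravel()
        cols = np.tile(dof, (1, 3 * nn)).ravel()
        return rows, cols

    def set_fiber(self, fiber_dir: np.ndarray | None) -> None:
        """Project 3D fiber directions into the reference element frames."""
        if fiber_dir is None:
            self.a_loc = None
            return
        a1 = np.einsum("ij,ij->i", fiber_dir, self.E1)
        a2 = np.einsum("ij,ij->i", fiber_dir, self.E2)
        a = np.column_stack([a1, a2])
        n = np.linalg.norm(a, axis=1)
        n = np.where(n < 1e-12, 1.0, n)
        self.a_loc = a / n[:, None]

    # -- membrane ----------------------------------------------------------

    def _membrane_state(self, x: np.ndarray):
        tri = self.mesh.triangles
        g = np.stack([x[tri[:, 1]] - x[tri[:, 0]], x[tri[:, 2]] - x[tri[:, 0]]], axis=2)
        F = g @ self.D  # (m,3,2)
        C = np.einsum("eia,eib->eab", F, F)
        E = 0.5 * (C - _I2)
        trE = E[:, 0, 0] + E[:, 1, 1]
        S = self.lam_e[:, None, None] * trE[:, None, None] * _I2 + 2.0 * self.mu_e[
            :, None, None
        ] * E
        W = 0.5 * self.lam_e * trE**2 + self.mu_e * np.einsum("eab,eab->e", E, E)
        if self.a_loc is not None and np.any(self.zeta_e != 0):
            a = self.a_loc
            aea = np.einsum("ea,eab,eb->e", a, E, a)
            S = S + (self.zeta_e * aea)[:, None, None] * np.einsum(
                "ea,eb->eab", a, a
            )
            W = W + 0.5 * self.zeta_e * aea**2
        return g, F, E, S, W

    def elastic_energy(self, x: np.ndarray) -> float:
        _, _, _, _, W = self._membrane_state(x)
        total = float(np.sum(self.vol0 * W))
        if len(self.beams):
            d = x[self.beams[:, 1]] - x[self.beams[:, 0]]
            L2 = np.einsum("ij,ij->i", d, d)
            eps = (L2 - self.beam_L0**2) / (2.0 * self.beam_L0**2)
            total += float(np.sum(0.5 * self.beam_EA * self.beam_L0 * eps**2))
        return total

    def internal_force(self, x: np.ndarray) -> np.ndarray:
        tri = self.mesh.triangles
        _, F, _, S, _ = self._membrane_state(x)
        # dW/dg = F S D^T per element, volume-weighted
        fg = self.vol0[:, None, None] * np.einsum(
            "eia,eab,ecb->eic", F, S, self.D
        )  # (m,3,2)
        fnod = np.einsum("na,eia->eni", _T, fg)  # (m, 3 nodes, 3)
        f = np.zeros((len(x), 3))
        np.add.at(f, tri, fnod)
        if len(self.beams):
            d = x[self.beams[:, 1]] - x[self.beams[:, 0]]
            L2 = np.einsum("ij,ij->i", d, d)
            eps = (L2 - self.beam_L0**2) / (2.0 * self.beam_L0**2)
            fb = (self.beam_EA * eps / self.beam_L0)[:, None] * d
            np.add.at(f, self.beams[:, 1], fb)
            np.add.at(f, self.beams[:, 0], -fb)
        return f

    def stiffness_blocks(self, x: np.ndarray) -> sp.coo_matrix:
        """Tangent of the internal force (symmetric part)."""
        m = self.mesh.n_elements
        _, F, E, S, _ = self._membrane_state(x)
        D = self.D
        # geometric part: delta_ij (D S D^T)_{mu alpha}
        DSDt = np.einsum("ema,eab,enb->emn", D, S, D)  # (m,2,2) indices (mu, alpha)
        geo = np.einsum("emn,ij->einjm", DSDt, np.eye(3))  # (e,i,alpha,j,mu)
        # material tangent C_{b c r s}
        Cm = np.zeros((m, 2, 2, 2, 2))
        for b in range(2):
            for c in range(2):
                for r in range(2):
                    for s_ in range(2):
                        Cm[:, b, c, r, s_] = (
                            self.lam_e * _I2[b, c] * _I2[r, s_]
                            + self.mu_e
                            * (_I2[b, r] * _I2[c, s_] + _I2[b, s_] * _I2[c, r])
                        )
        if self.a_loc is not None and np.any(self.zeta_e != 0):
            a = self.a_loc
            Cm += self.zeta_e[:, None, None, None, None] * np.einsum(
                "eb,ec,er,es->ebcrs", a, a, a, a
            )
        # B_{rs, j mu} = 0.5 (D_{mu r} F_{j s} + F_{j r} D_{mu s})
        B = 0.5 * (
            np.einsum("emr,ejs->ersjm", D, F) + np.einsum("ejr,ems->ersjm", F, D)
        )
        mat = np.einsum("eib,ebcrs,ersjm,eac->eiajm", F, Cm, B, D, optimize=True)
        Hg = self.vol0[:, None, None, None, None] * (geo + mat)  # (e,i,al,j,mu)
        Hn = np.einsum("na,pm,eiajm->enipj", _T, _T, Hg)  # (e, n,i, p,j)
        vals = Hn.reshape(m, 9, 9).ravel()
        K = sp.coo_matrix(
            (vals, (self._tri_rows, self._tri_cols)), shape=(self.ndof, self.ndof)
        )
        if len(self.beams):
            d = x[self.beams[:, 1]] - x[self.beams[:, 0]]
            L2 = np.einsum("ij,ij->i", d, d)
            L0 = self.beam_L0
            eps = (L2 - L0**2) / (2.0 * L0**2)
            k1 = (self.beam_EA / L0**3)[:, None, None] * np.einsum(
                "ei,ej->eij", d, d
            )
            k2 = (self.beam_EA * eps / L0)[:, None, None] * np.eye(3)
            kb = k1 + k2  # (k,3,3) block for (b1,b1); signs via [-1, 1] pattern
            sgn = np.array([[1.0, -1.0], [-1.0, 1.0]])
            blocks = np.einsum("ab,eij->eaibj", sgn, kb).reshape(len(d), 6, 6)
            Kb = sp.coo_matrix(
                (blocks.ravel(), (self._beam_rows, self._beam_cols)),
                shape=(self.ndof, self.ndof),
            )
            K = (K + Kb).tocoo()
        return K

    # -- follower pressure -------------------------------------------------

    def pressure_force(self, x: np.ndarray, pressure: np.ndarray) -> np.ndarray:
        tri = self.mesh.triangles
        u = x[tri[:, 1]] - x[tri[:, 0]]
        v = x[tri[:, 2]] - x[tri[:, 0]]
        w = np.cross(u, v)
        fn = (pressure / 6.0)[:, None] * w
        f = np.zeros((len(x), 3))
        for k in range(3):
            np.add.at(f, tri[:, k], fn)
        return f

    def pressure_stiffness(self, x: np.ndarray, pressure: np.ndarray) -> sp.coo_matrix:
        """Exact (unsymmetric) tangent of the follower pressure force."""
        tri = self.mesh.triangles
        u = x[tri[:, 1]] - x[tri[:, 0]]
        v = x[tri[:, 2]] - x[tri[:, 0]]

        def skew(a: np.ndarray) -> np.ndarray:
            s = np.zeros((len(a), 3, 3))
            s[:, 0, 1], s[:, 0, 2] = -a[:, 2], a[:, 1]
            s[:, 1, 0], s[:, 1, 2] = a[:, 2], -a[:, 0]
            s[:, 2, 0], s[:, 2, 1] = -a[:, 1], a[:, 0]
            return s

        su, sv = skew(u), skew(v)
        p6 = (pressure / 6.0)[:, None, None]
        dfdx = np.stack([p6 * (sv - su), -p6 * sv, p6 * su], axis=1)  # (m, 3src, 3, 3)
        # every node row gets the same three source blocks
        m = len(tri)
        blocks = np.broadcast_to(dfdx[:, None], (m, 3, 3, 3, 3))  # (m, row, src, 3, 3)
        vals = np.transpose(blocks, (0, 1, 3, 2, 4)).reshape(m, 9, 9).ravel()
        return sp.coo_matrix(
            (vals, (self._tri_rows, self._tri_cols)), shape=(self.ndof, self.ndof)
        )

    def enclosed_volume(self, x: np.ndarray) -> float:
        """Volume via z-flux; exact for surfaces closed by a z=const base."""
        tri = self.mesh.triangles
        p = x[tri]
        w = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return float(np.sum(w[:, 2] / 2.0 * p[:, :, 2].mean(axis=1)))


def solve_equilibrium(
    mesh: SurfaceMesh,
    material: MaterialParams,
    loads: LoadCase,
    n_increments: int = 4,
    tol_rel: float = 1e-8,
    tol_abs: float = 1e-10,
    max_iter: int = 200,
    contact_plane: tuple[float, float] | None = None,
    system: FemSystem | None = None,
    x0: np.ndarray | None = None,
) -> Displacements:
    """Newton-Raphson equilibrium under pressure + prescribed displacements.

    ``contact_plane = (z_plate, penalty)`` adds a frictionless rigid
    plane at z = z_plate penalizing vertex penetration from below.
    Raises :class:`ConvergenceError` on failure.
    """
    fem = system if system is not None else FemSystem(mesh, material)
    X0 = mesh.vertices
    x = X0.copy() if x0 is None else x0.copy()
    mask = loads.fixed_mask
    free = ~mask.ravel()
    trace: list[float] = []
    n_it_total = 0

    if not free.any():
        raise ValueError("all degrees of freedom constrained")

    # diagonal regularization scale: flat unstressed membranes have a
    # singular out-of-plane tangent; a tiny diagonal shift stabilizes the
    # iteration matrix without changing the converged solution.
    reg0 = 1e-8 * material.E_matrix * float(np.mean(mesh.thickness))

    factors = np.linspace(1.0 / n_increments, 1.0, n_increments)
    for fac in factors:
        x_presc = X0 + fac * (loads.fixed_target - X0)
        x[mask] = x_presc[mask]
        pres = fac * loads.pressure
        converged = False
        for it in range(max_iter):
            R = fem.internal_force(x) - fem.pressure_force(x, pres)
            if contact_plane is not None:
                zp, kc = contact_plane
                pen = np.maximum(0.0, x[:, 2] - zp)
                R[:, 2] += kc * pen
            r = R.ravel()[free]
            rnorm = float(np.linalg.norm(r))
            trace.append(rnorm)
            fref = float(np.linalg.norm(fem.pressure_force(x, pres))) + float(
                np.linalg.norm(fem.internal_force(x))
            )
            tol = tol_rel * max(fref, 1.0) + tol_abs
            if rnorm < tol:
                converged = True
                n_it_total += it
                break
            K = fem.stiffness_blocks(x) - fem.pressure_stiffness(x, pres)
            if contact_plane is not None:
                zp, kc = contact_plane
                hit = np.where(x[:, 2] > zp)[0]
                if len(hit):
                    idx = 3 * hit + 2
                    Kc = sp.coo_matrix(
                        (np.full(len(idx), kc), (idx, idx)),
                        shape=(fem.ndof, fem.ndof),
                    )
                    K = (K + Kc).tocoo()
            K = K.tocsr()[free][:, free].tocsc()
            reg = reg0 * max(1.0, rnorm)
            K = K + reg * sp.identity(K.shape[0], format="csc")
            try:
                dx = spla.splu(K).solve(-r)
            except RuntimeError as exc:
                raise ConvergenceError(
                    f"singular tangent ({exc}); check constraints for "
                    "rigid-body modes",
                    trace,
                ) from exc
            # backtracking line search on the residual norm
            alpha = 1.0
            x_flat = x.ravel().copy()
            accepted = False
            for _ in range(30):
                x_try = x_flat.copy()
                x_try[free] += alpha * dx
                xt = x_try.reshape(-1, 3)
                Rt = fem.internal_force(xt) - fem.pressure_force(xt, pres)
                if contact_plane is not None:
                    zp, kc = contact_plane
                    Rt[:, 2] += kc * np.maximum(0.0, xt[:, 2] - zp)
                rt = float(np.linalg.norm(Rt.ravel()[free]))
                if np.isfinite(rt) and rt < (1.0 - 1e-4 * alpha) * rnorm:
                    x = xt
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                # accept the smallest step anyway; Newton may still recover
                x_flat[free] += alpha * dx
                x = x_flat.reshape(-1, 3)
        else:
            raise ConvergenceError(
                f"no convergence in {max_iter} iterations at load factor "
                f"{fac:.3f} (residual {trace[-1]:.3e})",
                trace,
            )
        n_it_total += it
    return Displacements(
        u=x - X0,
        converged=True,
        residual_norm=trace[-1] if trace else 0.0,
        n_iter=n_it_total,
        trace=trace,
    )
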