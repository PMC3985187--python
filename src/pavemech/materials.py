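"""Material parameters for the turgid cell-wall model.

The outer (periclinal) wall is modelled as a thin hyperelastic membrane:
an isotropic Saint Venant-Kirchhoff matrix augmented by a transversely
isotropic fiber term representing cellulose microfibrils oriented along a
single preferred direction per element.  Anticlinal walls enter as axial
beam elements along the cell-boundary polylines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class MaterialParams:
    """Wall material and loading constants (units: MPa, micrometre).

    Attributes
    ----------
    E_matrix : float
        Young's modulus of the isotropic wall matrix, MPa.
    nu_matrix : float
        Poisson ratio of the matrix under plane stress.  The membrane
        formulation is ill-conditioned at 0.5, so the default is 0.3.
    fiber_ratio : float
        Ratio of the small-strain constrained-axial stiffness along the
        fiber direction to the matrix value; 1 recovers the isotropic
        material.
    turgor_P : float
        Turgor pressure applied as a follower load on every cell, MPa.
    wall_thickness : float
        Thickness of the periclinal wall, micrometre.
    beam_fraction : float
        Anticlinal beam thickness as a fraction of the wall thickness.
    boundary_expansion : float
        In-plane radial expansion of the outer template boundary
        (tissue tension), as a fraction.
    """

    E_matrix: float = 40.0
    nu_matrix: float = 0.3
    fiber_ratio: float = 5.0
    turgor_P: float = 0.2
    wall_thickness: float = 1.0
    beam_fraction: float = 0.2
    boundary_expansion: float = 0.01

    def __post_init__(self) -> None:
        if self.E_matrix <= 0:
            raise ValueError("E_matrix must be positive")
        if not 0.0 <= self.nu_matrix < 0.5:
            raise ValueError("nu_matrix must be in [0, 0.5)")
        if self.fiber_ratio < 1.0:
            raise ValueError("fiber_ratio must be >= 1")
        if self.turgor_P < 0.0:
            raise ValueError("turgor_P must be >= 0")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")

    def lame_plane_stress(self) -> tuple[float, float]:
        """Plane-stress Lame constants (lambda_ps, mu) in MPa.

        lambda_ps = E nu / (1 - nu^2) is the plane-stress-reduced first
        Lame constant, so a uniaxial stress test of the 2D membrane has
        stiffness exactly E_matrix.
        """
        e, nu = self.E_matrix, self.nu_matrix
        lam = e * nu / (1.0 - nu * nu)
        mu = e / (2.0 * (1.0 + nu))
        return lam, mu

    @property
    def fiber_zeta(self) -> float:
        """Fiber modulus zeta of W_f = 0.5 zeta (a.eps.a)^2, MPa.

        Calibrated so the small-strain constrained-axial stiffness along
        the fiber, d2W/d(eps_aa)^2 = lambda + 2 mu + zeta, equals
        fiber_ratio times the matrix value lambda + 2 mu.
        """
        lam, mu = self.lame_plane_stress()
        return (self.fiber_ratio - 1.0) * (lam + 2.0 * mu)

    @property
    def beam_thickness(self) -> float:
        return self.beam_fraction * self.wall_thickness

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown material keys: {sorted(unknown)}")
        return cls(**d)
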