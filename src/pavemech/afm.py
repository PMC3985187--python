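"""AFM force-curve fitting: Hertz-Sneddon cone and DMT sphere models.

Fits the contact region of indentation force curves (separation nm,
force nN) for an apparent elastic modulus Ea in MPa, with automatic
contact-point detection (piecewise flat-baseline + power-law model,
coarse grid search refined continuously).  Grids of fits assemble into
stiffness maps with per-pixel topography (= contact-point height).

Conventions: the Sneddon cone F = (2/pi) tan(alpha) E/(1-nu^2) delta^2
is fitted on the approach segment; the DMT sphere
F - F_adh = (4/3) E* sqrt(R) (d - d0)^{3/2} on the retract segment,
with the reduced modulus E* = E/(1-nu^2) and Ea = E* (1-nu^2) (so
Ea/E* = 0.75 at nu = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .synthetic import UNIT_NN, ForceCurve


@dataclass
class TipParams:
    """Indenter geometry and sample Poisson ratio."""

    half_angle: float = 18.0  # degrees (cone)
    radius: float = 6.0  # nm (sphere; manufacturer range 2-10)
    poisson: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.half_angle < 90.0:
            raise ValueError("half_angle must be in (0, 90) degrees")
        if self.radius <= 0:
            raise ValueError("tip radius must be positive")


@dataclass
class FitResult:
    """Per-curve fit output."""

    Ea: float  # apparent modulus, MPa
    E_star: float | None  # reduced modulus (DMT), MPa
    F_adh: float  # adhesion force, nN (0 for Hertz)
    contact_point: float  # separation at contact, nm
    r_squared: float
    ok: bool
    message: str = ""


def _power_law_fit(
    s: np.ndarray, f: np.ndarray, exponent: float, contact_offset: float = 0.0
) -> tuple[float, float, float]:
    """Best (coef, contact point s0, SSE) for the piecewise contact law.

    Model: f = 0 for s > s0, f = coef * (s0 - s)^p + contact_offset for
    s <= s0 (flat zero baseline out of contact).  Coarse search over
    sample positions, then continuous refinement.
    """

    def sse_at(s0: float) -> tuple[float, float]:
        contact = s < s0
        m = np.where(contact, np.maximum(s0 - s, 0.0) ** exponent, 0.0)
        g = f - np.where(contact, contact_offset, 0.0)
        mm = float(m @ m)
        if mm <= 0:
            return float(g @ g), 0.0
        coef = float(g @ m) / mm
        return float(g @ g) - coef**2 * mm, coef

    order = np.argsort(-s)  # descending separation
    s_sorted = s[order]
    cands = s_sorted[:: max(1, len(s_sorted) // 128)]
    sse = np.array([sse_at(c)[0] for c in cands])
    k = int(np.argmin(sse))
    lo = cands[min(k + 1, len(cands) - 1)]
    hi = cands[max(k - 1, 0)]
    if hi <= lo:
        lo, hi = lo - 1e-6, hi + 1e-6
    res = minimize_scalar(
        lambda c: sse_at(c)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    s0 = float(res.x)
    best_sse, coef = sse_at(s0)
    return coef, s0, best_sse


def _r_squared(f: np.ndarray, sse: float) -> float:
    tot = float(np.sum((f - f.mean()) ** 2))
    return 1.0 - sse / tot if tot > 0 else 0.0


def fit_hertz_cone(curve: ForceCurve, tip: TipParams) -> FitResult:
    """Least-squares Sneddon-cone fit on the approach segment."""
    s, f = curve.approach()
    if len(s) < 8:
        raise ValueError("approach segment too short")
    fmax = float(np.max(np.abs(f)))
    if fmax <= 0 or np.max(f) < 5.0 * max(np.std(f[: len(f) // 4]), 1e-12):
        raise ValueError("no contact detected on the approach segment")
    coef, s0, sse = _power_law_fit(s, f, exponent=2.0)
    geom = (2.0 / np.pi) * np.tan(np.radians(tip.half_angle)) / (
        1.0 - tip.poisson**2
    ) * UNIT_NN
    Ea = coef / geom
    ok = Ea > 0
    return FitResult(
        Ea=Ea,
        E_star=None,
        F_adh=0.0,
        contact_point=s0,
        r_squared=_r_squared(f, sse),
        ok=ok,
        message="" if ok else "negative fitted modulus",
    )


def fit_dmt_sphere(curve: ForceCurve, tip: TipParams) -> FitResult:
    """DMT sphere fit with adhesion on the retract segment.

    F_adh is read off as minus the minimum retract force; the shifted
    force F + F_adh is then fitted with the 3/2-power contact law.
    """
    if tip.radius is None:
        raise ValueError("tip radius required for the DMT model")
    s, f = curve.retract()
    if len(s) < 8:
        raise ValueError("retract segment missing or too short")
    # adhesion well depth: -min(retract force) as the direct estimate,
    # refined jointly with the contact law inside the contact-point
    # search (the raw minimum is quantized to the separation sampling)
    adh0 = max(0.0, float(-np.min(f)))

    def joint_fit(s0: float) -> tuple[float, float, float]:
        """(SSE, coef, F_adh) for the piecewise model at contact point s0."""
        contact = s < s0
        if contact.sum() < 4:
            return float(f @ f), 0.0, adh0
        m = np.where(contact, np.maximum(s0 - s, 0.0) ** 1.5, 0.0)
        design = np.column_stack([m, -contact.astype(float)])
        sol, *_ = np.linalg.lstsq(design, f, rcond=None)
        resid = f - design @ sol
        return float(resid @ resid), float(sol[0]), float(sol[1])

    cands = np.sort(s)[::-1][:: max(1, len(s) // 128)]
    sses = np.array([joint_fit(c)[0] for c in cands])
    k = int(np.argmin(sses))
    lo = cands[min(k + 1, len(cands) - 1)]
    hi = cands[max(k - 1, 0)]
    if hi <= lo:
        lo, hi = lo - 1e-6, hi + 1e-6
    opt = minimize_scalar(
        lambda c: joint_fit(c)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    s0 = float(opt.x)
    sse, coef, F_adh = joint_fit(s0)
    if F_adh < 0 or coef <= 0:
        F_adh = adh0
        coef, s0, sse = _power_law_fit(s, f, exponent=1.5, contact_offset=-F_adh)
    geom = (4.0 / 3.0) * np.sqrt(tip.radius) * UNIT_NN
    E_star = coef / geom
    Ea = E_star * (1.0 - tip.poisson**2)
    ok = E_star > 0
    return FitResult(
        Ea=Ea,
        E_star=E_star,
        F_adh=F_adh,
        contact_point=s0,
        r_squared=_r_squared(f + F_adh, sse),
        ok=ok,
        message="" if ok else "non-physical fit",
    )


@dataclass
class StiffnessMap:
    """Fitted apparent-modulus grid with topography and diagnostics."""

    modulus: np.ndarray  # (ny, nx) MPa, NaN where the fit failed
    topography: np.ndarray  # (ny, nx) nm contact-point height
    r_squared: np.ndarray
    adhesion: np.ndarray  # nN (DMT) or zeros
    model: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.modulus.shape

    def to_frame(self) -> pd.DataFrame:
        ny, nx = self.shape
        ii, jj = np.mgrid[0:ny, 0:nx]
        return pd.DataFrame(
            {
                "row": ii.ravel(),
                "col": jj.ravel(),
                "Ea_MPa": self.modulus.ravel(),
                "height_nm": self.topography.ravel(),
                "r_squared": self.r_squared.ravel(),
                "F_adh_nN": self.adhesion.ravel(),
            }
        )


def _grid_fast_fit(
    F: np.ndarray, s: np.ndarray, exponent: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched piecewise power-law fit for curves sharing one s-axis.

    Coarse contact-point scan over the sample positions as matrix
    products, then vectorized parabolic refinement of the SSE minimum.
    Returns (coef, s0, r_squared) per curve (rows of ``F``).
    """
    order = np.argsort(-s)
    s_sorted = s[order]
    Fs = F[:, order]
    cands = s_sorted
    M = np.maximum(cands[:, None] - s_sorted[None, :], 0.0) ** exponent
    mm = np.einsum("cs,cs->c", M, M)  # (ncand,)
    num = Fs @ M.T  # (npix, ncand)
    ff = np.einsum("ps,ps->p", Fs, Fs)
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = ff[:, None] - np.where(mm > 0, num**2 / mm, 0.0)
    k = np.argmin(sse, axis=1)
    k = np.clip(k, 1, len(cands) - 2)
    # parabolic vertex through (k-1, k, k+1)
    idx = np.arange(len(F))
    y0, y1, y2 = sse[idx, k - 1], sse[idx, k], sse[idx, k + 1]
    x0, x1, x2 = cands[k - 1], cands[k], cands[k + 1]
    denom = (x0 - x1) * (y0 - y2) - (x0 - x2) * (y0 - y1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s0 = np.where(
            np.abs(denom) > 1e-300,
            0.5
            * ((x0**2 - x1**2) * (y0 - y2) - (x0**2 - x2**2) * (y0 - y1))
            / denom,
            x1,
        )
    s0 = np.clip(s0, np.minimum(x0, x2), np.maximum(x0, x2))
    m = np.maximum(s0[:, None] - s[None, :], 0.0) ** exponent
    mm2 = np.einsum("ps,ps->p", m, m)
    coef = np.where(mm2 > 0, np.einsum("ps,ps->p", F, m) / np.where(mm2 > 0, mm2, 1.0), 0.0)
    resid = F - coef[:, None] * m
    sse_f = np.einsum("ps,ps->p", resid, resid)
    tot = np.sum((F - F.mean(axis=1, keepdims=True)) ** 2, axis=1)
    r2 = np.where(tot > 0, 1.0 - sse_f / np.where(tot > 0, tot, 1.0), 0.0)
    return coef, s0, r2


def _shared_axis(curves: list[list[ForceCurve]]) -> bool:
    ref = curves[0][0]
    return all(
        len(c.separation) == len(ref.separation)
        and np.array_equal(c.separation, ref.separation)
        and np.array_equal(c.segment, ref.segment)
        for row in curves
        for c in row
    )


def build_stiffness_map(
    curves: list[list[ForceCurve]],
    tip: TipParams,
    model: str = "hertz_cone",
) -> StiffnessMap:
    """Fit every curve of a grid into a stiffness map.

    Raises on ragged grids; pixels whose fit fails are NaN-masked.
    Topography is the per-pixel contact-point height.  Hertz-cone grids
    whose curves share one separation axis are fitted in a single
    vectorized pass; otherwise curves are fitted one by one.
    """
    if model not in ("hertz_cone", "dmt_sphere"):
        raise ValueError("model must be hertz_cone or dmt_sphere")
    ny = len(curves)
    nx = len(curves[0]) if ny else 0
    if any(len(row) != nx for row in curves):
        raise ValueError("ragged curve grid")
    Ea = np.full((ny, nx), np.nan)
    topo = np.full((ny, nx), np.nan)
    r2 = np.full((ny, nx), np.nan)
    adh = np.zeros((ny, nx))

    if model == "hertz_cone" and ny * nx > 64 and _shared_axis(curves):
        mask = curves[0][0].segment == "approach"
        s = curves[0][0].separation[mask]
        F = np.stack([c.force[mask] for row in curves for c in row])
        geom = (2.0 / np.pi) * np.tan(np.radians(tip.half_angle)) / (
            1.0 - tip.poisson**2
        ) * UNIT_NN
        coef, s0, rr = _grid_fast_fit(F, s, exponent=2.0)
        E = coef / geom
        ok = E > 0
        Ea = np.where(ok, E, np.nan).reshape(ny, nx)
        topo = np.where(ok, s0, np.nan).reshape(ny, nx)
        r2 = rr.reshape(ny, nx)
        return StiffnessMap(Ea, topo, r2, adh, model)

    fit = fit_hertz_cone if model == "hertz_cone" else fit_dmt_sphere
    for i in range(ny):
        for j in range(nx):
            try:
                res = fit(curves[i][j], tip)
            except ValueError:
                continue
            if res.ok:
                Ea[i, j] = res.Ea
                topo[i, j] = res.contact_point
                r2[i, j] = res.r_squared
                adh[i, j] = res.F_adh
    return StiffnessMap(modulus=Ea, topography=topo, r_squared=r2, adhesion=adh, model=model)
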