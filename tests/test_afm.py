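"""AFM force-curve forward models, fits, and stiffness maps."""

import numpy as np
import pytest

import pavemech as pm
from pavemech.synthetic import UNIT_NN


def one_curve(model="hertz_cone", E=4.0, noise=0.0, adhesion=1.0, seed=0,
              topo=None):
    spec = pm.CurveGridSpec(
        modulus_map=np.full((1, 1), E), model=model, noise_sd=noise,
        adhesion_force=adhesion, seed=seed,
        topography=None if topo is None else np.full((1, 1), topo),
    )
    return pm.make_force_curves(spec)[0][0]


def test_hertz_forward_formula_exact():
    """F = (2/pi) tan(a) E/(1-nu^2) delta^2, nm/nN/MPa units."""
    delta = np.array([0.0, 10.0, 100.0])
    f = pm.hertz_cone_force(delta, E_mpa=4.0, half_angle_deg=18.0, poisson=0.5)
    expect = (2 / np.pi) * np.tan(np.radians(18.0)) * 4.0 / 0.75 * delta**2 * 1e-3
    assert np.allclose(f, expect, rtol=1e-12)


def test_dmt_forward_minimum_is_minus_adhesion():
    curve = one_curve("dmt_sphere", E=6.0, adhesion=1.0)
    _, f_ret = curve.retract()
    assert -f_ret.min() == pytest.approx(1.0, abs=0.03)


def test_two_phase_forward_contact_stiffness_ratio():
    """Curves at 2 vs 8 MPa differ in contact stiffness by exactly E2/E1."""
    c2 = one_curve(E=2.0)
    c8 = one_curve(E=8.0)
    s, f2 = c2.approach()
    _, f8 = c8.approach()
    contact = s < -10
    ratios = f8[contact] / f2[contact]
    assert np.allclose(ratios, 4.0, rtol=1e-9)


def test_nonpositive_modulus_rejected():
    with pytest.raises(ValueError, match="positive"):
        pm.CurveGridSpec(modulus_map=np.array([[4.0, -1.0]]))


def test_hertz_roundtrip_noiseless():
    fit = pm.fit_hertz_cone(one_curve(E=4.0), pm.TipParams())
    assert fit.Ea == pytest.approx(4.0, rel=0.01)
    assert fit.ok and fit.r_squared > 0.999


def test_hertz_linearity_in_force():
    curve = one_curve(E=4.0)
    doubled = pm.ForceCurve(curve.separation, 2.0 * curve.force, curve.segment)
    f1 = pm.fit_hertz_cone(curve, pm.TipParams())
    f2 = pm.fit_hertz_cone(doubled, pm.TipParams())
    assert f2.Ea == pytest.approx(2.0 * f1.Ea, rel=1e-6)


def test_hertz_no_contact_rejected():
    curve = one_curve(E=4.0)
    flat = pm.ForceCurve(curve.separation, np.zeros_like(curve.force),
                         curve.segment)
    with pytest.raises(ValueError, match="contact"):
        pm.fit_hertz_cone(flat, pm.TipParams())


def test_dmt_roundtrip_noiseless():
    fit = pm.fit_dmt_sphere(one_curve("dmt_sphere", E=6.0, adhesion=1.0),
                            pm.TipParams())
    assert fit.Ea == pytest.approx(6.0, rel=0.01)
    assert fit.F_adh == pytest.approx(1.0, rel=0.01)
    assert fit.E_star == pytest.approx(8.0, rel=0.01)  # E/(1-0.25)


def test_poisson_convention_ea_over_estar():
    fit = pm.fit_dmt_sphere(one_curve("dmt_sphere", E=6.0), pm.TipParams())
    assert fit.Ea / fit.E_star == pytest.approx(0.75, rel=1e-9)


def test_dmt_zero_adhesion_below_noise_floor():
    fit = pm.fit_dmt_sphere(one_curve("dmt_sphere", E=6.0, adhesion=0.0),
                            pm.TipParams())
    assert fit.F_adh <= 1e-6


def test_contact_point_recovered_within_2nm():
    for topo in (0.0, 13.7, -21.3):
        fit = pm.fit_hertz_cone(one_curve(E=4.0, topo=topo), pm.TipParams())
        assert abs(fit.contact_point - topo) < 2.0
        fit = pm.fit_dmt_sphere(one_curve("dmt_sphere", E=6.0, topo=topo),
                                pm.TipParams())
        assert abs(fit.contact_point - topo) < 2.0


def test_unit_discipline_dimensional_curve():
    """An analytic curve built from first principles in nm/nN gives MPa
    back without hidden scale factors."""
    tip = pm.TipParams(half_angle=20.0, poisson=0.3)
    s = np.linspace(100.0, -80.0, 300)
    delta = np.maximum(-s, 0.0)
    E_true = 5.5  # MPa
    force = (2 / np.pi) * np.tan(np.radians(20.0)) * E_true / (1 - 0.09) \
        * delta**2 * UNIT_NN
    curve = pm.ForceCurve(
        separation=np.concatenate([s, s[::-1]]),
        force=np.concatenate([force, force[::-1]]),
        segment=np.array(["approach"] * 300 + ["retract"] * 300),
    )
    fit = pm.fit_hertz_cone(curve, tip)
    assert fit.Ea == pytest.approx(E_true, rel=1e-6)


@pytest.mark.parametrize("model,E", [("hertz_cone", 4.0), ("dmt_sphere", 6.0)])
def test_bias_under_multiplicative_noise(model, E):
    """Bias < 2% at 5% multiplicative noise over 200 replicates."""
    rng = np.random.default_rng(42)
    base = one_curve(model, E=E)
    fit_fn = pm.fit_hertz_cone if model == "hertz_cone" else pm.fit_dmt_sphere
    vals = []
    for _ in range(200):
        noisy = pm.ForceCurve(
            base.separation,
            base.force * (1 + 0.05 * rng.normal(size=base.force.shape)),
            base.segment,
        )
        res = fit_fn(noisy, pm.TipParams())
        if res.ok:
            vals.append(res.Ea)
    assert len(vals) > 190
    assert abs(np.mean(vals) - E) / E < 0.02


def test_homogeneous_map_mean_and_spread():
    spec = pm.CurveGridSpec(modulus_map=np.full((16, 16), 4.0),
                            model="hertz_cone", noise_sd=0.02, seed=7)
    smap = pm.build_stiffness_map(pm.make_force_curves(spec), pm.TipParams())
    assert smap.shape == (16, 16)
    assert np.nanmean(smap.modulus) == pytest.approx(4.0, rel=0.03)
    assert np.nanstd(smap.modulus) < 0.5


def test_two_phase_map_recovery():
    """2 MPa background with 8 MPa stripes: phase means within 5% and
    midpoint-threshold classification >= 95% accurate."""
    ny = nx = 32
    jj = np.arange(nx)[None, :] * np.ones((ny, 1))
    stripes = ((jj // 4) % 2).astype(bool)
    mod = np.where(stripes, 8.0, 2.0)
    spec = pm.CurveGridSpec(modulus_map=mod, model="hertz_cone",
                            noise_sd=0.02, seed=9)
    smap = pm.build_stiffness_map(pm.make_force_curves(spec), pm.TipParams())
    assert np.nanmean(smap.modulus[stripes]) == pytest.approx(8.0, rel=0.05)
    assert np.nanmean(smap.modulus[~stripes]) == pytest.approx(2.0, rel=0.05)
    mask = smap.modulus > 5.0
    accuracy = np.mean(mask == stripes)
    assert accuracy >= 0.95


def test_map_topography_tracks_contact_height():
    topo = np.linspace(0, 50, 16).reshape(4, 4)
    spec = pm.CurveGridSpec(modulus_map=np.full((4, 4), 4.0),
                            topography=topo, seed=3)
    smap = pm.build_stiffness_map(pm.make_force_curves(spec), pm.TipParams())
    assert np.abs(smap.topography - topo).max() < 2.0


def test_full_resolution_grid_shape():
    """A 128 x 128 scan spec yields a 128 x 128 stiffness map."""
    spec = pm.CurveGridSpec(modulus_map=np.full((128, 128), 4.0),
                            n_samples=96, max_indentation=80.0,
                            approach_range=60.0, seed=1)
    curves = pm.make_force_curves(spec)
    smap = pm.build_stiffness_map(curves, pm.TipParams())
    assert smap.shape == (128, 128)
    assert np.isfinite(smap.modulus).all()


def test_ragged_grid_rejected():
    spec = pm.CurveGridSpec(modulus_map=np.full((2, 2), 4.0), seed=0)
    curves = pm.make_force_curves(spec)
    curves[1] = curves[1][:1]
    with pytest.raises(ValueError, match="ragged"):
        pm.build_stiffness_map(curves, pm.TipParams())
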