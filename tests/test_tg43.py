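"""Unit tests for the TG-43 formalism layer."""

import math

import numpy as np
import pandas as pd
import pytest

import brachyscatter as bs
from brachyscatter.tg43 import geometry_function


# --------------------------------------------------------------------------
# geometry function
# --------------------------------------------------------------------------

def test_point_source_limit_is_inverse_square():
    assert geometry_function(3.0, 1.0, 0.0) == pytest.approx(1.0 / 9.0)
    # a vanishingly short line converges to the same limit
    assert geometry_function(3.0, 1.0, 1e-6) == pytest.approx(1.0 / 9.0,
                                                              rel=1e-9)


def test_geometry_against_direct_beta_integral():
    r, theta, L = 2.0, math.radians(60.0), 1.5
    # beta by explicit angles to the tips
    x, z = r * math.sin(theta), r * math.cos(theta)
    a1 = math.atan2(x, z + L / 2)
    a2 = math.atan2(x, z - L / 2)
    beta = a2 - a1
    expect = beta / (L * r * math.sin(theta))
    assert geometry_function(r, theta, L) == pytest.approx(expect, rel=1e-12)


def test_geometry_on_axis_branch():
    L = 1.0
    assert geometry_function(2.0, 0.0, L) == pytest.approx(1.0 / (4 - 0.25))
    assert geometry_function(2.0, math.pi, L) == pytest.approx(1.0 / (4 - 0.25))
    with pytest.raises(ValueError, match="on-axis"):
        geometry_function(0.4, 0.0, L)


def test_geometry_input_validation():
    with pytest.raises(ValueError, match="positive"):
        geometry_function(0.0, 1.0, 0.5)
    with pytest.raises(ValueError, match="theta"):
        geometry_function(1.0, -0.1, 0.5)
    with pytest.raises(ValueError, match="theta"):
        geometry_function(1.0, 3.2, 0.5)


def test_geometry_vectorised_and_continuous_near_axis():
    r = np.array([1.0, 2.0, 5.0])
    out = geometry_function(r, math.pi / 2, 0.5)
    assert out.shape == (3,)
    # approaching the axis smoothly matches the axis branch
    near = geometry_function(2.0, 1e-7, 1.0)
    on = geometry_function(2.0, 0.0, 1.0)
    assert near == pytest.approx(on, rel=1e-6)


# --------------------------------------------------------------------------
# source models
# --------------------------------------------------------------------------

def test_source_models_for_isotopes():
    ir = bs.SourceModel.for_isotope("Ir192")
    assert ir.active_length_cm == 0.5 and ir.emission_mode == "line"
    pd103 = bs.SourceModel.for_isotope("Pd103")
    assert pd103.active_length_cm == pytest.approx(0.455)
    cs = bs.SourceModel.for_isotope("Cs137")
    assert cs.emission_mode == "pellets"
    assert cs.active_length_cm == pytest.approx(1.5)
    np.testing.assert_allclose(cs.pellet_z_cm, [-0.625, -0.125, 0.125, 0.625])
    cs6 = bs.SourceModel.for_isotope("Cs137", cs137_arrangement="AAAAAA")
    assert cs6.active_length_cm == pytest.approx(1.5)
    assert cs6.pellet_z_cm.size == 6


def test_source_model_validation():
    with pytest.raises(ValueError, match="unknown isotope"):
        bs.SourceModel.for_isotope("Ra226")
    with pytest.raises(ValueError, match="reference radius"):
        bs.SourceModel("Cs137", active_length_cm=2.5)
    with pytest.raises(ValueError, match="active length"):
        bs.SourceModel("Ir192", active_length_cm=0.0, emission_mode="line")


# --------------------------------------------------------------------------
# dose table containers
# --------------------------------------------------------------------------

def _tiny_table():
    df = pd.DataFrame({
        "r_cm": [1.0, 2.0, 1.0, 2.0],
        "theta_deg": [90.0, 90.0, 90.0, 90.0],
        "side": ["away", "away", "toward", "toward"],
        "dose_per_sk": [1.0, 0.25, 1.0, 0.24],
        "rel_err": [0.01, 0.02, 0.01, 0.02],
    })
    return bs.DoseRateTable(data=df, label="(15, 15)", isotope="Cs137")


def test_dose_table_validation():
    good = _tiny_table()
    assert good.sample(2.0, 90.0, "away") == (0.25, 0.02)
    assert good.sample(3.0, 90.0, "away") is None
    bad = good.data.copy()
    bad.loc[0, "r_cm"] = -1.0
    with pytest.raises(ValueError, match="r must be positive"):
        bs.DoseRateTable(data=bad)
    bad = good.data.copy()
    bad.loc[0, "dose_per_sk"] = -0.5
    with pytest.raises(ValueError, match="dose rates"):
        bs.DoseRateTable(data=bad)
    with pytest.raises(ValueError, match="missing columns"):
        bs.DoseRateTable(data=good.data.drop(columns=["rel_err"]))


def test_dose_table_csv_round_trip(tmp_path):
    t = _tiny_table()
    p = tmp_path / "t.csv"
    t.to_csv(p)
    back = bs.DoseRateTable.from_csv(p, label=t.label, isotope=t.isotope)
    pd.testing.assert_frame_equal(back.data, t.data)


# --------------------------------------------------------------------------
# extraction operations (on exact synthetic data)
# --------------------------------------------------------------------------

def _noiseless_table(isotope="Cs137"):
    spec = bs.SyntheticSpec(isotope=isotope, noise_sigma_10cm=0.0)
    return bs.generate_dose_table(spec, r_grid=np.arange(1.0, 10.1, 0.5),
                                  theta_grid_deg=np.array([30.0, 60.0, 90.0]))


def test_radial_dose_function_recovers_generator_exactly():
    table = _noiseless_table()
    src = bs.SourceModel.for_isotope("Cs137")
    for side in ("toward", "away"):
        g = bs.radial_dose_function(table, src, side=side)
        np.testing.assert_allclose(g.g, bs.G_MODELS["Cs137"](g.r_cm),
                                   rtol=1e-12)
        assert g.at(1.0) == pytest.approx(1.0)
        assert g.rel_err[np.isclose(g.r_cm, 1.0)][0] == 0.0


def test_radial_dose_function_missing_reference_raises():
    spec = bs.SyntheticSpec(isotope="Cs137", noise_sigma_10cm=0.0)
    table = bs.generate_dose_table(spec, r_grid=np.array([2.0, 3.0]))
    with pytest.raises(ValueError, match="reference sample"):
        bs.radial_dose_function(table, bs.SourceModel.for_isotope("Cs137"))


def test_anisotropy_function_unity_on_transverse_axis():
    table = _noiseless_table()
    src = bs.SourceModel.for_isotope("Cs137")
    grid = bs.anisotropy_function(table, src, side="away")
    j90 = int(np.flatnonzero(np.isclose(grid.theta_deg, 90.0))[0])
    np.testing.assert_allclose(grid.F[:, j90], 1.0, rtol=1e-12)
    # off-axis recovers the generator's anisotropy model
    from brachyscatter.synthetic import _f_model
    j30 = int(np.flatnonzero(np.isclose(grid.theta_deg, 30.0))[0])
    np.testing.assert_allclose(grid.F[:, j30], _f_model(30.0), rtol=1e-12)


def test_anisotropy_grid_masking_and_interpolation():
    F = np.array([[1.0, 0.8, 0.9], [1.0, np.nan, 0.9]])
    mask = np.array([[False, False, False], [False, True, False]])
    grid = bs.AnisotropyGrid(r_cm=np.array([1.0, 2.0]),
                             theta_deg=np.array([30.0, 60.0, 90.0]),
                             F=F, mask=mask)
    # any interpolation block touching the masked corner raises
    with pytest.raises(ValueError, match="masked"):
        grid.at(1.5, 75.0)
    # a clean block interpolates bilinearly
    clean = bs.AnisotropyGrid(r_cm=np.array([1.0, 2.0]),
                              theta_deg=np.array([60.0, 90.0]),
                              F=np.array([[0.8, 1.0], [0.9, 1.0]]),
                              mask=np.zeros((2, 2), dtype=bool))
    assert clean.at(1.5, 75.0) == pytest.approx((0.8 + 1.0 + 0.9 + 1.0) / 4)
    with pytest.raises(ValueError, match="outside"):
        clean.at(3.0, 90.0)


def test_dose_rate_constant_uses_both_sides():
    table = _tiny_table()
    lam = bs.dose_rate_constant(table, bs.AirKermaStrength(0.5))
    assert lam.value == pytest.approx(1.0 / 0.5)
    assert lam.label == "(15, 15)"
    with pytest.raises(ValueError, match="S_K must be positive"):
        bs.AirKermaStrength(0.0)


def test_reconstruct_decompose_round_trip():
    src = bs.SourceModel.for_isotope("Ir192")
    table = _noiseless_table("Ir192")
    g = bs.radial_dose_function(table, src, side="away")
    F = bs.anisotropy_function(table, src, side="away")
    lam = bs.DoseRateConstant(1.109)
    sk = bs.AirKermaStrength(2.0)
    for (r, t) in [(1.0, 90.0), (3.0, 60.0), (7.5, 45.0), (10.0, 30.0)]:
        dose = bs.reconstruct_dose_rate(src, lam, g, F, sk, r, t)
        gl = geometry_function(r, math.radians(t), src.active_length_cm)
        gl0 = geometry_function(1.0, math.pi / 2, src.active_length_cm)
        back = dose / (lam.value * sk.value * gl / gl0 * F.at(r, t))
        assert back == pytest.approx(g.at(r), rel=1e-10)


def test_radial_dose_curve_guards():
    with pytest.raises(ValueError, match="strictly increasing"):
        bs.RadialDoseCurve(r_cm=[1.0, 1.0], g=[1.0, 1.0], rel_err=[0, 0])
    with pytest.raises(ValueError, match="positive"):
        bs.RadialDoseCurve(r_cm=[1.0, 2.0], g=[1.0, -0.1], rel_err=[0, 0])
    c = bs.RadialDoseCurve(r_cm=[1.0, 2.0], g=[1.0, 0.9], rel_err=[0, 0])
    with pytest.raises(ValueError, match="outside"):
        c.at(2.5)
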