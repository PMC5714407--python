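"""Unit and behaviour tests for the Monte Carlo transport engine."""

import math

import numpy as np
import pytest

import brachyscatter as bs
from brachyscatter.mc import MEC2, TallyLayout, _run_kernel  # noqa: F401

from conftest import SEED, UNIT_SK


# --------------------------------------------------------------------------
# phantom configuration
# --------------------------------------------------------------------------

@pytest.mark.parametrize("label,axis,x", [
    ("(15, 15)", "none", 15.0),
    ("H(25, 5)", "H", 5.0),
    ("V(28, 2)", "V", 2.0),
    ("H(20, 10)", "H", 10.0),
])
def test_label_grammar_round_trip(label, axis, x):
    ph = bs.PhantomConfig.from_label(label)
    assert ph.shift_axis == axis
    assert ph.overlying_cm == x
    assert ph.label == label
    assert ph.missing_tissue_cm == pytest.approx(15.0 - x)


@pytest.mark.parametrize("label", ["(14, 15)", "H(26, 5)", "X(25, 5)",
                                   "H(25,5,1)", "shifted"])
def test_invalid_labels_raise(label):
    with pytest.raises(ValueError):
        bs.PhantomConfig.from_label(label)


def test_bounds_and_containment():
    ph = bs.PhantomConfig.from_label("H(25, 5)")
    lo, hi = ph.bounds()
    assert hi[0] == pytest.approx(5.0) and lo[0] == pytest.approx(-25.0)
    assert hi[2] == pytest.approx(15.0)
    pts = np.array([[4.9, 0, 0], [5.1, 0, 0], [-24.9, 0, 0], [0, 0, 14.9]])
    np.testing.assert_array_equal(ph.contains(pts), [True, False, True, True])
    phv = bs.PhantomConfig.from_label("V(28, 2)")
    lo, hi = phv.bounds()
    assert hi[2] == pytest.approx(2.0) and lo[2] == pytest.approx(-28.0)


def test_cell_position_conventions():
    ph = bs.PhantomConfig.from_label("H(25, 5)")
    np.testing.assert_allclose(bs.cell_position(ph, 5.0, 90.0, "toward"),
                               [5.0, 0.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(bs.cell_position(ph, 5.0, 90.0, "away"),
                               [-5.0, 0.0, 0.0], atol=1e-12)
    phv = bs.PhantomConfig.from_label("V(28, 2)")
    np.testing.assert_allclose(bs.cell_position(phv, 3.0, 0.0, "toward"),
                               [0.0, 0.0, 3.0], atol=1e-12)
    np.testing.assert_allclose(bs.cell_position(phv, 3.0, 0.0, "away"),
                               [0.0, 0.0, -3.0], atol=1e-12)
    # the toward cell at (r=3, theta=40 deg) pokes past the 2 cm face
    c = bs.cell_position(phv, 3.0, 40.0, "toward")
    assert c[2] > 2.0 and not phv.contains(c[None, :])[0]


# --------------------------------------------------------------------------
# sampling primitives
# --------------------------------------------------------------------------

def test_emit_geometry_and_spectrum():
    rng = np.random.default_rng(3)
    src = bs.SourceModel.for_isotope("Ir192")
    pos, dirs, e = bs.emit(src, rng, n=5000)
    assert np.all(np.abs(pos[:, 2]) <= 0.25 + 1e-12)
    assert np.all(pos[:, :2] == 0)
    np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
    spec = bs.spectrum_for("Ir192")
    assert set(np.round(e, 6)) <= set(np.round(spec.energies, 6))
    # isotropy: mean direction cosine ~ 0
    assert abs(dirs[:, 2].mean()) < 0.05
    cs = bs.SourceModel.for_isotope("Cs137")
    pos, _, _ = bs.emit(cs, rng, n=2000)
    assert set(np.round(pos[:, 2], 3)) <= {-0.625, -0.125, 0.125, 0.625}


def test_sample_free_path_statistics():
    rng = np.random.default_rng(4)
    w = bs.water()
    mu = float(w.mu_linear(0.6617))
    paths = bs.sample_free_path(w, 0.6617, rng, n=200_000)
    assert paths.mean() == pytest.approx(1.0 / mu, rel=0.02)
    assert bs.sample_free_path(None, 0.6617, rng) == math.inf


def test_compton_scatter_kinematic_bounds():
    rng = np.random.default_rng(5)
    e0 = 0.6617
    alpha = e0 / MEC2
    e, theta = bs.compton_scatter(e0, rng, n=50_000)
    assert np.all(e <= e0 + 1e-12)
    assert np.all(e >= e0 / (1.0 + 2.0 * alpha) - 1e-12)
    assert np.all((theta >= 0) & (theta <= np.pi))
    # backscatter carries the minimum energy
    back = theta > 3.0
    assert e[back].max() < e[theta < 0.5].min()


# --------------------------------------------------------------------------
# transport behaviour
# --------------------------------------------------------------------------

def test_run_is_deterministic_for_fixed_seed():
    src = bs.SourceModel.for_isotope("Cs137")
    ph = bs.PhantomConfig.from_label("(15, 15)")
    cfg = bs.SimulationConfig(n_histories=100_000, seed=99)
    r_grid = np.array([1.0, 3.0])
    a = bs.run_configuration(src, ph, cfg, r_grid=r_grid, sk=UNIT_SK)
    b = bs.run_configuration(src, ph, cfg, r_grid=r_grid, sk=UNIT_SK)
    np.testing.assert_array_equal(a.data["dose_per_sk"], b.data["dose_per_sk"])
    c = bs.run_configuration(
        src, ph, bs.SimulationConfig(n_histories=100_000, seed=100),
        r_grid=r_grid, sk=UNIT_SK)
    assert not np.allclose(a.data["dose_per_sk"], c.data["dose_per_sk"])


def test_fixed_photon_transport_scores_aimed_cell():
    ph = bs.PhantomConfig.from_label("(15, 15)")
    cfg = bs.SimulationConfig(n_histories=2000, seed=12)
    layout = TallyLayout.build(ph, [(3.0, 90.0, "toward"), (3.0, 90.0, "away")])
    photon = bs.PhotonState(position=np.zeros(3),
                            direction=np.array([1.0, 0.0, 0.0]),
                            energy=0.6617)
    # 'toward' cell lies at +x on this unshifted phantom by convention
    dose, rel, hits = bs.transport_history(photon, ph, cfg, layout,
                                           n_histories=2000)
    # most primaries reach the cell un-collided (mu ~ 0.086/cm over 3 cm)
    assert hits[0] > 1500
    assert dose[0] > 10 * max(dose[1], 1e-300)  # only scatter reaches -x
    with pytest.raises(ValueError, match="inside the phantom"):
        bs.transport_history(
            bs.PhotonState(position=np.array([20.0, 0, 0]),
                           direction=np.array([1.0, 0, 0]), energy=0.6617),
            ph, cfg, layout)


def test_out_of_phantom_cells_are_masked(cs_v28):
    _, table = cs_v28
    d = table.data
    masked = d[d["masked"]]
    # (r=3, theta=30 or 60, toward) exceeds the 2 cm overlying water
    assert ((masked["side"] == "toward") & (masked["r_cm"] >= 3.0)).any()
    assert masked["dose_per_sk"].isna().all()
    inside = d[~d["masked"]]
    assert inside["dose_per_sk"].notna().all()


def test_air_kerma_strength_far_field_consistency():
    src = bs.SourceModel.for_isotope("Cs137")
    cfg = bs.SimulationConfig(n_histories=400_000, seed=SEED)
    sk = bs.air_kerma_strength_run(src, cfg)
    assert sk.value > 0 and sk.rel_err < 0.05
    diag = sk.diagnostics
    far = diag[diag["d_cm"] >= 5.0]
    # each far-field estimate within 4 sigma of the combined value
    pulls = (far["sk_est"] - sk.value) / (far["sk_est"] * far["rel_err"])
    assert np.all(np.abs(pulls) < 4.0)


def test_scatter_contributes_beyond_primary_attenuation(cs_pair):
    """In water the dose at 10 cm vastly exceeds the primary-only estimate."""
    src, full, _ = cs_pair
    g = bs.radial_dose_function(full, src, side="away")
    w = bs.water()
    mu = float(w.mu_linear(0.6617))
    primary_only = math.exp(-mu * (10.0 - 1.0))   # ~ e^-0.77 per cm
    assert g.at(10.0) > 1.5 * primary_only


def test_simulation_config_validation():
    with pytest.raises(ValueError):
        bs.SimulationConfig(n_histories=0)
    with pytest.raises(ValueError):
        bs.SimulationConfig(cutoff_MeV=1e-5)
    cfg = bs.SimulationConfig()
    assert cfg.cutoff_for("Pd103") == 0.005
    assert bs.SimulationConfig(cutoff_MeV=0.02).cutoff_for("Pd103") == 0.02


def test_photon_state_validation():
    with pytest.raises(ValueError, match="unit vector"):
        bs.PhotonState(position=np.zeros(3), direction=np.array([1.0, 1.0, 0]),
                       energy=1.0)
    with pytest.raises(ValueError, match="energy"):
        bs.PhotonState(position=np.zeros(3), direction=np.array([1.0, 0, 0]),
                       energy=0.0)
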