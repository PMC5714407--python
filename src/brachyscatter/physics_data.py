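"""Embedded photon-interaction data and emission spectra.

Provides mass attenuation and mass energy-absorption coefficients for
liquid water and dry air on a coarse (28-point) energy grid transcribed by
hand from the standard public compilation, together with per-energy
interaction-channel fractions (photoelectric / incoherent / coherent), and
line emission spectra for the three source isotopes (103Pd, 192Ir, 137Cs).

Coefficients are interpolated log-log, the standard practice for photon
cross sections (exact for power-law behaviour between nodes).  Channel
fractions were apportioned consistently with the total attenuation column:
the incoherent part follows the Klein-Nishina free-electron cross section
with a smooth binding-suppression factor, the photoelectric part is
reconstructed from the energy-absorption column, and the coherent part is
the residual.  Absolute agreement with any particular production
cross-section library is therefore not claimed; the ratio estimands this
package targets are insensitive at this level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger("brachyscatter")

#: transport cutoff energies, MeV (photons below are terminated / lines dropped)
CUTOFF_MEV = {"Pd103": 0.005, "Ir192": 0.010, "Cs137": 0.010}

#: mass densities, g/cm^3
DENSITY = {"water": 1.0, "dry_air": 1.205e-3}

SUPPORTED_ISOTOPES = ("Pd103", "Ir192", "Cs137")

_CHANNELS = ("photoelectric", "compton", "rayleigh")


def _data_path(name: str):
    return resources.files("brachyscatter").joinpath("data", name)


@dataclass(frozen=True)
class MaterialTable:
    """Photon interaction data for one material on an ascending energy grid."""

    name: str
    energy: np.ndarray          # MeV, strictly increasing
    mu_rho: np.ndarray          # mass attenuation coefficient, cm^2/g
    muen_rho: np.ndarray        # mass energy-absorption coefficient, cm^2/g
    f_pe: np.ndarray            # photoelectric fraction of mu
    f_compton: np.ndarray       # incoherent fraction
    f_rayleigh: np.ndarray      # coherent fraction
    density: float              # g/cm^3

    def __post_init__(self):
        e = np.asarray(self.energy, dtype=float)
        if e.ndim != 1 or np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be 1-D and strictly increasing")
        for name in ("mu_rho", "muen_rho"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive everywhere")
        if np.any(self.muen_rho > self.mu_rho * (1 + 1e-12)):
            raise ValueError("muen/rho must not exceed mu/rho")
        fsum = self.f_pe + self.f_compton + self.f_rayleigh
        for f in (self.f_pe, self.f_compton, self.f_rayleigh):
            if np.any((f < 0) | (f > 1)):
                raise ValueError("channel fractions must lie in [0, 1]")
        if np.any(np.abs(fsum - 1.0) > 1e-6):
            raise ValueError("channel fractions must sum to 1 at every node")

    @classmethod
    def from_csv(cls, name: str, path, density: float) -> "MaterialTable":
        df = pd.read_csv(path)
        return cls(
            name=name,
            energy=df["energy_MeV"].to_numpy(),
            mu_rho=df["mu_rho"].to_numpy(),
            muen_rho=df["muen_rho"].to_numpy(),
            f_pe=df["f_pe"].to_numpy(),
            f_compton=df["f_compton"].to_numpy(),
            f_rayleigh=df["f_rayleigh"].to_numpy(),
            density=density,
        )

    # -- derived grids used by the transport kernel ------------------------
    @property
    def log_energy(self) -> np.ndarray:
        return np.log(self.energy)

    def mu_linear(self, energy) -> np.ndarray:
        """Linear attenuation coefficient mu (cm^-1) at `energy`."""
        return interpolate_mu(self, energy, kind="total") * self.density


@lru_cache(maxsize=None)
def water() -> MaterialTable:
    return MaterialTable.from_csv("water", _data_path("water.csv"), DENSITY["water"])


@lru_cache(maxsize=None)
def dry_air() -> MaterialTable:
    return MaterialTable.from_csv("dry_air", _data_path("dry_air.csv"),
                                  DENSITY["dry_air"])


def _check_energy_range(material: MaterialTable, energy: np.ndarray) -> None:
    lo, hi = material.energy[0], material.energy[-1]
    bad = (energy < lo) | (energy > hi)
    if np.any(bad):
        e = np.atleast_1d(energy)[np.atleast_1d(bad)][0]
        raise ValueError(
            f"energy {e:g} MeV outside {material.name} grid "
            f"[{lo:g}, {hi:g}] MeV"
        )


def interpolate_mu(material: MaterialTable, energy, kind: str = "total"):
    """Log-log interpolated mass coefficient (cm^2/g).

    ``kind`` is ``"total"`` for mu/rho or ``"energy_absorption"`` for
    muen/rho.  Exact at grid nodes; raises outside the grid range.
    """
    if kind == "total":
        col = material.mu_rho
    elif kind == "energy_absorption":
        col = material.muen_rho
    else:
        raise ValueError(f"unknown kind {kind!r}; use 'total' or 'energy_absorption'")
    e = np.asarray(energy, dtype=float)
    _check_energy_range(material, e)
    out = np.exp(np.interp(np.log(e), material.log_energy, np.log(col)))
    return out if out.ndim else float(out)


def interaction_fractions(material: MaterialTable, energy):
    """Channel fractions (photoelectric, compton, rayleigh) at `energy`.

    Interpolated linearly in log-energy and renormalised to sum to one.
    """
    e = np.asarray(energy, dtype=float)
    _check_energy_range(material, e)
    x = np.log(e)
    xp = material.log_energy
    fpe = np.interp(x, xp, material.f_pe)
    fc = np.interp(x, xp, material.f_compton)
    fr = np.interp(x, xp, material.f_rayleigh)
    tot = fpe + fc + fr
    return fpe / tot, fc / tot, fr / tot


def sample_interaction(material: MaterialTable, energy: float, rand):
    """Select an interaction channel proportionally to the local fractions.

    ``rand`` is one or more uniforms on [0, 1).  A draw landing exactly on a
    cumulative boundary is assigned to the upper channel (documented tie
    rule).  Returns a channel name, or an array of names for array input.
    """
    fpe, fc, _ = interaction_fractions(material, energy)
    r = np.asarray(rand, dtype=float)
    if np.any((r < 0) | (r >= 1)):
        raise ValueError("rand must lie in [0, 1)")
    # boundaries: [0, f_pe) -> pe, [f_pe, f_pe+f_c) -> compton, rest rayleigh
    idx = np.searchsorted(np.array([fpe, fpe + fc]), r, side="right")
    out = np.asarray(_CHANNELS)[idx]
    return out if out.ndim else str(out)


@dataclass(frozen=True)
class EmissionSpectrum:
    """Discrete photon emission spectrum of a sealed-source isotope."""

    isotope: str
    energies: np.ndarray        # MeV
    probabilities: np.ndarray   # normalised emission probabilities
    normalized: bool = True
    provenance: str = field(default="", compare=False)

    def __post_init__(self):
        if np.any(self.probabilities <= 0):
            raise ValueError("emission probabilities must be positive")
        if self.normalized and abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("normalised spectrum must sum to 1")

    @property
    def mean_energy(self) -> float:
        """Probability-weighted mean photon energy (MeV)."""
        return float(np.sum(self.energies * self.probabilities)
                     / np.sum(self.probabilities))

    @property
    def cumulative(self) -> np.ndarray:
        c = np.cumsum(self.probabilities)
        return c / c[-1]


_SPECTRUM_FILES = {
    "Pd103": "spectrum_pd103.csv",
    "Ir192": "spectrum_ir192.csv",
    "Cs137": "spectrum_cs137.csv",
}

_PROVENANCE = (
    "Hand transcription of the evaluated decay radiations (principal gamma "
    "and K x-ray lines); intensities per decay before normalisation."
)


def spectrum_for(isotope: str, cutoff_MeV: float | None = None) -> EmissionSpectrum:
    """Normalised emission spectrum for a supported isotope.

    Lines below the isotope's transport cutoff (5 keV for 103Pd, 10 keV for
    137Cs and 192Ir by default) are dropped with a logged warning.
    """
    if isotope not in _SPECTRUM_FILES:
        raise ValueError(
            f"unknown isotope {isotope!r}; supported: {sorted(_SPECTRUM_FILES)}"
        )
    if cutoff_MeV is None:
        cutoff_MeV = CUTOFF_MEV[isotope]
    df = pd.read_csv(_data_path(_SPECTRUM_FILES[isotope]))
    e = df["energy_MeV"].to_numpy()
    p = df["probability"].to_numpy()
    keep = e >= cutoff_MeV
    if not np.all(keep):
        logger.warning(
            "%s: dropping %d emission line(s) below the %g MeV transport cutoff",
            isotope, int((~keep).sum()), cutoff_MeV,
        )
    e, p = e[keep], p[keep]
    if e.size == 0:
        raise ValueError(f"{isotope}: no emission lines above cutoff")
    order = np.argsort(e)
    e, p = e[order], p[order]
    return EmissionSpectrum(isotope=isotope, energies=e, probabilities=p / p.sum(),
                            normalized=True, provenance=_PROVENANCE)
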