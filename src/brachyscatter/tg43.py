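"""TG-43 / TG-43U1 dose-calculation formalism for line sources.

Implements the line-source geometry function G_L(r, theta), the radial dose
function g_L(r), the 2D anisotropy function F(r, theta), the dose rate
constant Lambda = D(1 cm, pi/2) / S_K, and full dose-rate reconstruction

    D(r, theta) = Lambda * S_K * G_L(r,theta)/G_L(r0,theta0) * g_L(r) * F(r,theta)

with the reference point at r0 = 1 cm on the transverse axis
(theta0 = pi/2).  Angles are degrees in I/O and radians internally; the two
sides of the source (toward / away from the missing-tissue surface) are
carried as an explicit tag rather than extending theta beyond 180 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .physics_data import SUPPORTED_ISOTOPES

SIDES = ("toward", "away")

#: effective active lengths, cm
ACTIVE_LENGTH_CM = {"Pd103": 0.455, "Ir192": 0.5, "Cs137": 1.5}

# pellet-train arrangements for the LDR 137Cs source: 2.5 mm pellets,
# 'A' active / 'N' dummy, listed applicator order
CS137_ARRANGEMENTS = ("NANAANAN", "AAAAAA")


def _pellet_active_z(arrangement: str) -> np.ndarray:
    """Centres (cm) of the active pellets of a 2.5 mm pellet train."""
    n = len(arrangement)
    centres = (np.arange(n) - (n - 1) / 2) * 0.25
    return centres[np.array([c == "A" for c in arrangement])]


@dataclass(frozen=True)
class SourceModel:
    """A simplified sealed source: isotope, active geometry, reference point."""

    isotope: str
    active_length_cm: float
    emission_mode: str = "line"            # 'point' | 'line' | 'pellets'
    pellet_z_cm: np.ndarray | None = None  # active pellet centres ('pellets')
    r0_cm: float = 1.0
    theta0: float = math.pi / 2

    def __post_init__(self):
        if self.active_length_cm < 0:
            raise ValueError("active length must be >= 0")
        if self.emission_mode == "line" and self.active_length_cm <= 0:
            raise ValueError("line source needs active length > 0")
        if self.r0_cm <= self.active_length_cm / 2:
            raise ValueError("reference radius must exceed half the active length")
        if self.emission_mode == "pellets" and self.pellet_z_cm is None:
            raise ValueError("pellet source needs pellet positions")

    @classmethod
    def for_isotope(cls, isotope: str, cs137_arrangement: str = "NANAANAN"
                    ) -> "SourceModel":
        if isotope not in SUPPORTED_ISOTOPES:
            raise ValueError(
                f"unknown isotope {isotope!r}; supported: {sorted(SUPPORTED_ISOTOPES)}"
            )
        if isotope == "Cs137":
            if not set(cs137_arrangement) <= {"A", "N"}:
                raise ValueError("arrangement must be a string of 'A'/'N'")
            z = _pellet_active_z(cs137_arrangement)
            span = (z.max() - z.min()) + 0.25 if z.size else 0.0
            return cls("Cs137", active_length_cm=span, emission_mode="pellets",
                       pellet_z_cm=z)
        return cls(isotope, active_length_cm=ACTIVE_LENGTH_CM[isotope],
                   emission_mode="line")


# --------------------------------------------------------------------------
# geometry function
# --------------------------------------------------------------------------

def geometry_function(r, theta, L):
    """Line-source geometry function G_L(r, theta) in cm^-2.

    ``theta`` in radians, measured from the source long axis.  The subtended
    angle beta is built from explicit vectors to the two active-line tips,
    which is numerically stable near the line extension.  On the axis
    (sin(theta) ~ 0) the (r^2 - L^2/4)^-1 branch applies and requires
    r > L/2.
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    L = float(L)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if np.any((theta < 0) | (theta > math.pi)):
        raise ValueError("theta must lie in [0, pi]")
    r, theta = np.broadcast_arrays(r, theta)

    if L == 0:
        out = 1.0 / r**2
        return out if out.ndim else float(out)

    sin_t, cos_t = np.sin(theta), np.cos(theta)
    on_axis = sin_t < 1e-12
    if np.any(on_axis & (r <= L / 2)):
        raise ValueError("on-axis points require r > L/2")

    # vectors from the point of interest to the two active-line endpoints
    px, pz = r * sin_t, r * cos_t
    v1x, v1z = -px, -L / 2 - pz
    v2x, v2z = -px, +L / 2 - pz
    cross = v1x * v2z - v1z * v2x
    dot = v1x * v2x + v1z * v2z
    beta = np.arctan2(np.abs(cross), dot)

    with np.errstate(divide="ignore", invalid="ignore"):
        g_line = beta / (L * r * sin_t)
        g_axis = 1.0 / (r**2 - L**2 / 4)
        out = np.where(on_axis, g_axis, g_line)
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# tabulated dose-rate containers
# --------------------------------------------------------------------------

REQUIRED_COLUMNS = ["r_cm", "theta_deg", "side", "dose_per_sk", "rel_err"]


@dataclass
class DoseRateTable:
    """Tabulated dose rate per unit air-kerma strength around a source.

    ``data`` columns: r_cm, theta_deg, side ('toward'/'away'), dose_per_sk
    (cGy h^-1 U^-1), rel_err (relative standard error).  Masked points
    (outside the phantom) carry NaN dose.
    """

    data: pd.DataFrame
    label: str = "(15, 15)"
    isotope: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"dose table missing columns: {missing}")
        d = self.data
        if (d["r_cm"] <= 0).any():
            raise ValueError("r must be positive")
        if ((d["theta_deg"] < 0) | (d["theta_deg"] > 180)).any():
            raise ValueError("theta_deg must lie in [0, 180]")
        valid = d["dose_per_sk"].notna()
        if (d.loc[valid, "dose_per_sk"] < 0).any():
            raise ValueError("dose rates must be >= 0")
        if (d.loc[valid, "rel_err"] < 0).any():
            raise ValueError("standard errors must be >= 0")

    def sample(self, r: float, theta_deg: float, side: str):
        """(dose, rel_err) at an exact tabulated point, or None."""
        d = self.data
        m = (np.isclose(d["r_cm"], r) & np.isclose(d["theta_deg"], theta_deg)
             & (d["side"] == side))
        rows = d[m]
        if rows.empty:
            return None
        return float(rows["dose_per_sk"].mean()), float(rows["rel_err"].mean())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label="(15, 15)", isotope="") -> "DoseRateTable":
        return cls(pd.read_csv(path), label=label, isotope=isotope)


@dataclass
class RadialDoseCurve:
    """Radial dose function g_L(r) on one side of the source."""

    r_cm: np.ndarray
    g: np.ndarray
    rel_err: np.ndarray
    side: str = "away"
    label: str = "(15, 15)"
    isotope: str = ""

    def __post_init__(self):
        self.r_cm = np.asarray(self.r_cm, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.rel_err = np.asarray(self.rel_err, dtype=float)
        if np.any(np.diff(self.r_cm) <= 0):
            raise ValueError("r grid must be strictly increasing")
        if np.any(self.g <= 0):
            raise ValueError("g values must be positive")

    def at(self, r) -> np.ndarray:
        """Log-linear (in r) interpolation of g; raises outside the grid."""
        r = np.asarray(r, dtype=float)
        if np.any((r < self.r_cm[0]) | (r > self.r_cm[-1])):
            raise ValueError(
                f"r outside tabulated range [{self.r_cm[0]:g}, {self.r_cm[-1]:g}] cm"
            )
        out = np.interp(np.log(r), np.log(self.r_cm), self.g)
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_cm": self.r_cm, "g": self.g,
                             "rel_err": self.rel_err})


@dataclass
class AnisotropyGrid:
    """2D anisotropy function F(r, theta) with an out-of-phantom mask."""

    r_cm: np.ndarray
    theta_deg: np.ndarray
    F: np.ndarray                 # shape (n_r, n_theta); NaN where masked
    mask: np.ndarray              # True where the point lies outside the phantom
    side: str = "away"
    label: str = "(15, 15)"
    isotope: str = ""

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.F.shape != (len(self.r_cm), len(self.theta_deg)):
            raise ValueError("F shape must be (n_r, n_theta)")
        if np.any(~np.isnan(self.F[self.mask])):
            raise ValueError("masked entries must carry no value (NaN)")
        ok = ~self.mask & ~np.isnan(self.F)
        if np.any(self.F[ok] <= 0):
            raise ValueError("F must be positive where defined")

    def at(self, r: float, theta_deg: float) -> float:
        """Bilinear interpolation in (r, theta); raises outside grids/mask."""
        r_grid = np.asarray(self.r_cm, dtype=float)
        t_grid = np.asarray(self.theta_deg, dtype=float)
        if not (r_grid[0] <= r <= r_grid[-1]):
            raise ValueError("r outside anisotropy grid")
        if not (t_grid[0] <= theta_deg <= t_grid[-1]):
            raise ValueError("theta outside anisotropy grid")
        i = min(np.searchsorted(r_grid, r, side="right") - 1, len(r_grid) - 2)
        j = min(np.searchsorted(t_grid, theta_deg, side="right") - 1,
                len(t_grid) - 2)
        i, j = max(i, 0), max(j, 0)
        fr = 0.0 if r_grid[i + 1] == r_grid[i] else \
            (r - r_grid[i]) / (r_grid[i + 1] - r_grid[i])
        ft = 0.0 if t_grid[j + 1] == t_grid[j] else \
            (theta_deg - t_grid[j]) / (t_grid[j + 1] - t_grid[j])
        corners = self.F[i:i + 2, j:j + 2]
        if np.any(np.isnan(corners)):
            raise ValueError("interpolation touches a masked point")
        return float(corners[0, 0] * (1 - fr) * (1 - ft)
                     + corners[1, 0] * fr * (1 - ft)
                     + corners[0, 1] * (1 - fr) * ft
                     + corners[1, 1] * fr * ft)


@dataclass(frozen=True)
class DoseRateConstant:
    """Dose rate constant Lambda (cGy h^-1 U^-1)."""

    value: float
    rel_err: float = 0.0
    label: str = "(15, 15)"

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("Lambda must be positive")


@dataclass(frozen=True)
class AirKermaStrength:
    """Air kerma strength S_K with per-distance fit diagnostics."""

    value: float                   # U, consistently per history
    rel_err: float = 0.0
    diagnostics: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("S_K must be positive")


# --------------------------------------------------------------------------
# TG-43 extraction operations
# --------------------------------------------------------------------------

def _transverse_samples(table: DoseRateTable, side: str) -> pd.DataFrame:
    d = table.data
    rows = d[(d["side"] == side) & np.isclose(d["theta_deg"], 90.0)
             & d["dose_per_sk"].notna()]
    return rows.sort_values("r_cm")


def radial_dose_function(table: DoseRateTable, source: SourceModel,
                         side: str = "away") -> RadialDoseCurve:
    """Extract g_L(r) from transverse-axis samples on the requested side.

    g_L(r) = [D(r, pi/2) / D(r0, pi/2)] * [G_L(r0, pi/2) / G_L(r, pi/2)],
    normalised exactly at the tabulated reference sample r0 = 1 cm.
    """
    rows = _transverse_samples(table, side)
    if rows.empty:
        raise ValueError(f"no transverse-axis samples on side {side!r}")
    ref = rows[np.isclose(rows["r_cm"], source.r0_cm)]
    if ref.empty:
        raise ValueError(f"missing reference sample at r0 = {source.r0_cm} cm")
    d0 = float(ref["dose_per_sk"].iloc[0])
    if d0 == 0:
        raise ValueError("zero dose rate at the reference point")
    e0 = float(ref["rel_err"].iloc[0])
    L = source.active_length_cm
    r = rows["r_cm"].to_numpy()
    dose = rows["dose_per_sk"].to_numpy()
    g0 = geometry_function(source.r0_cm, math.pi / 2, L)
    g = (dose / d0) * (g0 / geometry_function(r, math.pi / 2, L))
    rel = np.sqrt(rows["rel_err"].to_numpy() ** 2 + e0**2)
    rel[np.isclose(r, source.r0_cm)] = 0.0   # exact by construction
    return RadialDoseCurve(r_cm=r, g=g, rel_err=rel, side=side,
                           label=table.label, isotope=table.isotope)


def anisotropy_function(table: DoseRateTable, source: SourceModel,
                        side: str = "away") -> AnisotropyGrid:
    """Extract F(r, theta) on one side; out-of-phantom points stay masked.

    F(r, theta) = [D(r,theta) / D(r, pi/2)] * [G_L(r, pi/2) / G_L(r, theta)].
    """
    d = table.data
    rows = d[d["side"] == side]
    if rows.empty:
        raise ValueError(f"no samples on side {side!r}")
    r_grid = np.unique(rows["r_cm"].to_numpy())
    t_grid = np.unique(rows["theta_deg"].to_numpy())
    L = source.active_length_cm
    F = np.full((len(r_grid), len(t_grid)), np.nan)
    mask = np.zeros_like(F, dtype=bool)
    for i, r in enumerate(r_grid):
        ref = table.sample(r, 90.0, side)
        if ref is None or not np.isfinite(ref[0]):
            raise ValueError(f"missing transverse sample at r = {r} cm")
        d90, _ = ref
        gl90 = geometry_function(r, math.pi / 2, L)
        for j, t in enumerate(t_grid):
            s = table.sample(r, t, side)
            if s is None:
                mask[i, j] = True
                continue
            dose, _ = s
            if not np.isfinite(dose):
                mask[i, j] = True
                continue
            theta = math.radians(t)
            F[i, j] = (dose / d90) * (gl90 / geometry_function(r, theta, L))
    return AnisotropyGrid(r_cm=r_grid, theta_deg=t_grid, F=F, mask=mask,
                          side=side, label=table.label, isotope=table.isotope)


def dose_rate_constant(table: DoseRateTable, sk: AirKermaStrength,
                       source: SourceModel | None = None) -> DoseRateConstant:
    """Lambda = D(r0, pi/2) / S_K with errors propagated in quadrature.

    When both sides carry a reference sample their mean is used (they are
    statistically equivalent at 1 cm).
    """
    r0 = source.r0_cm if source is not None else 1.0
    samples = [table.sample(r0, 90.0, s) for s in SIDES]
    samples = [s for s in samples if s is not None and np.isfinite(s[0])]
    if not samples:
        raise ValueError(f"missing reference sample at r0 = {r0} cm")
    dose = float(np.mean([s[0] for s in samples]))
    rel = float(np.sqrt(np.mean([s[1] ** 2 for s in samples]) / len(samples)))
    return DoseRateConstant(value=dose / sk.value,
                            rel_err=math.hypot(rel, sk.rel_err),
                            label=table.label)


def reconstruct_dose_rate(source: SourceModel, lam: DoseRateConstant | float,
                          g: RadialDoseCurve, F: AnisotropyGrid,
                          sk: AirKermaStrength | float,
                          r: float, theta_deg: float) -> float:
    """Dose rate (cGy/h) from the five TG-43 factors at (r, theta).

    g is interpolated log-linearly in r, F bilinearly in (r, theta); no
    silent extrapolation beyond either grid.
    """
    lam_v = lam.value if isinstance(lam, DoseRateConstant) else float(lam)
    sk_v = sk.value if isinstance(sk, AirKermaStrength) else float(sk)
    L = source.active_length_cm
    theta = math.radians(theta_deg)
    gl = geometry_function(r, theta, L)
    gl0 = geometry_function(source.r0_cm, source.theta0, L)
    return lam_v * sk_v * (gl / gl0) * float(g.at(r)) * F.at(r, theta_deg)
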