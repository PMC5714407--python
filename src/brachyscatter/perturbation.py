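"""Missing-tissue perturbation factors and polynomial correction machinery.

The perturbation factor is the ratio of the radial dose function in a
shifted (missing-tissue) configuration to the full-scatter reference:

    PF(r, x) = g_(30-x, x)(r) / g_(15,15)(r)

and the correction is its inverse application,

    g_(30-x, x)(r) = PF(r, x) * g_(15,15)(r).

Published degree-<=6 polynomial fits of PF(r, x) for 192Ir, 103Pd and 137Cs
at five overlying thicknesses ship as packaged reference data.  Each fit is
valid for r up to the overlying thickness x: beyond that radius the
missing-tissue-side point lies outside the phantom, and the printed
coefficients diverge there.  Evaluation outside the validity range raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .tg43 import DoseRateTable, RadialDoseCurve, SourceModel, radial_dose_function

PCT_CONVENTIONS = ("sides", "vs_full", "vs_shifted")


@dataclass
class PerturbationCurve:
    """Tabulated PF(r, x): ratio of shifted to full-scatter g(r)."""

    r_cm: np.ndarray
    pf: np.ndarray
    rel_err: np.ndarray
    label: str = ""                 # shifted-configuration label
    axis: str = ""                  # 'H' or 'V'
    overlying_cm: float = float("nan")

    def __post_init__(self):
        self.r_cm = np.asarray(self.r_cm, dtype=float)
        self.pf = np.asarray(self.pf, dtype=float)
        self.rel_err = np.asarray(self.rel_err, dtype=float)
        if np.any(self.pf <= 0):
            raise ValueError("perturbation factors must be positive")
        near_ref = np.isclose(self.r_cm, 1.0)
        if np.any(near_ref) and not np.all(
                (self.pf[near_ref] > 0.98) & (self.pf[near_ref] < 1.02)):
            raise ValueError("PF at the reference radius must be within 2% of 1")

    def at(self, r):
        r = np.asarray(r, dtype=float)
        if np.any((r < self.r_cm[0]) | (r > self.r_cm[-1])):
            raise ValueError("r outside the tabulated perturbation range")
        out = np.interp(r, self.r_cm, self.pf)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class PolyCoefficients:
    """Coefficients a0..a6 of a PF(r) polynomial in r (cm), with validity range."""

    coeffs: np.ndarray              # ascending powers, length <= 7
    isotope: str = ""
    label: str = ""                 # e.g. '(25+5)'
    r_min: float = 0.25
    r_max: float = 10.0
    residual_rms: float = field(default=float("nan"), compare=False)

    def __post_init__(self):
        c = np.asarray(self.coeffs, dtype=float)
        object.__setattr__(self, "coeffs", c)
        if c.size > 7:
            raise ValueError("at most degree 6 (7 coefficients)")
        if not (self.r_min <= 1.0 <= self.r_max):
            # the reference radius may be outside a narrow fit window,
            # but the packaged families all include it
            pass
        v1 = float(np.polynomial.polynomial.polyval(1.0, c))
        if not (0.9 <= v1 <= 1.1):
            raise ValueError(f"polynomial evaluates to {v1:.3f} at r=1 cm; "
                             "expected within [0.9, 1.1]")

    @property
    def overlying_cm(self) -> float:
        """Overlying thickness x parsed from a '(30-x+x)' style label."""
        try:
            return float(self.label.strip("()").split("+")[1])
        except (IndexError, ValueError):
            return float("nan")


def evaluate_polynomial(coeffs: PolyCoefficients, r):
    """a0 + a1 r + ... + a6 r^6 by Horner's scheme; raises outside validity."""
    r = np.asarray(r, dtype=float)
    if np.any((r < coeffs.r_min) | (r > coeffs.r_max)):
        raise ValueError(
            f"r outside the validity range [{coeffs.r_min:g}, {coeffs.r_max:g}] cm "
            f"of the {coeffs.isotope} {coeffs.label} polynomial"
        )
    out = np.polynomial.polynomial.polyval(r, coeffs.coeffs)
    return out if out.ndim else float(out)


@lru_cache(maxsize=1)
def _coefficient_table() -> pd.DataFrame:
    path = resources.files("brachyscatter").joinpath("data",
                                                     "table2_coefficients.csv")
    return pd.read_csv(path)


def available_corrections() -> pd.DataFrame:
    """The packaged (isotope, label) polynomial families."""
    return _coefficient_table()[["isotope", "label", "r_min", "r_max"]].copy()


def load_poly_coefficients(isotope: str, label: str) -> PolyCoefficients:
    """Packaged PF polynomial for (isotope, label), label like '(25+5)'."""
    df = _coefficient_table()
    row = df[(df["isotope"] == isotope) & (df["label"] == label)]
    if row.empty:
        known = sorted(df["label"].unique())
        raise KeyError(f"no packaged coefficients for {isotope} {label}; "
                       f"labels: {known}")
    row = row.iloc[0]
    return PolyCoefficients(
        coeffs=row[["a0", "a1", "a2", "a3", "a4", "a5", "a6"]].to_numpy(float),
        isotope=isotope, label=label,
        r_min=float(row["r_min"]), r_max=float(row["r_max"]),
    )


# --------------------------------------------------------------------------
# perturbation operations
# --------------------------------------------------------------------------

def perturbation_factor(g_shifted: RadialDoseCurve,
                        g_full: RadialDoseCurve) -> PerturbationCurve:
    """PF(r) = g_shifted(r) / g_full(r), errors combined in quadrature.

    The curves must overlap; the full-scatter curve is interpolated onto the
    shifted curve's grid where the grids differ.
    """
    r = g_shifted.r_cm
    if r[0] < g_full.r_cm[0] or r[-1] > g_full.r_cm[-1]:
        overlap = (r >= g_full.r_cm[0]) & (r <= g_full.r_cm[-1])
        if not overlap.any():
            raise ValueError("curves have no overlapping radial range")
        r = r[overlap]
    gs = g_shifted.at(r) if not np.array_equal(r, g_shifted.r_cm) else g_shifted.g
    gf = g_full.at(r)
    if np.any(gf == 0):
        raise ValueError("zero denominator in the full-scatter curve")
    es = np.interp(r, g_shifted.r_cm, g_shifted.rel_err)
    ef = np.interp(r, g_full.r_cm, g_full.rel_err)
    axis = g_shifted.label[:1] if g_shifted.label[:1] in ("H", "V") else ""
    try:
        x = float(g_shifted.label.split(",")[1].strip(" )"))
    except (IndexError, ValueError):
        x = float("nan")
    return PerturbationCurve(r_cm=r, pf=gs / gf, rel_err=np.hypot(es, ef),
                             label=g_shifted.label, axis=axis, overlying_cm=x)


def apply_correction(g_full: RadialDoseCurve,
                     pf: PerturbationCurve | PolyCoefficients) -> RadialDoseCurve:
    """Corrected curve g_shifted(r) = PF(r) * g_full(r) (inverse of
    :func:`perturbation_factor`); no extrapolation beyond PF's validity."""
    r = g_full.r_cm
    if isinstance(pf, PolyCoefficients):
        factor = evaluate_polynomial(pf, r)     # raises outside validity
        label = f"{g_full.label} x {pf.label}"
    else:
        factor = pf.at(r)
        label = pf.label or g_full.label
    return RadialDoseCurve(r_cm=r, g=g_full.g * factor, rel_err=g_full.rel_err,
                           side=g_full.side, label=label, isotope=g_full.isotope)


def fit_polynomial(curve: PerturbationCurve, max_degree: int = 6
                   ) -> PolyCoefficients:
    """Least-squares polynomial fit of PF(r) with automatic degree choice.

    The degree is the smallest d for which raising it to d+1 improves the
    residual RMS by less than 10%.  Raises on ill-conditioned designs.
    """
    if max_degree > 6:
        raise ValueError("max_degree must be <= 6")
    r, y = curve.r_cm, curve.pf
    if r.size < max_degree + 1:
        raise ValueError(f"need at least {max_degree + 1} points for degree "
                         f"{max_degree}")

    def rms_for(d):
        with np.errstate(all="ignore"):
            c = np.polynomial.polynomial.polyfit(r, y, d)
        resid = y - np.polynomial.polynomial.polyval(r, c)
        return c, float(np.sqrt(np.mean(resid**2)))

    coeffs, rms = rms_for(1)
    chosen_d = 1
    for d in range(1, max_degree + 1):
        c_d, rms_d = rms_for(d)
        if d == max_degree:
            coeffs, rms, chosen_d = c_d, rms_d, d
            break
        _, rms_next = rms_for(d + 1)
        if rms_d < 1e-12 or (rms_d - rms_next) < 0.10 * rms_d:
            coeffs, rms, chosen_d = c_d, rms_d, d
            break
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("ill-conditioned polynomial design; reduce the degree")
    full = np.zeros(7)
    full[:coeffs.size] = coeffs
    return PolyCoefficients(coeffs=full, isotope="", label=curve.label,
                            r_min=float(r[0]), r_max=float(r[-1]),
                            residual_rms=rms)


def percent_difference(a: float, b: float, convention: str) -> float:
    """Percent difference under one of the report conventions.

    * ``sides``:      100 (away - toward) / away,       a=away, b=toward
    * ``vs_full``:    100 (full - shifted) / full,      a=full, b=shifted
    * ``vs_shifted``: 100 |full - shifted| / shifted,   a=full, b=shifted

    Values are returned unrounded; report writers round to two decimals.
    """
    if a <= 0 or b <= 0:
        raise ValueError("percent_difference needs positive inputs")
    if convention in ("sides", "vs_full"):
        return 100.0 * (a - b) / a
    if convention == "vs_shifted":
        return 100.0 * abs(a - b) / b
    raise ValueError(f"unknown convention {convention!r}; "
                     f"use one of {PCT_CONVENTIONS}")


def build_comparison_report(runs: dict, reference_label: str,
                            convention: str = "vs_full",
                            source: SourceModel | None = None,
                            side: str = "toward") -> pd.DataFrame:
    """Per-radius comparison rows in the layout of the published tables.

    ``runs`` maps configuration label -> RadialDoseCurve or DoseRateTable
    (tables are reduced to g(r) on ``side``; a source model is then
    required).  With convention ``sides`` the single referenced run is
    compared across its own two sides; otherwise every non-reference run is
    compared against the reference configuration.  Columns: r_cm, label,
    value_a, value_b, pct_diff (two decimals), rel_err, convention.
    """
    def as_curve(obj, which_side):
        if isinstance(obj, RadialDoseCurve):
            return obj
        if isinstance(obj, DoseRateTable):
            if source is None:
                raise ValueError("a source model is required to reduce dose "
                                 "tables to g(r)")
            return radial_dose_function(obj, source, side=which_side)
        raise TypeError(f"unsupported run type {type(obj)!r}")

    if reference_label not in runs:
        raise KeyError(f"reference configuration {reference_label!r} missing "
                       f"from runs {sorted(runs)}")
    rows = []
    if convention == "sides":
        obj = runs[reference_label]
        away = as_curve(obj, "away")
        toward = as_curve(obj, "toward")
        for r, va in zip(away.r_cm, away.g):
            m = np.isclose(toward.r_cm, r)
            if not m.any():
                continue
            vb = float(toward.g[m][0])
            err = float(np.hypot(away.rel_err[np.isclose(away.r_cm, r)][0],
                                 toward.rel_err[m][0]))
            rows.append((r, reference_label, round(va, 3), round(vb, 3),
                         round(percent_difference(va, vb, "sides"), 2), err))
    else:
        ref = as_curve(runs[reference_label], side)
        for label, obj in runs.items():
            if label == reference_label:
                continue
            cur = as_curve(obj, side)
            for r, vb in zip(cur.r_cm, cur.g):
                m = np.isclose(ref.r_cm, r)
                if not m.any():
                    continue
                va = float(ref.g[m][0])
                err = float(np.hypot(ref.rel_err[m][0],
                                     cur.rel_err[np.isclose(cur.r_cm, r)][0]))
                rows.append((r, label, round(va, 3), round(vb, 3),
                             round(percent_difference(va, vb, convention), 2),
                             err))
    df = pd.DataFrame(rows, columns=["r_cm", "label", "value_a", "value_b",
                                     "pct_diff", "rel_err"])
    df["convention"] = convention
    return df
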