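"""Calibration-based quantification and method-validation figures of merit.

Analyte responses are internal-standard area ratios; calibration fits a
least-squares polynomial (degree 1 by default, 2 supported) of response on
nominal concentration.  Detection limits follow the replicate-calibration
convention LOD = 3.3*Sb/a and LOQ = 10*Sb/a, with a the mean slope and Sb
the standard deviation of the intercepts over (at least) three low-range
linear curves.  Accuracy is spike recovery with an 80-120% pass band, and
precision is the percent relative standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CalibrationCurve",
    "LodLoq",
    "QuantResult",
    "response_ratio",
    "fit_calibration",
    "lod_loq",
    "quantify",
    "recovery",
    "rsd",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted response-vs-concentration polynomial.

    ``coefficients`` are highest order first (numpy convention); ``r`` is
    the correlation between observed and fitted responses (sqrt of the
    coefficient of determination of the fit).
    """

    compound: str
    levels: tuple[tuple[float, float], ...]  # (concentration ug/mL, ratio)
    degree: int
    coefficients: tuple[float, ...]
    r: float
    linear_range: tuple[float, float]

    @property
    def slope(self) -> float:
        if self.degree != 1:
            raise ValueError("slope defined for degree-1 curves only")
        return self.coefficients[0]

    @property
    def intercept(self) -> float:
        return self.coefficients[-1]

    def predict(self, concentration: float) -> float:
        return float(np.polyval(self.coefficients, concentration))


@dataclass(frozen=True)
class LodLoq:
    slope: float
    intercept_sd: float
    lod: float
    loq: float


@dataclass(frozen=True)
class QuantResult:
    concentration: float  # ug/mL in the measured solution
    below_loq: bool | None
    amount_per_gram: float | None = None  # ug per g of starting material


def response_ratio(area_compound: float, area_internal_standard: float) -> float:
    """Analyte/internal-standard peak-area ratio."""
    if area_internal_standard <= 0:
        raise ValueError("internal standard area must be positive")
    return area_compound / area_internal_standard


def fit_calibration(
    levels: Sequence[tuple[float, float]],
    degree: int = 1,
    compound: str = "",
) -> CalibrationCurve:
    """Least-squares polynomial of response ratio on nominal concentration.

    Requires at least ``degree + 2`` levels with strictly positive,
    strictly increasing concentrations.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if len(levels) < degree + 2:
        raise ValueError(f"need >= {degree + 2} levels for degree {degree}")
    conc = np.asarray([c for c, _ in levels], dtype=float)
    resp = np.asarray([r for _, r in levels], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    coeffs = np.polyfit(conc, resp, degree)
    fitted = np.polyval(coeffs, conc)
    ss_res = float(np.sum((resp - fitted) ** 2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r = math.sqrt(max(0.0, 1.0 - ss_res / ss_tot)) if ss_tot > 0 else 1.0
    return CalibrationCurve(
        compound=compound,
        levels=tuple((float(c), float(r_)) for c, r_ in levels),
        degree=degree,
        coefficients=tuple(float(c) for c in coeffs),
        r=r,
        linear_range=(float(conc.min()), float(conc.max())),
    )


def lod_loq(curves: Sequence[CalibrationCurve]) -> LodLoq:
    """LOD/LOQ from replicate low-range linear curves.

    a = mean slope, Sb = sample standard deviation of the intercepts;
    LOD = 3.3*Sb/a, LOQ = 10*Sb/a.
    """
    if len(curves) < 3:
        raise ValueError("need at least three replicate calibration curves")
    if any(c.degree != 1 for c in curves):
        raise ValueError("LOD/LOQ estimation requires linear fits")
    slopes = np.asarray([c.slope for c in curves])
    intercepts = np.asarray([c.intercept for c in curves])
    a = float(slopes.mean())
    if a <= 0:
        raise ValueError("mean slope must be positive")
    sb = float(intercepts.std(ddof=1))
    return LodLoq(slope=a, intercept_sd=sb, lod=3.3 * sb / a, loq=10 * sb / a)


def quantify(
    ratio: float,
    curve: CalibrationCurve,
    loq: float | None = None,
    dilution_factor: float = 1.0,
    extract_volume_ml: float | None = None,
    sample_mass_g: float = 0.010,
) -> QuantResult:
    """Invert the calibration curve for one sample response ratio.

    Degree 1 inverts analytically; degree 2 takes the real root inside the
    calibrated range (error when none exists).  When ``loq`` is given,
    concentrations below it are flagged rather than trusted.  Per-gram
    amounts use the extract volume, dilution factor and starting mass
    (default 10 mg, 100% extraction yield).
    """
    coeffs = np.asarray(curve.coefficients)
    if curve.degree == 1:
        a, b = coeffs
        if a == 0:
            raise ValueError("zero slope")
        conc = (ratio - b) / a
    else:
        roots = np.roots(coeffs - np.array([0, 0, ratio]))
        real = [float(r.real) for r in roots if abs(r.imag) < 1e-9]
        lo, hi = curve.linear_range
        margin = 0.05 * (hi - lo)
        in_range = [r for r in real if lo - margin <= r <= hi + margin]
        if not in_range:
            raise ValueError("no real root within the calibrated range")
        conc = min(in_range, key=lambda r: abs(r - (lo + hi) / 2))
    conc = float(conc) * dilution_factor
    below = (conc < loq) if loq is not None else None
    per_gram = None
    if extract_volume_ml is not None:
        per_gram = conc * extract_volume_ml / sample_mass_g
    return QuantResult(concentration=conc, below_loq=below, amount_per_gram=per_gram)


def recovery(
    measured_spiked: float, measured_base: float, expected_added: float
) -> tuple[float, bool]:
    """Percent spike recovery and whether it sits in the 80-120% pass band."""
    if expected_added <= 0:
        raise ValueError("expected_added must be positive")
    pct = 100.0 * (measured_spiked - measured_base) / expected_added
    return pct, 80.0 <= pct <= 120.0


def rsd(values: Sequence[float]) -> float:
    """Percent relative standard deviation (sample sd / mean * 100)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("mean is zero; RSD undefined")
    return float(100.0 * v.std(ddof=1) / mean)
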