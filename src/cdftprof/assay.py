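"""Ellman-assay inhibition math, 4-parameter-logistic IC50 fitting, and the
Scherrer crystallite-size utility.

Percent inhibition follows the Ellman colorimetric convention,
``(1 - A_sample/A_control) * 100``: zero when the sample absorbs like the
uninhibited control, 100 at complete inhibition.  IC50 estimation fits the
four-parameter logistic

    y(x) = bottom + (top - bottom) / (1 + (ic50 / x)^hill)

to (dose, % inhibition) data by nonlinear least squares.  The Hill slope is
free; ``ic50`` is constrained positive.  A fit that does not converge is
returned with ``converged=False`` and diagnostics, never silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponse",
    "Ic50Fit",
    "percent_inhibition",
    "four_pl",
    "fit_ic50",
    "scherrer_size",
]


@dataclass(frozen=True)
class DoseResponse:
    """A dose-response series: doses in µg/mL, responses in % inhibition."""

    concentrations: tuple[float, ...]
    inhibition_pct: tuple[float, ...]
    replicate_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.inhibition_pct):
            raise ValueError("concentrations and inhibition_pct must have equal length")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")
        cs = sorted(self.concentrations)
        if any(a >= b for a, b in zip(cs, cs[1:])):
            raise ValueError("concentrations must be distinct")

    def sorted_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(self.concentrations)
        return (np.asarray(self.concentrations, float)[order],
                np.asarray(self.inhibition_pct, float)[order])


@dataclass(frozen=True)
class Ic50Fit:
    """Result of a 4PL dose-response fit."""

    ic50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    method: str = "4PL nonlinear least squares"
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and not math.isfinite(self.rss):
            raise ValueError("converged fit must carry a finite rss")


def percent_inhibition(abs_sample: float, abs_control: float) -> float:
    """Ellman percent inhibition: (1 - A_sample/A_control) * 100."""
    if abs_control <= 0:
        raise ValueError(f"control absorbance must be positive, got {abs_control}")
    if abs_sample < 0:
        raise ValueError(f"sample absorbance must be non-negative, got {abs_sample}")
    return (1.0 - abs_sample / abs_control) * 100.0


def four_pl(x: np.ndarray, bottom: float, top: float, ic50: float, hill: float) -> np.ndarray:
    """The four-parameter logistic in its IC50 parametrisation."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / x) ** hill)


def fit_ic50(dr: DoseResponse) -> Ic50Fit:
    """Fit the 4PL model to a dose-response series.

    Initialisation: bottom = min(y), top = max(y), ic50 = geometric median
    dose, hill = 1.  Requires at least four distinct doses so the four
    parameters are identifiable.
    """
    x, y = dr.sorted_arrays()
    if len(np.unique(x)) < 4:
        raise ValueError(
            f"4PL fit needs >= 4 distinct concentrations, got {len(np.unique(x))}"
        )
    p0 = [float(y.min()), float(y.max()), float(np.exp(np.median(np.log(x)))), 1.0]
    bounds = ([-np.inf, -np.inf, 1e-12, 1e-6], [np.inf, np.inf, np.inf, np.inf])
    try:
        popt, _ = curve_fit(four_pl, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return Ic50Fit(ic50=p0[2], hill=1.0, top=p0[1], bottom=p0[0],
                       rss=float("inf"), converged=False, message=str(exc))
    bottom, top, ic50, hill = (float(v) for v in popt)
    resid = y - four_pl(x, *popt)
    rss = float(np.dot(resid, resid))
    if not (math.isfinite(rss) and ic50 > 0):
        return Ic50Fit(ic50=max(ic50, 1e-12), hill=hill, top=top, bottom=bottom,
                       rss=float("inf"), converged=False,
                       message="optimizer returned a non-finite or non-positive solution")
    return Ic50Fit(ic50=ic50, hill=hill, top=top, bottom=bottom, rss=rss, converged=True)


def scherrer_size(fwhm_rad: float, theta_rad: float, wavelength_angstrom: float,
                  k: float = 0.9) -> float:
    """Scherrer crystallite size D = k·λ / (β·cosθ), returned in nm.

    ``fwhm_rad`` is the peak's full width at half maximum β in radians,
    ``theta_rad`` the Bragg angle θ (half of 2θ), ``wavelength_angstrom``
    the X-ray wavelength λ in Å, and ``k`` the dimensionless shape factor.
    """
    if fwhm_rad <= 0:
        raise ValueError(f"FWHM must be positive, got {fwhm_rad}")
    if not 0 < theta_rad < math.pi / 2:
        raise ValueError(f"theta must lie in (0, pi/2), got {theta_rad}")
    d_angstrom = k * wavelength_angstrom / (fwhm_rad * math.cos(theta_rad))
    return d_angstrom / 10.0
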