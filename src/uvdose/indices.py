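"""Empirical dose-adjustment indices sigma and rho.

Across vessels, the half-effect UV dose D_1/2 follows two empirical
regularities:

* log10(D_1/2) is linear in log10(S)  ->  a power law in the growth
  area; sigma = k1 * D * S**0.687 is constant across vessels at equal
  biological effect (default exponent from a four-vessel calibration).
* log10(D_1/2) is linear in r = h/2a  ->  an exponential in the aspect
  ratio; rho = k2 * D / 5.0**r (default base likewise).

``sigma`` has the awkward dimension mJ * cm^-1.374 when k1 = 1; ``rho``
stays in mJ/cm^2.  The standardization constants k1, k2 rescale either
index so a chosen reference vessel's index equals its set dose.

Two usage modes: the printed constants (exponent 0.687, base 5.0) for
compatibility with the published calibration, or a user recalibration via
:func:`calibrate_log_log` / :func:`calibrate_semi_log` on their own
(vessel, D_1/2) panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .geometry import WellGeometry

__all__ = [
    "SIGMA_EXPONENT",
    "RHO_BASE",
    "CALIBRATED_AREA_RANGE",
    "IndexCalibration",
    "StandardizedIndex",
    "calibrate_log_log",
    "calibrate_semi_log",
    "sigma_index",
    "rho_index",
    "k1_for_reference",
    "k2_for_reference",
    "convert_dose",
]

#: exponent of the published area power law (sigma = D * S**0.687)
SIGMA_EXPONENT = 0.687
#: base of the published aspect-ratio exponential (rho = D / 5.0**r)
RHO_BASE = 5.0
#: growth-area range (cm^2) spanned by the original four-vessel calibration
CALIBRATED_AREA_RANGE = (0.31, 8.87)


@dataclass(frozen=True)
class IndexCalibration:
    """An OLS calibration of log10(D_1/2) against log10(S) or r.

    ``model_type`` is "log-log" (area power law) or "semi-log"
    (aspect-ratio exponential).  ``sigma_exponent`` (= -slope) is defined
    for the log-log model; ``rho_base`` (= 10**slope) for the semi-log
    model.
    """

    model_type: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.model_type not in ("log-log", "semi-log"):
            raise ValidationError(f"unknown model type {self.model_type!r}")

    @property
    def sigma_exponent(self) -> float:
        if self.model_type != "log-log":
            raise ValidationError("sigma exponent is defined by the log-log model")
        return -self.slope

    @property
    def rho_base(self) -> float:
        if self.model_type != "semi-log":
            raise ValidationError("rho base is defined by the semi-log model")
        return 10.0**self.slope

    def predict_d_half(self, x) -> np.ndarray:
        """D_1/2 predicted at S (log-log) or r (semi-log) values ``x``."""
        x = np.asarray(x, dtype=float)
        if self.model_type == "log-log":
            return 10.0**self.intercept * x**self.slope
        return 10.0 ** (self.slope * x + self.intercept)


@dataclass(frozen=True)
class StandardizedIndex:
    """k1/k2 pair anchoring sigma and rho to a reference vessel's set dose."""

    k1: float
    k2: float
    reference_vessel: str

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValidationError("k1 and k2 must be > 0")


def _check_pairs(x, d_half, what: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    d = np.asarray(d_half, dtype=float)
    if x.shape != d.shape:
        raise ValidationError(f"{what} and D_1/2 arrays must have equal length")
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 ({what}, D_1/2) pairs, got {x.size}")
    if np.any(d <= 0):
        raise ValidationError("D_1/2 values must be > 0")
    return x, d


def calibrate_log_log(surface_areas, d_half_values) -> IndexCalibration:
    """OLS of log10(D_1/2) on log10(S): calibrates the sigma power law."""
    s, d = _check_pairs(surface_areas, d_half_values, "S")
    if np.any(s <= 0):
        raise ValidationError("surface areas must be > 0")
    res = stats.linregress(np.log10(s), np.log10(d))
    return IndexCalibration(
        model_type="log-log",
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=s.size,
    )


def calibrate_semi_log(aspect_ratios, d_half_values) -> IndexCalibration:
    """OLS of log10(D_1/2) on r: calibrates the rho exponential."""
    r, d = _check_pairs(aspect_ratios, d_half_values, "r")
    res = stats.linregress(r, np.log10(d))
    return IndexCalibration(
        model_type="semi-log",
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=r.size,
    )


def _warn_if_outside_range(surface_area: float) -> None:
    lo, hi = CALIBRATED_AREA_RANGE
    if not (lo <= surface_area <= hi):
        warnings.warn(
            f"S = {surface_area:.4g} cm^2 lies outside the calibrated range "
            f"[{lo}, {hi}] cm^2; the power-law adjustment is an extrapolation",
            UserWarning,
            stacklevel=3,
        )


def sigma_index(dose, surface_area: float, exponent: float = SIGMA_EXPONENT, k1: float = 1.0):
    """Area-adjusted dose sigma = k1 * D * S**exponent.

    Units mJ * cm^(2*exponent - 2) when k1 = 1 (mJ cm^-1.374 at the
    default exponent).  Linear in D; sigma(D, S=1) = k1 * D.
    """
    if surface_area <= 0:
        raise ValidationError("surface area must be > 0")
    if np.any(np.asarray(dose, dtype=float) < 0):
        raise ValidationError("dose must be >= 0")
    _warn_if_outside_range(surface_area)
    return k1 * np.asarray(dose, dtype=float) * surface_area**exponent


def rho_index(dose, aspect_ratio: float, base: float = RHO_BASE, k2: float = 1.0):
    """Aspect-ratio-adjusted dose rho = k2 * D / base**r, in mJ/cm^2.

    Linear in D; rho(D, r=0) = k2 * D (a wall of zero height adjusts
    nothing).
    """
    if base <= 0:
        raise ValidationError("base must be > 0")
    if np.any(np.asarray(dose, dtype=float) < 0):
        raise ValidationError("dose must be >= 0")
    return k2 * np.asarray(dose, dtype=float) / base**aspect_ratio


def k1_for_reference(surface_area_ref: float, exponent: float = SIGMA_EXPONENT) -> float:
    """k1 = 1 / S_ref**exponent, making sigma(reference vessel) equal D."""
    if surface_area_ref <= 0:
        raise ValidationError("reference surface area must be > 0")
    return 1.0 / surface_area_ref**exponent


def k2_for_reference(aspect_ratio_ref: float, base: float = RHO_BASE) -> float:
    """k2 = base**r_ref, making rho(reference vessel) equal D."""
    if base <= 0:
        raise ValidationError("base must be > 0")
    if aspect_ratio_ref < 0:
        raise ValidationError("reference aspect ratio must be >= 0")
    return base**aspect_ratio_ref


def convert_dose(
    dose,
    source: WellGeometry,
    target: WellGeometry,
    index: str = "sigma",
    exponent: float = SIGMA_EXPONENT,
    base: float = RHO_BASE,
):
    """Set dose on ``target`` producing the same adjusted index as ``dose``
    set on ``source``.

    sigma mode: D_target = D * (S_source / S_target)**exponent;
    rho mode:   D_target = D * base**(r_target - r_source).
    The standardization constants cancel, so none are needed.  Converting
    a vessel to itself returns the dose unchanged.
    """
    if index == "sigma":
        _warn_if_outside_range(source.surface_area)
        _warn_if_outside_range(target.surface_area)
        return np.asarray(dose, dtype=float) * (
            source.surface_area / target.surface_area
        ) ** exponent
    if index == "rho":
        return np.asarray(dose, dtype=float) * base ** (
            target.aspect_ratio - source.aspect_ratio
        )
    raise ValidationError(f"index must be 'sigma' or 'rho', got {index!r}")
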