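"""Beer-Lambert attenuation of 302 nm light by culture medium.

Decadic convention throughout: ``T = 10**(-A)`` and ``A = eps * c * l``
with concentration ``c`` measured *relative* to the undiluted medium
(undiluted = 1), so the absorptivity ``eps`` carries units cm^-1 at c = 1
and is not molar.  The packaged default ``eps = 0.1695 /cm`` is the
measured value for keratinocyte growth medium (HuMedia-KG2) at 302 nm,
but every operation takes eps explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "DEFAULT_ABSORPTIVITY",
    "MediumOptics",
    "DilutionSeries",
    "AbsorptivityFit",
    "transmittance_from_absorbance",
    "absorbance_from_transmittance",
    "fit_absorptivity",
    "attenuation_factor",
]

#: decadic absorptivity of undiluted HuMedia-KG2 at 302 nm, per cm
DEFAULT_ABSORPTIVITY = 0.1695


@dataclass(frozen=True)
class MediumOptics:
    """Optical properties of the culture medium at the working wavelength."""

    absorptivity: float = DEFAULT_ABSORPTIVITY
    wavelength_nm: float = 302.0

    def __post_init__(self) -> None:
        if self.absorptivity < 0:
            raise ValidationError(f"absorptivity must be >= 0, got {self.absorptivity}")

    def attenuation(self, path_length: float) -> float:
        """Fraction of light transmitted through ``path_length`` cm of medium."""
        return attenuation_factor(self.absorptivity, path_length)


@dataclass(frozen=True)
class DilutionSeries:
    """A serial-dilution absorbance table measured in a cuvette.

    ``concentrations`` are relative to the undiluted sample (in (0, 1]);
    ``absorbances`` are decadic; ``path_length`` is the cuvette path in cm.
    """

    concentrations: tuple[float, ...]
    absorbances: tuple[float, ...]
    path_length: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if c.shape != a.shape:
            raise ValidationError("concentrations and absorbances must have equal length")
        if c.size < 2:
            raise InsufficientDataError("at least 2 dilution points are required")
        if np.any(c <= 0):
            raise ValidationError("relative concentrations must be strictly positive")
        if self.path_length <= 0:
            raise ValidationError("cuvette path length must be > 0")


@dataclass(frozen=True)
class AbsorptivityFit:
    """Origin-constrained regression result: A = eps * (c * l)."""

    absorptivity: float
    r_squared: float
    n_points: int


def transmittance_from_absorbance(absorbance):
    """Decadic transmittance T = 10**(-A), in [0, 1] for A >= 0."""
    a = np.asarray(absorbance, dtype=float)
    if np.any(a < 0):
        raise ValidationError("absorbance must be >= 0")
    t = 10.0 ** (-a)
    return float(t) if np.isscalar(absorbance) else t


def absorbance_from_transmittance(transmittance):
    """Inverse of :func:`transmittance_from_absorbance`: A = -log10(T)."""
    t = np.asarray(transmittance, dtype=float)
    if np.any((t <= 0) | (t > 1)):
        raise ValidationError("transmittance must lie in (0, 1]")
    a = -np.log10(t)
    return float(a) if np.isscalar(transmittance) else a


def fit_absorptivity(series: DilutionSeries) -> AbsorptivityFit:
    """Estimate eps from a dilution series by regression through the origin.

    The slope of A against c*l constrained through zero has the closed form
    sum(x*y)/sum(x*x); the intercept is pinned at 0 because a blank
    (c = 0) transmits fully by construction.  R^2 is the uncentered
    coefficient of determination appropriate for a through-origin fit.
    """
    x = np.asarray(series.concentrations, dtype=float) * series.path_length
    y = np.asarray(series.absorbances, dtype=float)
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise InsufficientDataError("all concentration*path products are zero; singular fit")
    eps = float(np.dot(x, y)) / sxx
    resid = y - eps * x
    ss_tot = float(np.dot(y, y))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.dot(resid, resid)) / ss_tot
    return AbsorptivityFit(absorptivity=eps, r_squared=r2, n_points=x.size)


def attenuation_factor(absorptivity: float, path_length) -> float:
    """Transmitted fraction 10**(-eps * l) along a path of ``path_length`` cm.

    Multiplicative over concatenated paths:
    ``factor(l1) * factor(l2) == factor(l1 + l2)``.
    """
    if absorptivity < 0:
        raise ValidationError("absorptivity must be >= 0")
    p = np.asarray(path_length, dtype=float)
    if np.any(p < 0):
        raise ValidationError("path length must be >= 0")
    f = 10.0 ** (-absorptivity * p)
    return float(f) if np.isscalar(path_length) else f
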