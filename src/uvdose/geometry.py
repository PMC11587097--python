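"""Culture-vessel and exposure-chamber geometry.

A cylindrical well is described by its growth-area diameter ``2a``, wall
height ``h`` and medium volume ``v``; everything else is derived:

* growth surface area ``S = pi * a**2`` (cm^2),
* aspect ratio ``r = h / 2a`` (dimensionless) — the variable that governs
  how much oblique light the wall blocks,
* medium depth ``l = v / S`` (cm).

The chamber is the reflective UV-crosslinker cavity; the only chamber
quantity used downstream is the ceiling height ``H`` entering the
point-source solid angle ``Omega = S / ((H - delta)**2 + a**2)``, where
``delta`` raises the vessel rim above the chamber floor (stacked dishes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import MediumOverflowError, ValidationError

__all__ = [
    "WellGeometry",
    "ChamberGeometry",
    "derive_geometry",
    "solid_angle",
    "msr_to_sr",
    "sr_to_msr",
]

#: millisteradians per steradian
MSR_PER_SR = 1000.0


@dataclass(frozen=True)
class WellGeometry:
    """A cylindrical culture vessel with derived geometric quantities.

    Lengths in cm, areas in cm^2, volumes in mL (= cm^3).
    """

    name: str
    diameter: float
    wall_height: float
    medium_volume: float
    seeding_cells: float | None = None

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise ValidationError(f"{self.name}: diameter must be > 0, got {self.diameter}")
        if not (self.wall_height > 0):
            raise ValidationError(f"{self.name}: wall height must be > 0, got {self.wall_height}")
        if self.medium_volume < 0:
            raise ValidationError(
                f"{self.name}: medium volume must be >= 0, got {self.medium_volume}"
            )
        if self.medium_depth > self.wall_height * (1 + 1e-12):
            raise MediumOverflowError(
                f"{self.name}: medium depth {self.medium_depth:.4g} cm exceeds "
                f"wall height {self.wall_height:.4g} cm"
            )

    @property
    def radius(self) -> float:
        """Growth-area radius a (cm)."""
        return self.diameter / 2.0

    @property
    def surface_area(self) -> float:
        """Growth surface area S = pi a^2 (cm^2)."""
        return math.pi * self.radius**2

    @property
    def aspect_ratio(self) -> float:
        """Height-to-diameter ratio r = h / 2a."""
        return self.wall_height / self.diameter

    @property
    def medium_depth(self) -> float:
        """Medium column height l = v / S (cm)."""
        return self.medium_volume / self.surface_area

    @property
    def seeding_density(self) -> float | None:
        """Initial cell density N0 / S (cells per cm^2), if N0 was given."""
        if self.seeding_cells is None:
            return None
        return self.seeding_cells / self.surface_area

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "diameter_cm": self.diameter,
            "wall_height_cm": self.wall_height,
            "medium_volume_ml": self.medium_volume,
            "radius_cm": self.radius,
            "surface_area_cm2": self.surface_area,
            "aspect_ratio": self.aspect_ratio,
            "medium_depth_cm": self.medium_depth,
        }
        if self.seeding_cells is not None:
            d["seeding_cells"] = self.seeding_cells
            d["seeding_density_per_cm2"] = self.seeding_density
        return d


@dataclass(frozen=True)
class ChamberGeometry:
    """The UV exposure chamber (a reflective box with ceiling lamps).

    Defaults are the CL-1000 cavity: 25.4 x 30.5 x 12.7 cm.
    ``platform_offset`` (delta, cm) is the height of the vessel rim
    reference above the chamber floor, e.g. the cumulative height of a
    stack of dishes.
    """

    width: float = 25.4
    depth: float = 30.5
    height: float = 12.7
    platform_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.platform_offset < self.height):
            raise ValidationError(
                f"platform offset must satisfy 0 <= delta < H={self.height}, "
                f"got {self.platform_offset}"
            )


def derive_geometry(
    name: str,
    diameter: float,
    wall_height: float,
    medium_volume: float,
    seeding_cells: float | None = None,
) -> WellGeometry:
    """Build a :class:`WellGeometry`, validating and deriving all fields.

    Raises
    ------
    ValidationError
        On non-positive diameter/height or negative volume.
    MediumOverflowError
        If the implied medium depth v/S exceeds the wall height.
    """
    return WellGeometry(name, diameter, wall_height, medium_volume, seeding_cells)


def solid_angle(
    surface_area: float,
    radius: float,
    chamber: ChamberGeometry | None = None,
    delta: float | None = None,
) -> float:
    """Solid angle (msr) of the growth area seen from a ceiling point source.

    Omega = S / ((H - delta)^2 + a^2), treating the lamp as a point at the
    chamber ceiling directly above the vessel, with the rim raised ``delta``
    above the floor.  This quantity is *diagnostic only*: the point-source
    picture is contradicted by the observation that the biological response
    does not change with lamp distance, which is why the effective-dose
    model assumes an isotropic radiance field instead.

    Parameters
    ----------
    surface_area : growth area S, cm^2.
    radius : growth-area radius a, cm.
    chamber : chamber geometry; CL-1000 defaults if omitted.
    delta : override for the chamber's platform offset (cm), e.g. the
        cumulative height of a dish stack.
    """
    chamber = chamber or ChamberGeometry()
    d = chamber.platform_offset if delta is None else delta
    if not (0.0 <= d < chamber.height):
        raise ValidationError(f"delta must satisfy 0 <= delta < H={chamber.height}, got {d}")
    if surface_area < 0:
        raise ValidationError("surface area must be >= 0")
    omega_sr = surface_area / ((chamber.height - d) ** 2 + radius**2)
    return omega_sr * MSR_PER_SR


def msr_to_sr(omega_msr: float) -> float:
    return omega_msr / MSR_PER_SR


def sr_to_msr(omega_sr: float) -> float:
    return omega_sr * MSR_PER_SR
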