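"""Physical parameters and well geometry.

Everything the solver needs is geometric (well radius, media depth, slice
radius and the heights ``h1 < h2`` of its lower and upper faces) or a
transport coefficient (oxygen diffusivity in the culture media ``D1`` and in
the tissue ``D2``, and a first-order volumetric uptake rate ``V``).  All
internal quantities are SI (metres, seconds); oxygen levels are carried as
partial pressures in mmHg throughout, with no solubility conversion.

Coordinates: ``z`` is measured upward from the well bottom, ``z in [0, H]``
with ``H`` the media depth; ``r in [0, r_o]`` with ``r_o`` the well radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "WellSystem",
    "TransportParams",
    "SurfaceOxygen",
    "InvalidGeometryError",
    "media_depth_from_volume",
    "surface_partial_pressure",
    "standard_placements",
    "default_parameters",
    "TOP_CLEARANCE",
    "ATMOSPHERIC_O2_FRACTION",
    "ATMOSPHERIC_O2_MMHG",
]

#: Gap left between the slice top and the media surface for the "top of well"
#: placement: one micron below the surface.
TOP_CLEARANCE = 1.0e-6  # [m]

ATMOSPHERIC_O2_FRACTION = 0.21
ATMOSPHERIC_O2_MMHG = 160.0


class InvalidGeometryError(ValueError):
    """Raised when well/slice dimensions are inconsistent."""


@dataclass(frozen=True)
class WellSystem:
    """Geometry of one well plus the slice placement inside it.

    Parameters
    ----------
    well_radius : float
        Inner radius of the well ``r_o`` [m].
    media_depth : float
        Depth of the culture media ``H`` [m], measured from the well bottom.
    slice_radius : float
        Radius of the tissue disc ``r_T`` [m].  Must satisfy
        ``0 < r_T <= r_o``; equality means the slice spans the whole well
        cross-section, in which case the oxygen field is purely
        one-dimensional in ``z``.
    h1, h2 : float
        Heights of the bottom and top faces of the slice [m],
        ``0 <= h1 < h2 < H``.
    well_depth : float, optional
        Physical depth of the well [m]; must be at least ``media_depth``.
    media_volume : float, optional
        Volume of media [m^3] the depth was derived from, if any.
    """

    well_radius: float
    media_depth: float
    slice_radius: float
    h1: float
    h2: float
    well_depth: float | None = None
    media_volume: float | None = None

    def __post_init__(self) -> None:
        r_o, H = self.well_radius, self.media_depth
        if r_o <= 0.0:
            raise InvalidGeometryError(f"well_radius must be positive, got {r_o}")
        if H <= 0.0:
            raise InvalidGeometryError(f"media_depth must be positive, got {H}")
        if not 0.0 < self.slice_radius <= r_o:
            raise InvalidGeometryError(
                f"slice_radius must lie in (0, well_radius]; got "
                f"{self.slice_radius} with well_radius {r_o}"
            )
        if not 0.0 <= self.h1 < self.h2:
            raise InvalidGeometryError(
                f"slice faces must satisfy 0 <= h1 < h2; got h1={self.h1}, h2={self.h2}"
            )
        if self.h2 >= H:
            raise InvalidGeometryError(
                f"slice top h2={self.h2} must lie strictly below the media surface H={H}"
            )
        if self.well_depth is not None and self.well_depth < H:
            raise InvalidGeometryError(
                f"well_depth {self.well_depth} shallower than media depth {H}"
            )

    @property
    def thickness(self) -> float:
        """Slice thickness ``h2 - h1`` [m]."""
        return self.h2 - self.h1

    @property
    def full_span(self) -> bool:
        """True when the slice spans the entire well cross-section (r_T = r_o)."""
        return self.slice_radius >= self.well_radius * (1.0 - 1e-12)

    def with_placement(self, h1: float, h2: float | None = None) -> "WellSystem":
        """Return a copy with the slice moved to ``[h1, h2]`` (same thickness
        if ``h2`` is omitted)."""
        if h2 is None:
            h2 = h1 + self.thickness
        return replace(self, h1=h1, h2=h2)

    def with_media_depth(self, media_depth: float, *, keep_placement: bool = False,
                         media_volume: float | None = None) -> "WellSystem":
        """Return a copy with a new media depth.

        Unless ``keep_placement`` is set, the slice is re-seated at the top of
        the well (its default position for media-volume sweeps).
        """
        if keep_placement:
            return replace(self, media_depth=media_depth, media_volume=media_volume)
        t = self.thickness
        h2 = media_depth - TOP_CLEARANCE
        h1 = h2 - t
        if h1 < 0.0:
            raise InvalidGeometryError(
                f"media depth {media_depth} too shallow for a {t} m slice"
            )
        return replace(self, media_depth=media_depth, h1=h1, h2=h2,
                       media_volume=media_volume)


@dataclass(frozen=True)
class TransportParams:
    """Oxygen transport coefficients.

    ``d_media`` (D1) and ``d_tissue`` (D2) are diffusivities [m^2/s];
    ``uptake_rate`` (V) is the first-order consumption rate in the tissue
    [1/s].  The derived absorption wavenumber ``k = sqrt(V/D2)`` [1/m]
    separates vertically trapped modes (eigenvalue below k, hyperbolic inside
    the tissue) from free modes (oscillatory throughout).
    """

    d_media: float
    d_tissue: float
    uptake_rate: float

    def __post_init__(self) -> None:
        if self.d_media <= 0.0 or self.d_tissue <= 0.0:
            raise ValueError("diffusivities must be positive")
        if self.uptake_rate < 0.0:
            raise ValueError("uptake_rate must be non-negative")

    @property
    def k(self) -> float:
        """Absorption wavenumber sqrt(V/D2) [1/m]."""
        return math.sqrt(self.uptake_rate / self.d_tissue)


@dataclass(frozen=True)
class SurfaceOxygen:
    """Oxygen condition imposed at the media surface.

    ``phi0`` is the partial pressure [mmHg] applied as the Dirichlet value at
    ``z = H``; ``oxygen_fraction`` is the incubator O2 fraction it derives
    from (atmospheric 0.21 maps to 160 mmHg, other fractions scale linearly).
    """

    oxygen_fraction: float
    phi0: float

    @classmethod
    def from_fraction(cls, oxygen_fraction: float) -> "SurfaceOxygen":
        return cls(oxygen_fraction, surface_partial_pressure(oxygen_fraction))


def media_depth_from_volume(media_volume: float, well_radius: float) -> float:
    """Media depth ``H = volume / (pi r_o^2)`` [m] of a cylindrical well.

    Parameters are in SI units (m^3 and m).
    """
    if well_radius <= 0.0:
        raise InvalidGeometryError(f"well_radius must be positive, got {well_radius}")
    if media_volume < 0.0:
        raise InvalidGeometryError(f"media_volume must be non-negative, got {media_volume}")
    return media_volume / (math.pi * well_radius**2)


def surface_partial_pressure(oxygen_fraction: float) -> float:
    """Surface oxygen partial pressure [mmHg] for an incubator O2 fraction.

    Uses the linear partial-pressure scaling anchored at atmospheric
    conditions: 21% O2 corresponds to 160 mmHg.
    """
    if not 0.0 <= oxygen_fraction <= 1.0:
        raise ValueError(f"oxygen_fraction must lie in [0, 1], got {oxygen_fraction}")
    return ATMOSPHERIC_O2_MMHG * oxygen_fraction / ATMOSPHERIC_O2_FRACTION


def standard_placements(media_depth: float, thickness: float) -> dict[str, tuple[float, float]]:
    """The three named slice placements: resting on the well bottom, centred
    mid-column, and with its top face one micron below the media surface.

    Returns a dict ``{"bottom": (h1, h2), "middle": ..., "top": ...}`` in
    metres.
    """
    H, t = media_depth, thickness
    if t <= 0.0:
        raise InvalidGeometryError(f"thickness must be positive, got {t}")
    if t + TOP_CLEARANCE >= H:
        raise InvalidGeometryError(
            f"slice thickness {t} does not fit below the surface of {H} m of media"
        )
    return {
        "bottom": (0.0, t),
        "middle": ((H - t) / 2.0, (H + t) / 2.0),
        "top": (H - TOP_CLEARANCE - t, H - TOP_CLEARANCE),
    }


def default_parameters(
    slice_diameter: float = 5.0e-3,
    placement: str = "middle",
) -> tuple[WellSystem, TransportParams]:
    """Reference 12-well-plate configuration.

    22.1 mm well diameter, 3.4 mm media depth (1.3 ml of media), a 250 um
    thick slice of 5 mm or 8 mm diameter, media diffusivity 4.85e-9 m^2/s,
    tissue diffusivity 1.6e-9 m^2/s and uptake rate 0.057 1/s.
    """
    H = 3.4e-3
    thickness = 2.5e-4
    placements = standard_placements(H, thickness)
    if placement not in placements:
        raise ValueError(f"placement must be one of {sorted(placements)}, got {placement!r}")
    h1, h2 = placements[placement]
    system = WellSystem(
        well_radius=22.1e-3 / 2.0,
        well_depth=17.5e-3,
        media_depth=H,
        media_volume=1.3e-6,
        slice_radius=slice_diameter / 2.0,
        h1=h1,
        h2=h2,
    )
    transport = TransportParams(d_media=4.85e-9, d_tissue=1.6e-9, uptake_rate=0.057)
    return system, transport
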