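"""Cylindrical equal-area map projection on a spherical Earth.

The analysis grid needs a projection in which congruent squares have equal
geographic area, so that a 100 km cell at 50° latitude samples the same
area as one at the equator.  The Lambert cylindrical equal-area family has
that property exactly on the sphere and tiles trivially with squares:

    x = R cos(phi_s) (lambda - lambda_0)
    y = R sin(phi) / cos(phi_s)

with ``phi_s`` the standard parallel and ``lambda_0`` the central meridian
(angles in radians inside the formulas).  Area distortion is zero
everywhere; shape distortion grows away from ``phi_s``, which is harmless
here because only areas and planar distances between cell centers enter
the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class CylindricalEqualArea:
    """Equal-area cylindrical projection with a configurable standard parallel.

    Parameters
    ----------
    standard_parallel : float
        Latitude (degrees) at which the projection is free of shape
        distortion.  Default 30°, a conventional compromise for a domain
        spanning both hemispheres.
    central_meridian : float
        Longitude (degrees) mapped to x = 0.
    radius_km : float
        Spherical Earth radius in km.
    """

    standard_parallel: float = 30.0
    central_meridian: float = -77.5
    radius_km: float = EARTH_RADIUS_KM

    @property
    def _cos_sp(self) -> float:
        return math.cos(math.radians(self.standard_parallel))

    def forward(self, lon, lat):
        """Project geographic coordinates (degrees) to planar metres."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude outside [-90, 90]")
        r_m = self.radius_km * 1000.0
        x = r_m * self._cos_sp * np.radians(lon - self.central_meridian)
        y = r_m * np.sin(np.radians(lat)) / self._cos_sp
        return x, y

    def inverse(self, x, y):
        """Planar metres back to geographic degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r_m = self.radius_km * 1000.0
        lon = np.degrees(x / (r_m * self._cos_sp)) + self.central_meridian
        s = y * self._cos_sp / r_m
        if np.any(np.abs(s) > 1.0 + 1e-12):
            raise ValueError("y coordinate outside the projectable range")
        lat = np.degrees(np.arcsin(np.clip(s, -1.0, 1.0)))
        return lon, lat


def spherical_quad_area_km2(
    lon_min: float, lon_max: float, lat_min: float, lat_max: float,
    radius_km: float = EARTH_RADIUS_KM,
) -> float:
    """Exact spherical area (km²) of a lon/lat-aligned quadrangle.

    Independent of any projection: the area between two parallels and two
    meridians on a sphere is R² Δλ (sin φ₂ − sin φ₁) with Δλ in radians.
    """
    dlam = math.radians(lon_max - lon_min)
    return radius_km**2 * dlam * (
        math.sin(math.radians(lat_max)) - math.sin(math.radians(lat_min))
    )
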