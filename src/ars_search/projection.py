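"""Local tangent-plane projection between WGS84 lon/lat and planar meters.

Tracks analysed here span a few kilometres, so a spherical azimuthal
equidistant projection centred on the track is ample: planar distances
between points within ~10 km of the centre differ from geodesic distances
by far less than GPS error, and the forward/inverse pair is closed-form,
so round-trips are exact to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Mean Earth radius in meters (IUGG R1 for the WGS84 ellipsoid).
EARTH_RADIUS_M = 6371008.8


@dataclass(frozen=True)
class LocalProjection:
    """Azimuthal equidistant projection about a center (lon0, lat0), degrees."""

    lon0: float
    lat0: float
    radius: float = EARTH_RADIUS_M

    def forward(self, lon, lat):
        """Project lon/lat (degrees) to local x/y (meters east/north)."""
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        lam0, phi0 = np.radians(self.lon0), np.radians(self.lat0)

        cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k = c / sin(c), with the removable singularity at the center.
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = self.radius * k * np.cos(phi) * np.sin(lam - lam0)
        y = self.radius * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
        )
        return x, y

    def inverse(self, x, y):
        """Map local x/y (meters) back to lon/lat in degrees."""
        x = np.asarray(x, dtype=float) / self.radius
        y = np.asarray(y, dtype=float) / self.radius
        lam0, phi0 = np.radians(self.lon0), np.radians(self.lat0)

        c = np.hypot(x, y)
        safe_c = np.where(c > 1e-12, c, 1.0)
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.arcsin(
            np.clip(cos_c * np.sin(phi0) + np.where(c > 1e-12, y * sin_c / safe_c, 0.0) * np.cos(phi0), -1.0, 1.0)
        )
        lam = lam0 + np.arctan2(
            x * sin_c, safe_c * np.cos(phi0) * cos_c - y * np.sin(phi0) * sin_c
        )
        lam = np.where(c > 1e-12, lam, lam0)
        phi = np.where(c > 1e-12, phi, phi0)
        return np.degrees(lam), np.degrees(phi)
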