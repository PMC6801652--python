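"""WGS84 <-> UTM coordinate conversion.

Metric grid cells need a metric CRS.  The study-area gridding therefore
works in projected metres, and geographic input is projected to the UTM
zone of the area centroid (e.g. the Catalan coast falls in UTM 31N).

The transverse-Mercator conversion uses the Krueger series on the WGS84
ellipsoid (sub-millimetre accuracy in-zone), so no external projection
library is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

# WGS84 ellipsoid
_A = 6378137.0                  # semi-major axis, m
_F = 1.0 / 298.257223563        # flattening
_K0 = 0.9996                    # UTM scale factor on the central meridian
_E0 = 500_000.0                 # false easting, m
_N0_SOUTH = 10_000_000.0        # false northing, southern hemisphere

_n = _F / (2.0 - _F)
_AA = _A / (1.0 + _n) * (1.0 + _n**2 / 4.0 + _n**4 / 64.0)  # rectifying radius
_ALPHA = (
    _n / 2.0 - 2.0 * _n**2 / 3.0 + 5.0 * _n**3 / 16.0,
    13.0 * _n**2 / 48.0 - 3.0 * _n**3 / 5.0,
    61.0 * _n**3 / 240.0,
)
_BETA = (
    _n / 2.0 - 2.0 * _n**2 / 3.0 + 37.0 * _n**3 / 96.0,
    _n**2 / 48.0 + _n**3 / 15.0,
    17.0 * _n**3 / 480.0,
)
_DELTA = (
    2.0 * _n - 2.0 * _n**2 / 3.0 - 2.0 * _n**3,
    7.0 * _n**2 / 3.0 - 8.0 * _n**3 / 5.0,
    56.0 * _n**3 / 15.0,
)


@dataclass(frozen=True)
class UtmZone:
    """A UTM zone identified by number and hemisphere."""

    number: int
    north: bool = True

    @property
    def epsg(self) -> int:
        return (32600 if self.north else 32700) + self.number

    @property
    def central_meridian_deg(self) -> float:
        return (self.number - 1) * 6.0 - 180.0 + 3.0

    def __str__(self) -> str:  # e.g. "31N"
        return f"{self.number}{'N' if self.north else 'S'}"


def utm_zone_for(lon: float, lat: float) -> UtmZone:
    """UTM zone containing a WGS84 point (standard 6-degree zones)."""
    if not -180.0 <= lon <= 180.0 or not -90.0 <= lat <= 90.0:
        raise ValueError(f"invalid WGS84 coordinate ({lon}, {lat})")
    number = int((lon + 180.0) // 6.0) + 1
    number = min(number, 60)
    return UtmZone(number=number, north=lat >= 0.0)


def to_utm(lon: float, lat: float, zone: UtmZone) -> tuple[float, float]:
    """Project a WGS84 point to UTM easting/northing in metres."""
    phi = math.radians(lat)
    lam = math.radians(lon - zone.central_meridian_deg)

    e2n = 2.0 * math.sqrt(_n) / (1.0 + _n)
    t = math.sinh(
        math.atanh(math.sin(phi)) - e2n * math.atanh(e2n * math.sin(phi))
    )
    xi = math.atan2(t, math.cos(lam))
    eta = math.atanh(math.sin(lam) / math.hypot(1.0, t))

    x = eta
    y = xi
    for j, a in enumerate(_ALPHA, start=1):
        x += a * math.cos(2 * j * xi) * math.sinh(2 * j * eta)
        y += a * math.sin(2 * j * xi) * math.cosh(2 * j * eta)

    easting = _E0 + _K0 * _AA * x
    northing = _K0 * _AA * y
    if not zone.north:
        northing += _N0_SOUTH
    return easting, northing


def from_utm(easting: float, northing: float, zone: UtmZone) -> tuple[float, float]:
    """Inverse-project UTM metres back to WGS84 (lon, lat)."""
    if not zone.north:
        northing -= _N0_SOUTH
    xi = northing / (_K0 * _AA)
    eta = (easting - _E0) / (_K0 * _AA)

    xi_p = xi
    eta_p = eta
    for j, b in enumerate(_BETA, start=1):
        xi_p -= b * math.sin(2 * j * xi) * math.cosh(2 * j * eta)
        eta_p -= b * math.cos(2 * j * xi) * math.sinh(2 * j * eta)

    chi = math.asin(math.sin(xi_p) / math.cosh(eta_p))
    phi = chi
    for j, d in enumerate(_DELTA, start=1):
        phi += d * math.sin(2 * j * chi)

    lam = math.atan2(math.sinh(eta_p), math.cos(xi_p))
    return zone.central_meridian_deg + math.degrees(lam), math.degrees(phi)
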