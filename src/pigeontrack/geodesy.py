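"""Great-circle geodesy primitives.

All distances are computed on a sphere of radius 6371.0088 km (the IUGG mean
Earth radius) with the haversine formula.  Every distance in the analysis is
below ~50 km, where the ellipsoidal correction is far smaller than GPS noise.

Conventions
-----------
* Coordinates are decimal degrees, WGS84 datum, latitude in [-90, 90],
  longitude in (-180, 180].
* Bearings are degrees clockwise from true north in [0, 360).
* Relative angles are wrapped to (-180, 180].
"""

from __future__ import annotations

import re

import numpy as np

EARTH_RADIUS_M = 6_371_008.8

__all__ = [
    "EARTH_RADIUS_M",
    "geo_distance",
    "geo_bearing",
    "destination",
    "wrap_angle",
    "parse_dms",
]


def geo_distance(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in meters.

    Accepts scalars or numpy arrays (broadcasting).  Symmetric, non-negative,
    and zero iff the points coincide (to numerical tolerance).
    """
    phi1, lam1, phi2, lam2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(a))


def geo_bearing(lat1, lon1, lat2, lon2, *, strict: bool = True):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360).

    With ``strict`` (the scalar default) coincident points raise ``ValueError``
    because the bearing is undefined; array inputs with ``strict=False`` return
    0.0 for coincident pairs (callers are expected to mask them).
    """
    phi1, lam1, phi2, lam2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    same = (phi1 == phi2) & (lam1 == lam2)
    if strict and np.any(same):
        raise ValueError("bearing undefined for coincident points")
    y = np.sin(lam2 - lam1) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(lam2 - lam1)
    theta = np.degrees(np.arctan2(y, x))
    out = np.mod(theta, 360.0)
    if out.ndim == 0:
        return float(out)
    return out


def destination(lat, lon, bearing_deg, distance_m):
    """Point reached from (lat, lon) along an initial ``bearing_deg`` for
    ``distance_m`` meters of great-circle arc.  Returns (lat, lon) degrees."""
    phi1 = np.radians(np.asarray(lat, dtype=float))
    lam1 = np.radians(np.asarray(lon, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_m, dtype=float) / EARTH_RADIUS_M
    phi2 = np.arcsin(np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta))
    lam2 = lam1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(phi1),
                             np.cos(delta) - np.sin(phi1) * np.sin(phi2))
    lat2 = np.degrees(phi2)
    lon2 = np.degrees((lam2 + np.pi) % (2.0 * np.pi) - np.pi)
    if lat2.ndim == 0:
        return float(lat2), float(lon2)
    return lat2, lon2


def wrap_angle(x):
    """Wrap an angle in degrees to (-180, 180].  x ≡ result (mod 360)."""
    w = np.mod(np.asarray(x, dtype=float), 360.0)
    out = np.where(w > 180.0, w - 360.0, w)
    if out.ndim == 0:
        return float(out)
    return out


_DMS_RE = re.compile(
    r"""\s*(?P<deg>\d+(?:\.\d+)?)\s*[°d]\s*
        (?:(?P<min>\d+(?:\.\d+)?)\s*[′'m]\s*)?
        (?:(?P<sec>\d+(?:\.\d+)?)\s*[″"s]\s*)?
        (?P<hemi>[NSEW])\s*""",
    re.VERBOSE,
)


def parse_dms(text: str) -> tuple[float, float]:
    """Parse a ``deg°min′sec″Hemisphere`` coordinate pair to decimal degrees.

    Example: ``"43°39′26″N, 10°18′14″E"`` → ``(43.657222..., 10.303888...)``.
    """
    matches = list(_DMS_RE.finditer(text))
    if len(matches) != 2:
        raise ValueError(f"expected two DMS coordinates in {text!r}")
    lat = lon = None
    for m in matches:
        value = float(m.group("deg"))
        value += float(m.group("min") or 0.0) / 60.0
        value += float(m.group("sec") or 0.0) / 3600.0
        hemi = m.group("hemi")
        if hemi in "SW":
            value = -value
        if hemi in "NS":
            lat = value
        else:
            lon = value
    if lat is None or lon is None:
        raise ValueError(f"need one latitude and one longitude in {text!r}")
    return lat, lon
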