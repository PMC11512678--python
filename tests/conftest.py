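"""Shared fixture helpers: deterministic geometric track constructions."""

import numpy as np
import pytest

from pigeontrack.geodesy import destination
from pigeontrack.model import Loft, Track

RELEASE = (43.70, 10.80)   # generic release point used by geometric fixtures


def track_at_distances(distances_m, bearing=0.0, release=RELEASE, speeds=None,
                       t0=0.0, dt=1.0, bird_id="bird", **labels):
    """Track whose fixes sit at the given distances along one bearing."""
    distances_m = np.asarray(distances_m, dtype=float)
    lat, lon = destination(release[0], release[1], bearing, distances_m)
    if speeds is None:
        speeds = np.full(distances_m.size, 60.0)
    t = t0 + dt * np.arange(distances_m.size, dtype=float)
    return Track(bird_id, np.atleast_1d(lat), np.atleast_1d(lon), t,
                 np.asarray(speeds, dtype=float), **labels)


def track_through_points(points, t0=0.0, dt=1.0, speeds=None, bird_id="bird",
                         **labels):
    """Track visiting explicit (lat, lon) waypoints at 1 fix per ``dt``."""
    pts = np.asarray(points, dtype=float)
    if speeds is None:
        speeds = np.full(len(pts), 60.0)
    t = t0 + dt * np.arange(len(pts), dtype=float)
    return Track(bird_id, pts[:, 0], pts[:, 1], t,
                 np.asarray(speeds, dtype=float), **labels)


@pytest.fixture
def release_point():
    return RELEASE


@pytest.fixture
def far_home():
    """A home loft ~34 km due west of the release point."""
    lat, lon = destination(RELEASE[0], RELEASE[1], 270.0, 34_200.0)
    return Loft(lat, lon)
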