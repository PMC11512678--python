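"""Core data containers for the track-analysis pipeline.

A :class:`Track` stores one bird's fix stream as parallel numpy arrays
(latitude, longitude, UTC epoch seconds, logger speed in km/h) plus the
design labels: the site the bird was released at, the site it had been
passively exposed to the day before, and the derived treatment group —
``experimental`` when exposure and release site coincide, ``control``
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

EXPERIMENTAL = "experimental"
CONTROL = "control"

#: TrackSegment / bird exclusion reasons
NO_EXCLUSION = "none"
FOLLOWING = "following"
NEVER_EXITED = "never_exited"
TOO_FEW_FIXES = "too_few_fixes"


@dataclass(frozen=True)
class Fix:
    """One timestamped GPS observation."""

    lat: float
    lon: float
    t: float        # UTC epoch seconds
    speed: float    # km/h, logger-reported

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 < self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside (-180, 180]")
        if self.speed < 0.0:
            raise ValueError(f"negative speed {self.speed}")


@dataclass(frozen=True)
class Site:
    """A release/exposure site with its home geometry."""

    site_id: str
    lat: float
    lon: float
    home_bearing: float      # degrees clockwise from true north, [0, 360)
    home_distance_km: float  # > 0

    def __post_init__(self):
        if not 0.0 <= self.home_bearing < 360.0:
            raise ValueError("home_bearing must be in [0, 360)")
        if self.home_distance_km <= 0.0:
            raise ValueError("home_distance_km must be positive")


@dataclass(frozen=True)
class Loft:
    """The home loft (fixed per study)."""

    lat: float
    lon: float


def infer_group(release_site: str, exposure_site: str) -> str:
    return EXPERIMENTAL if release_site == exposure_site else CONTROL


@dataclass
class Track:
    """Time-ordered fix stream for one bird with design labels."""

    bird_id: str
    lat: np.ndarray
    lon: np.ndarray
    t: np.ndarray
    speed: np.ndarray
    release_site: str = ""
    exposure_site: str = ""
    group: str = ""

    def __post_init__(self):
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        n = len(self.t)
        if not (len(self.lat) == len(self.lon) == len(self.speed) == n):
            raise ValueError("fix arrays must have equal length")
        if n < 2:
            raise ValueError(f"track {self.bird_id!r} needs >= 2 fixes, got {n}")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"track {self.bird_id!r}: timestamps not strictly increasing")
        if self.release_site and self.exposure_site:
            expected = infer_group(self.release_site, self.exposure_site)
            if not self.group:
                self.group = expected
            elif self.group != expected:
                raise ValueError(
                    f"track {self.bird_id!r}: group {self.group!r} inconsistent with "
                    f"release={self.release_site!r}, exposure={self.exposure_site!r}"
                )

    @property
    def n_fixes(self) -> int:
        return len(self.t)

    @property
    def release_time(self) -> float:
        """Timestamp of the first raw fix (proxy for the release instant)."""
        return float(self.t[0])

    def fixes(self) -> Iterator[Fix]:
        for la, lo, tt, sp in zip(self.lat, self.lon, self.t, self.speed):
            yield Fix(float(la), float(lo), float(tt), float(sp))

    def subset(self, index) -> "Track":
        """New Track restricted to ``index`` (slice or boolean/int array)."""
        return replace(self, lat=self.lat[index], lon=self.lon[index],
                       t=self.t[index], speed=self.speed[index])

    @classmethod
    def from_fixes(cls, bird_id: str, fixes, **labels) -> "Track":
        fixes = list(fixes)
        return cls(bird_id,
                   np.array([f.lat for f in fixes]),
                   np.array([f.lon for f in fixes]),
                   np.array([f.t for f in fixes]),
                   np.array([f.speed for f in fixes]),
                   **labels)


@dataclass
class TrackSegment:
    """The analysed section of a (cleaned) track at one analysis radius.

    The segment runs from the first fix beyond the escape radius to the fix
    with which the bird leaves ``radius`` of the release point for the final
    time; that exit fix (the first fix beyond the radius after the last
    inside fix) is the last element of the arrays.
    """

    bird_id: str
    radius: float
    lat: np.ndarray
    lon: np.ndarray
    t: np.ndarray
    speed: np.ndarray
    release_lat: float
    release_lon: float
    release_time: float           # first raw fix of the bird's track
    exit_index: int = -1          # index of the exit fix within the arrays
    excluded: str = NO_EXCLUSION  # none | following | never_exited | too_few_fixes

    @property
    def n_fixes(self) -> int:
        return len(self.t)

    @property
    def usable(self) -> bool:
        return self.excluded == NO_EXCLUSION


@dataclass(frozen=True)
class FollowingEvent:
    """A sustained close-proximity episode between two birds."""

    bird_a: str
    bird_b: str
    overlap_start: float
    overlap_end: float
    median_separation: float

    def __post_init__(self):
        if self.overlap_end <= self.overlap_start:
            raise ValueError("overlap_end must exceed overlap_start")
        if self.median_separation < 0:
            raise ValueError("median_separation must be >= 0")


@dataclass(frozen=True)
class MetricRecord:
    """The four per-bird navigation metrics at one analysis radius."""

    bird_id: str
    radius: float
    vanishing_time: float          # s
    mean_vector_length: float      # [0, 1]
    mean_direction: float          # degrees, home-relative, (-180, 180]
    efficiency_index: float        # (0, 1]
    homing_efficiency_index: float # [-1, 1]
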