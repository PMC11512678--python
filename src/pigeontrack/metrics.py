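"""The four per-bird navigation metrics.

For a segment between the escape-radius exit and the final exit from the
analysis radius:

* **virtual vanishing time** — seconds from release (first raw fix) to the
  exit fix;
* **mean vector length / direction** — resultant of the unit vectors of the
  home-relative step directions θᵢ = bearing(fixᵢ → fixᵢ₊₁) −
  bearing(fixᵢ → home), each wrapped to (−180°, 180°];
* **efficiency index** — straight-line distance between the segment's first
  and last (exit) fixes divided by the path length, in (0, 1];
* **homing efficiency index** — reduction in distance-to-home over the
  segment divided by the path length, in [−1, 1]; 1 means a straight flight
  toward home, negative values mean net movement away from it.

Both indices share the segment path length as denominator and are anchored
at the segment's first fix, which makes HEI ≤ EI an exact triangle-inequality
consequence and HEI = 1 exact for a straight homeward geodesic.  An optional
``anchor="release_point"`` variant anchors the homing index at the release
point instead; at a 500 m escape radius the two differ by at most a few
percent.
"""

from __future__ import annotations

import numpy as np

from .geodesy import geo_bearing, geo_distance, wrap_angle
from .model import Loft, MetricRecord, TrackSegment

__all__ = [
    "MetricUndefinedError", "step_directions", "mean_vector", "vanishing_time",
    "path_length", "efficiency_index", "homing_efficiency_index", "compute_metrics",
]


class MetricUndefinedError(ValueError):
    """The segment does not support the requested metric."""


def _require_usable(segment: TrackSegment):
    if not segment.usable or segment.n_fixes < 2:
        raise MetricUndefinedError(
            f"bird {segment.bird_id}: segment excluded ({segment.excluded}) "
            "or has fewer than 2 fixes")


def step_directions(segment: TrackSegment, home: Loft) -> np.ndarray:
    """Home-relative direction of every step, degrees in (−180, 180].

    Steps with zero displacement are skipped (their bearing is undefined);
    at least one valid step is required.
    """
    _require_usable(segment)
    la0, lo0 = segment.lat[:-1], segment.lon[:-1]
    la1, lo1 = segment.lat[1:], segment.lon[1:]
    disp = geo_distance(la0, lo0, la1, lo1)
    moved = disp > 0.0
    if not np.any(moved):
        raise MetricUndefinedError(f"bird {segment.bird_id}: no non-zero step")
    step_bearing = geo_bearing(la0[moved], lo0[moved], la1[moved], lo1[moved],
                               strict=False)
    home_bearing = geo_bearing(la0[moved], lo0[moved], home.lat, home.lon,
                               strict=False)
    return np.atleast_1d(wrap_angle(step_bearing - home_bearing))


def mean_vector(directions_deg) -> tuple[float, float]:
    """Resultant (length, direction°) of unit vectors of the given angles.

    Length is in [0, 1] (1 = all directions identical); direction is wrapped
    to (−180, 180].
    """
    theta = np.radians(np.asarray(directions_deg, dtype=float))
    if theta.size == 0:
        raise MetricUndefinedError("mean vector of an empty direction set")
    c = float(np.mean(np.cos(theta)))
    s = float(np.mean(np.sin(theta)))
    length = min(float(np.hypot(c, s)), 1.0)
    direction = wrap_angle(np.degrees(np.arctan2(s, c)))
    return length, direction


def vanishing_time(segment: TrackSegment) -> float:
    """Seconds from release (first raw fix) to the final radius exit."""
    _require_usable(segment)
    return float(segment.t[segment.exit_index] - segment.release_time)


def path_length(segment: TrackSegment) -> float:
    """Sum of great-circle step lengths over the segment, meters."""
    _require_usable(segment)
    return float(np.sum(geo_distance(segment.lat[:-1], segment.lon[:-1],
                                     segment.lat[1:], segment.lon[1:])))


def efficiency_index(segment: TrackSegment) -> float:
    """Straight-line first→exit distance over path length, in (0, 1]."""
    plen = path_length(segment)
    if plen <= 0.0:
        raise MetricUndefinedError(f"bird {segment.bird_id}: zero path length")
    chord = geo_distance(segment.lat[0], segment.lon[0],
                         segment.lat[-1], segment.lon[-1])
    return min(float(chord / plen), 1.0)   # guard fp overshoot on straight tracks


def homing_efficiency_index(segment: TrackSegment, home: Loft,
                            anchor: str = "segment_start") -> float:
    """Net distance-to-home reduction over path length, in [−1, 1].

    ``anchor`` selects the start point of the numerator: the segment's first
    fix (default, shares the denominator with :func:`efficiency_index`) or
    the release point.
    """
    plen = path_length(segment)
    if plen <= 0.0:
        raise MetricUndefinedError(f"bird {segment.bird_id}: zero path length")
    if anchor == "segment_start":
        alat, alon = segment.lat[0], segment.lon[0]
    elif anchor == "release_point":
        alat, alon = segment.release_lat, segment.release_lon
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    d_start = geo_distance(alat, alon, home.lat, home.lon)
    d_exit = geo_distance(segment.lat[-1], segment.lon[-1], home.lat, home.lon)
    hei = float((d_start - d_exit) / plen)
    if anchor == "segment_start":
        hei = max(min(hei, 1.0), -1.0)     # guard fp overshoot at the limits
    return hei


def compute_metrics(segment: TrackSegment, home: Loft,
                    hei_anchor: str = "segment_start") -> MetricRecord:
    """All four metrics for one usable segment."""
    dirs = step_directions(segment, home)
    length, direction = mean_vector(dirs)
    return MetricRecord(
        bird_id=segment.bird_id,
        radius=segment.radius,
        vanishing_time=vanishing_time(segment),
        mean_vector_length=length,
        mean_direction=direction,
        efficiency_index=efficiency_index(segment),
        homing_efficiency_index=homing_efficiency_index(segment, home, hei_anchor),
    )
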