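"""Track filtering and release-site segmentation.

The cleaning order is: (1) strip the leading run of fixes inside the 500 m
escape radius (the initial escape response), (2) drop fixes slower than
5 km/h (stops), (3) truncate at the final exit from the analysis radius
(2 km or 5 km) around the release point.  Re-entries into the escape circle
after the bird first left it are retained — only the *initial* fixes go.

Following behaviour between birds is screened algorithmically: two birds
whose time-aligned fixes stay within ``d_max`` meters for at least ``t_min``
seconds inside the 2 km segment window count as a following dyad.  A dyad in
the same treatment group loses one member (seeded random draw); a dyad
spanning both groups loses both, since the behaviour cannot then be
attributed to either treatment.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

from .geodesy import geo_distance
from .model import (FOLLOWING, NEVER_EXITED, NO_EXCLUSION, TOO_FEW_FIXES,
                    FollowingEvent, Track, TrackSegment)

log = logging.getLogger(__name__)

DEFAULT_ESCAPE_RADIUS_M = 500.0
DEFAULT_MIN_SPEED_KMH = 5.0
DEFAULT_ANALYSIS_RADII_M = (2000.0, 5000.0)
DEFAULT_FOLLOW_D_MAX_M = 100.0
DEFAULT_FOLLOW_T_MIN_S = 120.0
DEFAULT_FOLLOW_SLACK_S = 2.0


class NeverExitedError(ValueError):
    """The track never leaves the given radius."""


class TooFewFixesError(ValueError):
    """Fewer than two fixes survive a filter."""


def _dist_to_release(track: Track, release_point) -> np.ndarray:
    rlat, rlon = release_point
    return geo_distance(track.lat, track.lon, rlat, rlon)


def strip_escape_radius(track: Track, release_point,
                        r_escape: float = DEFAULT_ESCAPE_RADIUS_M) -> Track:
    """Remove the leading run of fixes within ``r_escape`` of the release point.

    Later re-entries into the escape circle are retained.  Raises
    :class:`NeverExitedError` if the whole track stays inside.
    """
    d = _dist_to_release(track, release_point)
    outside = np.nonzero(d > r_escape)[0]
    if outside.size == 0:
        raise NeverExitedError(
            f"bird {track.bird_id}: no fix beyond the {r_escape:.0f} m escape radius")
    return track.subset(slice(int(outside[0]), None))


def filter_speed(track: Track, min_speed: float = DEFAULT_MIN_SPEED_KMH) -> Track:
    """Drop fixes with logger speed strictly below ``min_speed`` km/h.

    Raises :class:`TooFewFixesError` when fewer than two moving fixes remain
    (callers translate this into a ``too_few_fixes`` exclusion downstream).
    """
    keep = track.speed >= min_speed
    n_drop = int((~keep).sum())
    if n_drop:
        log.debug("bird %s: removed %d fixes below %.1f km/h",
                  track.bird_id, n_drop, min_speed)
    if int(keep.sum()) < 2:
        raise TooFewFixesError(
            f"bird {track.bird_id}: fewer than 2 fixes at or above {min_speed} km/h")
    return track.subset(keep)


def final_exit_segment(track: Track, release_point, radius: float,
                       release_time: float | None = None) -> TrackSegment:
    """Truncate a cleaned track at its final exit from ``radius``.

    Let L be the last index with distance ≤ radius; the segment is
    ``fixes[0 .. L+1]`` and the exit fix (index L+1, the first fix beyond the
    radius after the last inside fix) terminates it.  A track that never goes
    back outside after L (e.g. the logger died inside) is flagged
    ``never_exited``; a usable segment needs at least 3 fixes.
    """
    rlat, rlon = release_point
    if release_time is None:
        release_time = track.release_time
    base = dict(bird_id=track.bird_id, radius=float(radius),
                release_lat=rlat, release_lon=rlon, release_time=float(release_time))

    def _flagged(reason):
        return TrackSegment(lat=track.lat[:0], lon=track.lon[:0], t=track.t[:0],
                            speed=track.speed[:0], exit_index=-1, excluded=reason, **base)

    if track.n_fixes < 3:
        return _flagged(TOO_FEW_FIXES)
    d = _dist_to_release(track, release_point)
    inside = np.nonzero(d <= radius)[0]
    if inside.size == 0:
        # already beyond the radius at the first cleaned fix: nothing to analyse
        return _flagged(TOO_FEW_FIXES)
    last_inside = int(inside[-1])
    if last_inside == track.n_fixes - 1:
        return _flagged(NEVER_EXITED)
    end = last_inside + 1  # exit fix: first fix beyond radius after last inside fix
    if end + 1 < 3:
        return _flagged(TOO_FEW_FIXES)
    sl = slice(0, end + 1)
    return TrackSegment(lat=track.lat[sl], lon=track.lon[sl], t=track.t[sl],
                        speed=track.speed[sl], exit_index=end,
                        excluded=NO_EXCLUSION, **base)


def extract_segment(track: Track, release_point, radius: float,
                    r_escape: float = DEFAULT_ESCAPE_RADIUS_M,
                    min_speed: float = DEFAULT_MIN_SPEED_KMH) -> TrackSegment:
    """Full cleaning chain: escape strip → speed filter → final-exit segment."""
    release_time = track.release_time

    def _flagged(reason):
        return TrackSegment(bird_id=track.bird_id, radius=float(radius),
                            lat=track.lat[:0], lon=track.lon[:0], t=track.t[:0],
                            speed=track.speed[:0], release_lat=release_point[0],
                            release_lon=release_point[1], release_time=release_time,
                            exit_index=-1, excluded=reason)

    try:
        stripped = strip_escape_radius(track, release_point, r_escape)
    except NeverExitedError:
        return _flagged(NEVER_EXITED)
    try:
        moving = filter_speed(stripped, min_speed)
    except TooFewFixesError:
        return _flagged(TOO_FEW_FIXES)
    return final_exit_segment(moving, release_point, radius, release_time)


def detect_following(tracks, d_max: float = DEFAULT_FOLLOW_D_MAX_M,
                     t_min: float = DEFAULT_FOLLOW_T_MIN_S,
                     slack: float = DEFAULT_FOLLOW_SLACK_S,
                     windows: dict | None = None) -> list[FollowingEvent]:
    """Screen all bird pairs for sustained close-proximity episodes.

    For each pair, fixes of the first bird are matched to the
    nearest-timestamp fix of the second (within ``slack`` seconds); a
    contiguous run of matched fixes with separation ≤ ``d_max`` lasting at
    least ``t_min`` seconds produces one :class:`FollowingEvent`.
    ``windows`` optionally restricts each bird to a (start, end) time window
    (the 2 km segment window in the pipeline).  A bird is never paired with
    itself.
    """
    events = []
    tracks = sorted(tracks, key=lambda tr: tr.bird_id)
    for ta, tb in itertools.combinations(tracks, 2):
        wa = windows.get(ta.bird_id) if windows else (ta.t[0], ta.t[-1])
        wb = windows.get(tb.bird_id) if windows else (tb.t[0], tb.t[-1])
        if wa is None or wb is None:
            continue
        lo = max(wa[0], wb[0])
        hi = min(wa[1], wb[1])
        if hi - lo < t_min:
            continue
        ia = slice(*np.searchsorted(ta.t, [lo, hi + 1e-9]))
        at, alat, alon = ta.t[ia], ta.lat[ia], ta.lon[ia]
        if at.size < 2:
            continue
        ib = slice(*np.searchsorted(tb.t, [lo - slack, hi + slack]))
        bt, blat, blon = tb.t[ib], tb.lat[ib], tb.lon[ib]
        if bt.size == 0:
            continue
        # nearest-timestamp pairing of A fixes onto B fixes
        pos = np.searchsorted(bt, at)
        left = np.clip(pos - 1, 0, bt.size - 1)
        right = np.clip(pos, 0, bt.size - 1)
        nearest = np.where(np.abs(bt[left] - at) <= np.abs(bt[right] - at), left, right)
        dt_ok = np.abs(bt[nearest] - at) <= slack
        sep = geo_distance(alat, alon, blat[nearest], blon[nearest])
        close = dt_ok & (sep <= d_max)
        # contiguous runs of close, matched fixes
        edges = np.flatnonzero(np.diff(np.concatenate(([0], close.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            duration = at[stop - 1] - at[start]
            if duration >= t_min:
                events.append(FollowingEvent(
                    bird_a=ta.bird_id, bird_b=tb.bird_id,
                    overlap_start=float(at[start]), overlap_end=float(at[stop - 1]),
                    median_separation=float(np.median(sep[start:stop])),
                ))
    return events


def apply_following_exclusions(events, tracks, rng) -> dict[str, str]:
    """Return ``{bird_id: reason}`` exclusion flags implied by following dyads.

    Same-group dyad: exactly one member (seeded uniform draw) is excluded.
    Cross-group dyad: both are excluded.  Flags are idempotent across events.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    groups = {tr.bird_id: tr.group for tr in tracks}
    excluded: dict[str, str] = {}
    for ev in sorted(events, key=lambda e: (e.bird_a, e.bird_b, e.overlap_start)):
        if ev.bird_a not in groups or ev.bird_b not in groups:
            raise KeyError(f"following event references unknown bird "
                           f"{ev.bird_a!r}/{ev.bird_b!r}")
        if groups[ev.bird_a] == groups[ev.bird_b]:
            victim = ev.bird_a if rng.random() < 0.5 else ev.bird_b
            excluded.setdefault(victim, FOLLOWING)
        else:
            excluded.setdefault(ev.bird_a, FOLLOWING)
            excluded.setdefault(ev.bird_b, FOLLOWING)
    return excluded
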