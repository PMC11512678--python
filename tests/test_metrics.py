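"""The four navigation metrics against geometric oracles."""

import math

import numpy as np
import pytest

from pigeontrack.geodesy import destination
from pigeontrack.metrics import (MetricUndefinedError, compute_metrics,
                                 efficiency_index, homing_efficiency_index,
                                 mean_vector, step_directions, vanishing_time)
from pigeontrack.model import Loft, TrackSegment
from pigeontrack.preprocess import extract_segment, final_exit_segment

from conftest import RELEASE, track_at_distances, track_through_points


def straight_segment(bearing, radius=2000.0, step=25.0, start=520.0,
                     release=RELEASE, speeds_kmh=90.0):
    """Segment of a noise-free track of equally spaced fixes along a bearing."""
    d = np.arange(start, radius + 3 * step, step)
    tr = track_at_distances(d, bearing=bearing, release=release,
                            speeds=np.full(d.size, speeds_kmh))
    seg = final_exit_segment(tr, release, radius)
    assert seg.usable
    return seg


class TestStepDirections:
    def test_straight_to_home_all_zero(self, far_home):
        seg = straight_segment(bearing=270.0)   # home is due west
        theta = step_directions(seg, far_home)
        assert np.all(np.abs(theta) < 0.05)

    def test_track_opposite_home_all_180(self, far_home):
        seg = straight_segment(bearing=90.0)
        theta = step_directions(seg, far_home)
        assert np.all(np.abs(np.abs(theta) - 180.0) < 0.05)

    def test_square_path_matches_planar_oracle(self):
        # four legs of a small square, home ~3 km west so the whole scene is
        # small enough for planar arithmetic to be exact to < 0.1°
        near_home = Loft(*destination(*RELEASE, 270.0, 3000.0))
        p0 = destination(*RELEASE, 0.0, 1000.0)
        legs = [(0.0, 200.0), (90.0, 200.0), (180.0, 200.0), (270.0, 200.0)]
        pts = [p0]
        for brg, dist in legs:
            for _ in range(4):
                pts.append(destination(*pts[-1], brg, dist / 4))
        from pigeontrack.model import Track, TrackSegment
        tr = track_through_points(pts)
        seg = TrackSegment("sq", 2000.0, tr.lat, tr.lon, tr.t, tr.speed,
                           RELEASE[0], RELEASE[1], 0.0,
                           exit_index=tr.n_fixes - 1)
        theta = step_directions(seg, near_home)
        # independent planar oracle: equirectangular east/north offsets give
        # the home bearing, and each leg keeps its compass bearing
        R = 6_371_008.8
        expected = []
        for k, (brg, _dist) in enumerate(((b, d) for b, d in legs for _ in range(4))):
            la, lo = tr.lat[k], tr.lon[k]
            de = math.radians(near_home.lon - lo) * R * math.cos(math.radians(la))
            dn = math.radians(near_home.lat - la) * R
            home_brg = math.degrees(math.atan2(de, dn)) % 360.0
            expected.append(((brg - home_brg + 180.0) % 360.0) - 180.0)
        np.testing.assert_allclose(theta, expected, atol=0.1)

    def test_duplicate_fixes_are_skipped(self, far_home):
        seg = straight_segment(bearing=270.0)
        dup = type(seg)(seg.bird_id, seg.radius,
                        np.repeat(seg.lat, 2), np.repeat(seg.lon, 2),
                        np.arange(2 * seg.n_fixes, dtype=float),
                        np.repeat(seg.speed, 2), seg.release_lat,
                        seg.release_lon, 0.0, exit_index=2 * seg.n_fixes - 1)
        assert step_directions(dup, far_home).size == step_directions(seg, far_home).size


class TestMeanVector:
    def test_identical_directions_length_one(self):
        length, direction = mean_vector([37.0] * 12)
        assert length == pytest.approx(1.0, abs=1e-12)
        assert direction == pytest.approx(37.0)

    def test_uniform_four_directions_cancel(self):
        length, _ = mean_vector([0.0, 90.0, 180.0, 270.0])
        assert length == pytest.approx(0.0, abs=1e-9)

    def test_two_direction_closed_form(self):
        length, direction = mean_vector([0.0, 90.0])
        assert length == pytest.approx(math.cos(math.radians(45.0)), abs=1e-12)
        assert direction == pytest.approx(45.0, abs=1e-9)

    def test_rotation_invariance_of_length(self):
        rng = np.random.default_rng(4)
        dirs = rng.uniform(-180, 180, 40)
        l0, d0 = mean_vector(dirs)
        l1, d1 = mean_vector((dirs + 73.0 + 180.0) % 360.0 - 180.0)
        assert l1 == pytest.approx(l0, abs=1e-12)
        assert (d1 - d0) % 360.0 == pytest.approx(73.0, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(MetricUndefinedError):
            mean_vector([])


class TestVanishingTime:
    def test_straight_track_time_is_radius_over_speed(self):
        # 16.7 m/s ≈ 60 km/h, 1 Hz: first fix beyond 2 km is fix 120
        d = 16.7 * np.arange(0, 135)
        tr = track_at_distances(d, speeds=np.full(135, 60.0))
        seg = extract_segment(tr, RELEASE, 2000.0)
        assert vanishing_time(seg) == pytest.approx(120.0)

    def test_loitering_inside_counts(self):
        # bird sits (speed 0, filtered) for 600 s before flying out
        d = np.concatenate([np.full(600, 550.0 + 0.0), 550.0 + 16.7 * np.arange(1, 140)])
        speeds = np.concatenate([np.zeros(600), np.full(139, 60.0)])
        tr = track_at_distances(d, speeds=speeds)
        seg = extract_segment(tr, RELEASE, 2000.0)
        assert vanishing_time(seg) > 600.0

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(9)
        d = np.abs(np.cumsum(rng.normal(30, 60, 400))) + 520
        d = np.concatenate([d, [6500.0]])
        tr = track_at_distances(d)
        s2 = extract_segment(tr, RELEASE, 2000.0)
        s5 = extract_segment(tr, RELEASE, 5000.0)
        if s2.usable and s5.usable:
            assert vanishing_time(s5) >= vanishing_time(s2)


class TestEfficiencyIndex:
    def test_straight_track_is_one(self):
        seg = straight_segment(bearing=135.0)
        assert efficiency_index(seg) == pytest.approx(1.0, abs=1e-6)

    def test_right_angle_path_five_sevenths(self):
        # legs 3 km and 4 km → displacement 5 km over 7 km of path
        p0 = destination(*RELEASE, 0.0, 600.0)
        pts = [p0]
        for _ in range(30):
            pts.append(destination(*pts[-1], 0.0, 100.0))
        for _ in range(40):
            pts.append(destination(*pts[-1], 90.0, 100.0))
        from pigeontrack.model import TrackSegment
        tr = track_through_points(pts)
        seg = TrackSegment("L", 10_000.0, tr.lat, tr.lon, tr.t, tr.speed,
                           RELEASE[0], RELEASE[1], 0.0, exit_index=tr.n_fixes - 1)
        assert efficiency_index(seg) == pytest.approx(5.0 / 7.0, abs=1e-3)

    def test_out_and_back_near_zero(self):
        d_out = 520.0 + 25.0 * np.arange(0, 70)
        d_back = d_out[-2::-1]
        d = np.concatenate([d_out, d_back, [2300.0]])
        tr = track_at_distances(d)
        seg = final_exit_segment(tr, RELEASE, 2000.0)
        assert seg.usable
        assert efficiency_index(seg) < 0.35


class TestHomingEfficiencyIndex:
    def test_straight_toward_home_is_one(self, far_home):
        seg = straight_segment(bearing=270.0)
        assert homing_efficiency_index(seg, far_home) == pytest.approx(1.0, abs=1e-6)

    def test_perpendicular_track_near_zero(self, far_home):
        seg = straight_segment(bearing=0.0)   # due north, home due west
        assert abs(homing_efficiency_index(seg, far_home)) < 0.05

    def test_straight_away_from_home_is_minus_one(self, far_home):
        seg = straight_segment(bearing=90.0)
        assert homing_efficiency_index(seg, far_home) == pytest.approx(-1.0, abs=1e-6)

    def test_never_exceeds_efficiency_index(self, far_home):
        rng = np.random.default_rng(17)
        for _ in range(25):
            # random meandering walk leaving the radius eventually
            steps = rng.normal(25, 30, 200)
            d = np.abs(np.cumsum(steps)) + 520.0
            d = np.concatenate([d, [d.max() + 2500.0]])
            bearing = rng.uniform(0, 360)
            tr = track_at_distances(d, bearing=bearing)
            seg = final_exit_segment(tr, RELEASE, 2000.0)
            if not seg.usable:
                continue
            hei = homing_efficiency_index(seg, far_home)
            ei = efficiency_index(seg)
            assert hei <= ei + 1e-9

    def test_release_point_anchor_variant(self, far_home):
        seg = straight_segment(bearing=270.0)
        alt = homing_efficiency_index(seg, far_home, anchor="release_point")
        # numerator grows by the stripped 500 m but the denominator does not
        assert alt > 1.2


class TestComputeMetrics:
    def test_record_fields_and_bounds(self, far_home):
        seg = straight_segment(bearing=300.0)
        rec = compute_metrics(seg, far_home)
        assert 0.0 <= rec.mean_vector_length <= 1.0
        assert 0.0 < rec.efficiency_index <= 1.0
        assert -1.0 <= rec.homing_efficiency_index <= 1.0
        assert rec.vanishing_time > 0.0
        assert rec.radius == 2000.0

    def test_excluded_segment_rejected(self, far_home):
        tr = track_at_distances([600, 800, 1000])
        seg = extract_segment(tr, RELEASE, 2000.0)
        with pytest.raises(MetricUndefinedError):
            compute_metrics(seg, far_home)
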