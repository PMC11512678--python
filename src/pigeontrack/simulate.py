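"""Synthetic homing-track generator.

Tracks are biased correlated random walks (BCRW) at 1 Hz: each second the
heading is drawn from a von Mises distribution centred on a compromise
between the previous heading (weight 1 − w) and the perceived home
direction (weight w), with concentration κ.  The perceived home direction
is the true bearing to the loft deflected by a site-specific offset — the
classical *release-site bias* — and w itself carries a site-specific
decrement, so one site produces weaker, more deflected orientation than the
other.  An initial escape phase (w = 0) reproduces undirected circling near
the release point; stop episodes emit sub-5 km/h fixes with positional
jitter; Gaussian noise is added to recorded positions; birds fly until they
are 6 km from the release point or a maximum duration elapses.

The study layout mirrors a 2×2 passive-exposure design: birds are exposed
at one of two sites and released at one of them on a later day; a bird is
*experimental* when exposure and release site coincide.  Default cell
counts are 12/12/12/13.  Optional follower dyads clone one bird's path onto
another with jitter, for exercising the following-detection screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geodesy import EARTH_RADIUS_M, destination, geo_bearing, wrap_angle
from .model import Loft, Site, Track, infer_group

__all__ = ["SimConfig", "SimOutput", "default_loft", "default_sites",
           "simulate_bird", "simulate_study"]

#: Arnino field station loft, 43°39′26″N 10°18′14″E
_LOFT_LAT = 43.0 + 39.0 / 60.0 + 26.0 / 3600.0
_LOFT_LON = 10.0 + 18.0 / 60.0 + 14.0 / 3600.0

#: release-day epochs (UTC): two sites, released on different days
_RELEASE_EPOCHS = {"site1": 1628663700.0,   # 2021-08-11T06:35:00Z
                   "site2": 1628836500.0}   # 2021-08-13T06:35:00Z


def default_loft() -> Loft:
    return Loft(_LOFT_LAT, _LOFT_LON)


def _site_from_home_geometry(loft: Loft, site_id: str, home_bearing: float,
                             home_distance_km: float) -> Site:
    """Place a site so that bearing(site → loft) and the distance match."""
    out = (home_bearing + 180.0) % 360.0
    lat = lon = None
    for _ in range(6):
        lat, lon = destination(loft.lat, loft.lon, out, home_distance_km * 1000.0)
        err = wrap_angle(home_bearing - geo_bearing(lat, lon, loft.lat, loft.lon))
        out = (out + err) % 360.0
    actual = geo_bearing(lat, lon, loft.lat, loft.lon)
    return Site(site_id, lat, lon, actual, home_distance_km)


def default_sites() -> tuple[Site, Site]:
    """The two release sites: home bearings 261°/336°, distances 34.2/39.3 km."""
    loft = default_loft()
    return (_site_from_home_geometry(loft, "site1", 261.0, 34.2),
            _site_from_home_geometry(loft, "site2", 336.0, 39.3))


@dataclass
class SiteBias:
    """Release-site bias: angular deflection of the perceived home direction
    (degrees, negative = anticlockwise) and a decrement of the bias weight."""
    offset_deg: float = 0.0
    w_decrement: float = 0.0


@dataclass
class SimConfig:
    """Study-level generating parameters (defaults are the study conditions)."""

    seed: int = 0
    #: cells in order (release1/exposed1, release1/exposed2,
    #:                 release2/exposed1, release2/exposed2)
    n_birds_per_cell: tuple = (12, 12, 12, 13)
    loft: Loft = field(default_factory=default_loft)
    sites: tuple = field(default_factory=default_sites)
    sampling_hz: float = 1.0
    flight_speed_mean_kmh: float = 65.0
    flight_speed_sd_kmh: float = 8.0
    kappa: float = 4.0
    bias_weight: float = 0.35
    w_between_sd: float = 0.05    # persistent per-bird orientation-quality jitter
    site_bias: dict = field(default_factory=lambda: {
        "site1": SiteBias(offset_deg=-15.0, w_decrement=0.0),
        "site2": SiteBias(offset_deg=-30.0, w_decrement=0.12),
    })
    treatment_effect: float = 0.0      # additive increment to w for experimental birds
    stop_rate_per_min: float = 0.3     # per-minute probability of starting a stop
    stop_mean_duration_s: float = 20.0
    escape_phase_s: float = 60.0
    follower_pairs: int = 8
    gps_noise_sd_m: float = 3.0
    exit_radius_m: float = 6000.0
    max_duration_s: float = 1800.0
    release_spacing_s: float = 360.0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.flight_speed_mean_kmh <= 0:
            raise ValueError("flight speed must be positive")
        for bias in self.site_bias.values():
            w = self.bias_weight - bias.w_decrement
            if not 0.0 <= w + max(self.treatment_effect, 0.0) <= 1.0 or w < 0.0:
                raise ValueError("effective bias weight must stay in [0, 1]")

    def effective_w(self, site_id: str, experimental: bool) -> float:
        w = self.bias_weight - self.site_bias[site_id].w_decrement
        if experimental:
            w += self.treatment_effect
        return float(np.clip(w, 0.0, 1.0))


@dataclass
class SimOutput:
    tracks: list
    manifest: pd.DataFrame   # indexed by bird_id
    truth: pd.DataFrame      # per-bird generating parameters


def _simulate_cohort(rng, n: int, release, home, w_eff, bias_offset_deg,
                     cfg: SimConfig, no_early_stop: bool = False):
    """Vectorized BCRW for ``n`` birds sharing one release point.

    Returns recorded (east, north) offsets in meters from the release point,
    recorded speeds (km/h), and the per-bird number of steps (the fix at the
    step index is the first one at or beyond the exit radius, when reached).
    ``no_early_stop`` keeps the random stream length fixed (common random
    numbers for paired-parameter pilots).
    """
    dt = 1.0 / cfg.sampling_hz
    n_steps_max = int(round(cfg.max_duration_s * cfg.sampling_hz))
    rel_lat, rel_lon = release
    home_lat, home_lon = home
    # home position in the local tangent plane of the release point
    hx = np.radians(home_lon - rel_lon) * EARTH_RADIUS_M * np.cos(np.radians(rel_lat))
    hy = np.radians(home_lat - rel_lat) * EARTH_RADIUS_M
    offset = np.radians(np.asarray(bias_offset_deg, dtype=float))
    w = np.asarray(w_eff, dtype=float)

    x = np.zeros(n)
    y = np.zeros(n)
    h = rng.uniform(0.0, 2.0 * np.pi, n)       # initial headings: uniform
    stop_left = np.zeros(n)
    done = np.zeros(n, dtype=bool)
    exit_step = np.full(n, n_steps_max, dtype=int)

    xs = np.zeros((n, n_steps_max + 1))
    ys = np.zeros((n, n_steps_max + 1))
    vs = np.zeros((n, n_steps_max + 1))
    p_stop = cfg.stop_rate_per_min / 60.0 * dt

    for step in range(1, n_steps_max + 1):
        t_now = step * dt
        # draws are a fixed shape every step so seeded streams stay aligned
        vm = rng.vonmises(0.0, cfg.kappa, n)
        u_start = rng.random(n)
        durations = rng.geometric(1.0 / max(cfg.stop_mean_duration_s, 1.0), n)
        v_fly = np.maximum(rng.normal(cfg.flight_speed_mean_kmh,
                                      cfg.flight_speed_sd_kmh, n), 5.5)
        v_stop = rng.uniform(0.3, 4.5, n)
        psi = rng.uniform(0.0, 2.0 * np.pi, n)

        home_bearing = np.arctan2(hx - x, hy - y) + offset
        w_now = np.where(t_now <= cfg.escape_phase_s, 0.0, w)
        tx = w_now * np.sin(home_bearing) + (1.0 - w_now) * np.sin(h)
        ty = w_now * np.cos(home_bearing) + (1.0 - w_now) * np.cos(h)
        h_new = np.arctan2(tx, ty) + vm

        flying = stop_left <= 0.0
        start = flying & (t_now > cfg.escape_phase_s) & (u_start < p_stop)
        stop_left = np.where(start, durations.astype(float), stop_left)
        stopped = stop_left > 0.0

        h = np.where(stopped, h, h_new)        # heading frozen while perched
        v = np.where(stopped, v_stop, v_fly)
        move_dir = np.where(stopped, psi, h)   # stops only jitter in place
        step_m = v / 3.6 * dt
        adv = (~done).astype(float) * step_m
        x = x + adv * np.sin(move_dir)
        y = y + adv * np.cos(move_dir)
        stop_left = np.maximum(stop_left - dt, 0.0)

        xs[:, step] = x
        ys[:, step] = y
        vs[:, step] = np.where(done, 0.0, v)

        newly = (~done) & (np.hypot(x, y) >= cfg.exit_radius_m)
        exit_step[newly] = step
        done |= newly
        if done.all() and not no_early_stop:
            n_used = step
            break
    else:
        n_used = n_steps_max

    n_fix = np.minimum(exit_step, n_used)
    noise = rng.normal(0.0, cfg.gps_noise_sd_m, size=(2, n, n_used + 1))
    return (xs[:, :n_used + 1] + noise[0], ys[:, :n_used + 1] + noise[1],
            vs[:, :n_used + 1], n_fix)


def _to_track(bird_id, rel, x, y, v, n_fix, t0, labels) -> Track:
    sl = slice(0, n_fix + 1)
    lat = rel[0] + np.degrees(y[sl] / EARTH_RADIUS_M)
    lon = rel[1] + np.degrees(x[sl] / (EARTH_RADIUS_M * np.cos(np.radians(rel[0]))))
    t = t0 + np.arange(n_fix + 1, dtype=float)
    return Track(bird_id, lat, lon, t, np.maximum(v[sl], 0.0), **labels)


def _study_layout(cfg: SimConfig) -> pd.DataFrame:
    """Per-bird design rows, release order alternating between treatments."""
    cells = [("site1", "site1"), ("site1", "site2"),
             ("site2", "site1"), ("site2", "site2")]
    rows = []
    idx = 0
    for release in ("site1", "site2"):
        queue = {}
        for (rel, expo), count in zip(cells, cfg.n_birds_per_cell):
            if rel == release:
                queue[expo] = count
        order = []
        exposures = sorted(queue)
        k = 0
        while any(queue[e] > 0 for e in exposures):   # alternate treatments
            e = exposures[k % len(exposures)]
            if queue[e] > 0:
                order.append(e)
                queue[e] -= 1
            k += 1
        for slot, expo in enumerate(order):
            idx += 1
            rows.append({
                "bird_id": f"b{idx:02d}", "release_site": release,
                "exposure_site": expo, "group": infer_group(release, expo),
                "release_time": _RELEASE_EPOCHS[release] + slot * cfg.release_spacing_s,
                "release_order": slot,
            })
    return pd.DataFrame(rows)


def simulate_bird(cfg: SimConfig, bird_index: int, rng) -> Track:
    """Generate a single bird's track (bird ``bird_index`` of the layout)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    layout = _study_layout(cfg)
    row = layout.iloc[bird_index]
    site = next(s for s in cfg.sites if s.site_id == row["release_site"])
    w = cfg.effective_w(site.site_id, row["group"] == "experimental")
    w = float(np.clip(w + rng.normal(0.0, cfg.w_between_sd), 0.0, 1.0))
    x, y, v, n_fix = _simulate_cohort(
        rng, 1, (site.lat, site.lon), (cfg.loft.lat, cfg.loft.lon),
        np.array([w]), np.array([cfg.site_bias[site.site_id].offset_deg]), cfg)
    return _to_track(row["bird_id"], (site.lat, site.lon), x[0], y[0], v[0],
                     int(n_fix[0]), row["release_time"],
                     dict(release_site=row["release_site"],
                          exposure_site=row["exposure_site"], group=row["group"]))


def simulate_study(cfg: SimConfig, rng=None,
                   no_early_stop: bool = False) -> SimOutput:
    """Generate the full 2×2 study: all birds, manifest and truth table."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    layout = _study_layout(cfg)
    sites = {s.site_id: s for s in cfg.sites}
    tracks: list[Track] = []
    truth_rows = []
    for release in ("site1", "site2"):
        sub = layout[layout["release_site"] == release]
        site = sites[release]
        n = len(sub)
        w = np.array([cfg.effective_w(release, g == "experimental")
                      for g in sub["group"]])
        w = np.clip(w + rng.normal(0.0, cfg.w_between_sd, n), 0.0, 1.0)
        offs = np.full(n, cfg.site_bias[release].offset_deg)
        x, y, v, n_fix = _simulate_cohort(
            rng, n, (site.lat, site.lon), (cfg.loft.lat, cfg.loft.lon),
            w, offs, cfg, no_early_stop=no_early_stop)
        for i, (_, row) in enumerate(sub.iterrows()):
            tracks.append(_to_track(
                row["bird_id"], (site.lat, site.lon), x[i], y[i], v[i],
                int(n_fix[i]), row["release_time"],
                dict(release_site=row["release_site"],
                     exposure_site=row["exposure_site"], group=row["group"])))
            truth_rows.append({
                "bird_id": row["bird_id"], "release_site": row["release_site"],
                "exposure_site": row["exposure_site"], "group": row["group"],
                "w_effective": w[i], "kappa": cfg.kappa,
                "bias_offset_deg": offs[i], "release_time": row["release_time"],
                "follower_of": "",
            })
    truth = pd.DataFrame(truth_rows).set_index("bird_id")

    # follower dyads: clone the leader's path onto the follower with jitter
    by_id = {tr.bird_id: k for k, tr in enumerate(tracks)}
    if cfg.follower_pairs > 0:
        candidates = layout.groupby("release_site")["bird_id"].apply(list)
        free = {s: list(ids) for s, ids in candidates.items()}
        made = 0
        order = list(_RELEASE_EPOCHS)
        while made < cfg.follower_pairs:
            site_id = order[made % len(order)]
            pool = free[site_id]
            if len(pool) < 2:
                break
            pick = rng.choice(len(pool), size=2, replace=False)
            leader_id, follower_id = pool[int(pick[0])], pool[int(pick[1])]
            for b in (leader_id, follower_id):
                pool.remove(b)
            li, fi = by_id[leader_id], by_id[follower_id]
            lead = tracks[li]
            off_e, off_n = rng.normal(0.0, 25.0, 2)
            jit = rng.normal(0.0, 4.0, size=(2, lead.n_fixes))
            coslat = np.cos(np.radians(lead.lat))
            lat = lead.lat + np.degrees((off_n + jit[1]) / EARTH_RADIUS_M)
            lon = lead.lon + np.degrees((off_e + jit[0]) / (EARTH_RADIUS_M * coslat))
            old = tracks[fi]
            tracks[fi] = replace(old, lat=lat, lon=lon, t=lead.t.copy(),
                                 speed=lead.speed.copy())
            truth.loc[follower_id, "follower_of"] = leader_id
            truth.loc[follower_id, "release_time"] = lead.t[0]
            made += 1

    manifest = layout.set_index("bird_id")[
        ["release_site", "exposure_site", "group", "release_time"]]
    return SimOutput(tracks=tracks, manifest=manifest, truth=truth.reset_index())
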