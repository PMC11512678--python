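"""Orchestration: ingest → preprocess → metrics → statistics → power.

:func:`analyse_tracks` is the in-memory pipeline used by tests, calibration
experiments and the CLI alike; :func:`run_full_analysis` wraps it with file
output (tables, JSON reports, figures, an exclusion log and a run manifest
whose per-stage counts reconcile exactly with the exclusion arithmetic).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circstats import bird_vector_point, hotelling_two_sample
from .config import AnalysisConfig
from .inference import (DiagnosticsReport, EffectReport, ModelSpec,
                        effect_sizes, fit_metric_model, model_specs,
                        residual_diagnostics)
from .metrics import MetricUndefinedError, compute_metrics, step_directions
from .model import FOLLOWING, Loft
from .power import power_table
from .preprocess import (apply_following_exclusions, detect_following,
                         extract_segment)

log = logging.getLogger(__name__)

METRIC_COLUMNS = ("vanishing_time_s", "mean_vector_length", "mean_direction_deg",
                  "efficiency_index", "homing_efficiency_index")
POWER_ETAS = (0.26, 0.14, 0.06, 0.01)


@dataclass
class ModelReport:
    spec: ModelSpec
    n: int
    group: EffectReport
    site: EffectReport
    diagnostics: DiagnosticsReport | None = None

    def to_dict(self) -> dict:
        out = {"metric": self.spec.metric, "radius_m": self.spec.radius,
               "transform": self.spec.transform, "n": self.n,
               "group": self.group.to_dict(), "release_site": self.site.to_dict()}
        if self.diagnostics is not None:
            out["shapiro_W"] = self.diagnostics.shapiro_W
            out["shapiro_p"] = self.diagnostics.shapiro_p
        return out


@dataclass
class StudyResults:
    metrics: pd.DataFrame
    exclusions: pd.DataFrame
    hotelling: dict
    models: dict
    bird_points: dict
    power: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _segment_windows(tracks, sites, cfg: AnalysisConfig) -> dict:
    """Per-bird (start, end) window of the 2 km section, for the follow screen."""
    windows = {}
    radius = min(cfg.analysis_radii_m)
    for tr in tracks:
        site = sites[tr.release_site]
        seg = extract_segment(tr, (site.lat, site.lon), radius,
                              cfg.escape_radius_m, cfg.min_speed_kmh)
        if seg.usable:
            windows[tr.bird_id] = (tr.release_time, float(seg.t[-1]))
        else:
            windows[tr.bird_id] = (tr.release_time, float(tr.t[-1]))
    return windows


def analyse_tracks(tracks, sites, loft: Loft, cfg: AnalysisConfig | None = None,
                   compute_power: bool = True, full_reports: bool = True) -> StudyResults:
    """Run the whole statistical procedure on a collection of tracks.

    ``sites`` maps site_id → :class:`Site` (or is an iterable of Sites).
    With ``full_reports=False`` the per-term confidence intervals and
    residual diagnostics are skipped (used by large replicate experiments;
    F, p, η²p and the fitted mean differences are always computed).
    """
    cfg = cfg or AnalysisConfig()
    if not isinstance(sites, dict):
        sites = {s.site_id: s for s in sites}
    rng = np.random.default_rng(cfg.seed)

    # following screen inside the 2 km section windows
    windows = _segment_windows(tracks, sites, cfg)
    events = detect_following(tracks, cfg.following.d_max_m, cfg.following.t_min_s,
                              cfg.following.slack_s, windows=windows)
    follow_flags = apply_following_exclusions(events, tracks, rng)

    excl_rows = [{"bird_id": b, "radius_m": "all", "reason": FOLLOWING,
                  "parameters": f"d_max={cfg.following.d_max_m},t_min={cfg.following.t_min_s}"}
                 for b in sorted(follow_flags)]
    metric_rows = []
    points = {r: {} for r in cfg.analysis_radii_m}
    for tr in tracks:
        if tr.bird_id in follow_flags:
            continue
        site = sites[tr.release_site]
        for radius in cfg.analysis_radii_m:
            seg = extract_segment(tr, (site.lat, site.lon), radius,
                                  cfg.escape_radius_m, cfg.min_speed_kmh)
            if not seg.usable:
                excl_rows.append({"bird_id": tr.bird_id, "radius_m": radius,
                                  "reason": seg.excluded, "parameters": ""})
                continue
            try:
                rec = compute_metrics(seg, loft, cfg.hei_anchor)
                dirs = step_directions(seg, loft)
            except MetricUndefinedError as err:
                excl_rows.append({"bird_id": tr.bird_id, "radius_m": radius,
                                  "reason": "too_few_fixes", "parameters": str(err)})
                continue
            metric_rows.append({
                "bird_id": tr.bird_id, "group": tr.group,
                "release_site": tr.release_site, "radius_m": radius,
                "vanishing_time_s": rec.vanishing_time,
                "mean_vector_length": rec.mean_vector_length,
                "mean_direction_deg": rec.mean_direction,
                "efficiency_index": rec.efficiency_index,
                "homing_efficiency_index": rec.homing_efficiency_index,
            })
            points[radius][tr.bird_id] = bird_vector_point(dirs, cfg.unit_vectors)

    metrics = pd.DataFrame(metric_rows, columns=[
        "bird_id", "group", "release_site", "radius_m", *METRIC_COLUMNS])
    exclusions = pd.DataFrame(excl_rows,
                              columns=["bird_id", "radius_m", "reason", "parameters"])

    info = {tr.bird_id: tr for tr in tracks}
    hotelling = {}
    for radius in cfg.analysis_radii_m:
        ids = sorted(points[radius])
        arr = np.array([points[radius][b] for b in ids]) if ids else np.empty((0, 2))
        for comparison, split in (("treatment", lambda b: info[b].group == "experimental"),
                                  ("release_site", lambda b: info[b].release_site
                                   == sorted({t.release_site for t in tracks})[0])):
            mask = np.array([split(b) for b in ids], dtype=bool) if ids else np.array([], bool)
            if mask.sum() >= 3 and (~mask).sum() >= 3:
                hotelling[(comparison, radius)] = hotelling_two_sample(arr[mask], arr[~mask])

    rename = dict(zip(METRIC_COLUMNS,
                      ("vanishing_time", "mean_vector_length", "mean_direction",
                       "efficiency_index", "homing_efficiency_index")))
    fitting = metrics.rename(columns=rename)
    models = {}
    for spec in model_specs(cfg.analysis_radii_m):
        sub = fitting[fitting["radius_m"] == spec.radius]
        if sub.empty or sub["group"].nunique() < 2 or sub["release_site"].nunique() < 2:
            continue
        fit = fit_metric_model(fitting, spec)
        models[(spec.metric, spec.radius)] = ModelReport(
            spec=spec, n=len(sub),
            group=effect_sizes(fit, "group") if full_reports
            else _lean_effects(fit, "group"),
            site=effect_sizes(fit, "release_site") if full_reports
            else _lean_effects(fit, "release_site"),
            diagnostics=residual_diagnostics(fit) if full_reports else None)

    power = None
    if compute_power and not metrics.empty:
        ns = sorted(metrics.groupby("radius_m")["bird_id"].count().unique())
        power = power_table([int(ns[0]), int(ns[-1])], POWER_ETAS, alpha=cfg.alpha)

    manifest = {
        "config": cfg.to_dict(), "software_version": __version__,
        "n_tracks_in": len(tracks),
        "n_following_excluded": len(follow_flags),
        "n_analysed": {str(r): int((metrics["radius_m"] == r).sum())
                       for r in cfg.analysis_radii_m},
        "n_following_events": len(events),
    }
    return StudyResults(metrics=metrics, exclusions=exclusions, hotelling=hotelling,
                        models=models, bird_points=points, power=power,
                        manifest=manifest)


def _lean_effects(fit, term) -> EffectReport:
    """Effect report without the noncentral-t work (replicate experiments)."""
    from .inference import _INDICATORS, type2_anova
    name = _INDICATORS[term]
    table = type2_anova(fit)
    ss_term = float(table.loc[name, "sum_sq"])
    ss_resid = float(table.loc["Residual", "sum_sq"])
    df_den = int(table.loc["Residual", "df"])
    if ss_term + ss_resid <= 0:
        return EffectReport(term, 0.0, 1, df_den, 1.0, 0.0, 0.0, (0.0, 0.0),
                            0.0, (0.0, 0.0))
    return EffectReport(term=term, F=float(table.loc[name, "F"]), df_num=1,
                        df_den=df_den, p=float(table.loc[name, "PR(>F)"]),
                        partial_eta_sq=ss_term / (ss_term + ss_resid),
                        mean_difference=float(fit.params[name]),
                        mean_difference_ci=(float("nan"), float("nan")),
                        cohens_d=float("nan"), cohens_d_ci=(float("nan"), float("nan")))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_full_analysis(out_dir, tracks=None, sites=None, loft=None,
                      cfg: AnalysisConfig | None = None,
                      sim_cfg=None, make_figures: bool = True) -> Path:
    """Full reproducible run writing every output under ``out_dir``.

    Either pass ``tracks``/``sites``/``loft`` (read from files), or a
    ``sim_cfg`` to generate a synthetic study first.
    """
    from .io import write_manifest, write_tracks

    cfg = cfg or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if tracks is None:
        if sim_cfg is None:
            raise ValueError("either tracks or sim_cfg must be given")
        from .simulate import simulate_study
        sim = simulate_study(sim_cfg)
        tracks, sites, loft = sim.tracks, sim_cfg.sites, sim_cfg.loft
        write_tracks(tracks, out / "tracks.csv")
        write_manifest(tracks, out / "manifest.csv")
        sim.truth.to_csv(out / "truth.csv", index=False)

    results = analyse_tracks(tracks, sites, loft, cfg)
    results.metrics.to_csv(out / "metrics.csv", index=False)
    results.exclusions.to_csv(out / "exclusions.csv", index=False)

    hot = [{"comparison": comp, "radius_m": radius, **res.to_dict()}
           for (comp, radius), res in sorted(results.hotelling.items())]
    (out / "hotelling.json").write_text(json.dumps(hot, indent=2))

    reports = [rep.to_dict() for rep in results.models.values()]
    (out / "model_reports.json").write_text(json.dumps(reports, indent=2))
    if results.power is not None:
        results.power.to_csv(out / "power.csv", index=False)

    if make_figures:
        from .plots import plot_circular, plot_metric_boxes
        info = {tr.bird_id: tr for tr in tracks}
        for radius in cfg.analysis_radii_m:
            plot_circular(results.bird_points[radius], info,
                          out / f"orientations_{int(radius)}m.png")
        for metric in ("vanishing_time_s", "mean_vector_length",
                       "efficiency_index", "homing_efficiency_index"):
            plot_metric_boxes(results.metrics, metric, out / f"box_{metric}.png")

    manifest = dict(results.manifest)
    manifest["input_checksums"] = {p.name: _checksum(p) for p in sorted(out.glob("*.csv"))}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
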