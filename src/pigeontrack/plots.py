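"""Figures: circular orientation scatter and metric box plots.

The circular plot places the home direction at the top (12 o'clock) with
angles increasing clockwise, each bird drawn at its mean home-relative
direction at radius = mean vector length, and each group summarised by a
second-order mean-vector arrow.  Box plots show the median, the 25th/75th
percentiles and whiskers at the most extreme values within 1.5×IQR, with
the individual birds overplotted.
"""

from __future__ import annotations

import logging
import math

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .circstats import second_order_mean_vector

log = logging.getLogger(__name__)

_GROUP_STYLE = {"experimental": dict(color="forestgreen", marker="^"),
                "control": dict(color="goldenrod", marker="o")}


def box_stats(values) -> dict:
    """Median, quartiles and 1.5×IQR whisker positions for one sample."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_candidates = v[v >= q1 - 1.5 * iqr]
    hi_candidates = v[v <= q3 + 1.5 * iqr]
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": float(lo_candidates[0]),
            "whisker_high": float(hi_candidates[-1])}


def mean_point_to_polar(x: float, y: float) -> tuple[float, float]:
    """Map a mean-vector point to (theta_rad, r) for a clockwise,
    home-at-top polar axes: the home direction (0°) plots straight up."""
    return math.atan2(y, x), math.hypot(x, y)


def plot_circular(points_by_bird: dict, track_info: dict, path) -> None:
    """Per-bird mean vectors and per-group second-order vectors, home at top."""
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    groups: dict[str, list] = {}
    for bird_id, (x, y) in points_by_bird.items():
        tr = track_info[bird_id]
        groups.setdefault(tr.group, []).append((x, y))
        theta, r = mean_point_to_polar(x, y)
        style = _GROUP_STYLE.get(tr.group, dict(color="gray", marker="."))
        ax.plot(theta, r, linestyle="none", alpha=0.8, **style)
    for name in ("experimental", "control"):
        pts = groups.get(name)
        if not pts:
            log.warning("no birds in group %r: panel omitted", name)
            continue
        length, direction = second_order_mean_vector(pts)
        ax.annotate("", xy=(math.radians(direction), length), xytext=(0.0, 0.0),
                    arrowprops=dict(arrowstyle="-|>",
                                    color=_GROUP_STYLE[name]["color"], lw=2))
    ax.set_rmax(1.0)
    ax.set_title("mean home-relative directions (home at top)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metric_boxes(metrics, metric: str, path) -> None:
    """Box-and-point panels per radius × site × group for one metric."""
    radii = sorted(metrics["radius_m"].unique())
    fig, axes = plt.subplots(1, len(radii), figsize=(5 * len(radii), 4),
                             squeeze=False, sharey=True)
    for ax, radius in zip(axes[0], radii):
        sub = metrics[metrics["radius_m"] == radius]
        pos, data, labels = 0, [], []
        for site in sorted(sub["release_site"].unique()):
            for group in ("experimental", "control"):
                vals = sub[(sub["release_site"] == site)
                           & (sub["group"] == group)][metric].to_numpy()
                if vals.size == 0:
                    log.warning("no %s birds at %s: panel omitted", group, site)
                    continue
                pos += 1
                data.append(vals)
                labels.append(f"{site}\n{group[:4]}")
        if not data:
            continue
        bp = ax.boxplot(data, whis=1.5, showfliers=False, widths=0.6)
        for k, vals in enumerate(data, start=1):
            jitter = (np.arange(vals.size) % 5 - 2) * 0.03
            ax.plot(np.full(vals.size, k) + jitter, vals, linestyle="none",
                    marker=".", alpha=0.7, color="black")
        ax.set_xticklabels(labels, fontsize=8)
        ax.set_title(f"{metric} @ {int(radius)} m")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
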