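"""Group-level directional statistics.

Each bird is embedded as one bivariate point: the Cartesian components of
its mean vector of home-relative step directions, (x, y) =
(L·cos θ̄, L·sin θ̄) with L the mean vector length.  The embedding preserves
both the bird's mean direction and its directional concentration, so a
two-sample Hotelling T² on these points compares whole directional
distributions between groups.  A unit-vector variant (L forced to 1,
direction only) is available via ``unit_vectors=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

from .geodesy import wrap_angle

__all__ = ["bird_vector_point", "second_order_mean_vector",
           "hotelling_two_sample", "HotellingResult"]


def bird_vector_point(directions_deg, unit_vector: bool = False) -> tuple[float, float]:
    """One bird's (x, y) mean-vector point from its step directions."""
    theta = np.radians(np.asarray(directions_deg, dtype=float))
    if theta.size == 0:
        raise ValueError("empty direction set")
    x = float(np.mean(np.cos(theta)))
    y = float(np.mean(np.sin(theta)))
    if unit_vector:
        r = np.hypot(x, y)
        if r == 0.0:
            raise ValueError("mean direction undefined (zero resultant)")
        x, y = x / r, y / r
    return x, y


def second_order_mean_vector(points) -> tuple[float, float]:
    """Vector average of individual mean vectors → (length, direction°).

    Summarises a group's directional distribution; length ≤ 1 because each
    individual mean vector has length ≤ 1.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("no points")
    x, y = float(np.mean(pts[:, 0])), float(np.mean(pts[:, 1]))
    return float(np.hypot(x, y)), wrap_angle(np.degrees(np.arctan2(y, x)))


@dataclass(frozen=True)
class HotellingResult:
    n_total: int
    statistic: float      # classical T²
    f_statistic: float    # its F transform
    df: tuple[int, int]
    p_value: float
    group_means: tuple[tuple[float, float], tuple[float, float]]

    def to_dict(self) -> dict:
        return {"n": self.n_total, "T2": self.statistic, "F": self.f_statistic,
                "df": list(self.df), "p": self.p_value,
                "group_means": [list(m) for m in self.group_means]}


def hotelling_two_sample(group_a, group_b) -> HotellingResult:
    """Two-sample Hotelling T² for bivariate mean-vector points.

    T² = (n_a n_b)/(n_a+n_b) · d' S⁻¹ d with d the mean difference and S the
    pooled (unbiased) covariance; the p-value comes from
    F = (n−3)/(2(n−2)) · T² on (2, n−3) degrees of freedom.  Both T² and F
    are reported because the two scales are easy to confuse.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("points must be bivariate")
    na, nb = a.shape[0], b.shape[0]
    if na < 3 or nb < 3:
        raise ValueError("each group needs at least 3 points")
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    d = mean_a - mean_b
    pooled = ((na - 1) * np.cov(a, rowvar=False) + (nb - 1) * np.cov(b, rowvar=False)) \
        / (na + nb - 2)
    try:
        solved = np.linalg.solve(pooled, d)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular pooled covariance: the point sets are degenerate "
                         "(e.g. collinear fixture)") from err
    t2 = float(na * nb / (na + nb) * d @ solved)
    n = na + nb
    f_stat = (n - 3) / (2.0 * (n - 2)) * t2
    p = float(f_dist.sf(f_stat, 2, n - 3))
    return HotellingResult(n_total=n, statistic=t2, f_statistic=float(f_stat),
                           df=(2, n - 3), p_value=p,
                           group_means=(tuple(mean_a), tuple(mean_b)))
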