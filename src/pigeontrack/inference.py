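"""Per-metric linear models, effect sizes and residual diagnostics.

Each navigation metric is modelled as

    metric ~ treatment group + release site

by ordinary least squares with two binary predictors and no interaction,
assessed with Type II sums of squares.  The treatment indicator is 1 for the
experimental group and the site indicator is 1 for the second site (sorted
order), so positive fitted mean differences mean larger metric values in the
experimental group, and at site 2, respectively.  Virtual vanishing times
are natural-log transformed before fitting; their mean differences are
reported on the log scale.

For each tested term the report carries F (with degrees of freedom), the
p-value, partial η² = SS_term / (SS_term + SS_resid), the fitted mean
difference with its 95% t confidence interval, and Cohen's d = t·√(1/n₁+1/n₂)
with a 95% CI from inverting the noncentral-t distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.optimize import brentq
from scipy.stats import nct, norm, shapiro
from statsmodels.stats.anova import anova_lm

from .model import EXPERIMENTAL

__all__ = ["ModelSpec", "EffectReport", "DiagnosticsReport", "MODEL_SPECS",
           "fit_metric_model", "effect_sizes", "residual_diagnostics",
           "normal_qq_points", "cohens_d_ci"]

GROUP_TERM = "group"
SITE_TERM = "release_site"
_INDICATORS = {GROUP_TERM: "is_experimental", SITE_TERM: "is_site2"}


@dataclass(frozen=True)
class ModelSpec:
    metric: str
    radius: float
    transform: str = "identity"  # identity | natural_log

    def __post_init__(self):
        if self.transform not in ("identity", "natural_log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "natural_log" and self.metric != "vanishing_time":
            raise ValueError("the natural-log transform is reserved for vanishing_time")


def model_specs(radii=(2000.0, 5000.0)) -> list[ModelSpec]:
    """The study's model grid: four metrics at each analysis radius."""
    specs = []
    for r in radii:
        specs.append(ModelSpec("vanishing_time", r, "natural_log"))
        specs.append(ModelSpec("mean_vector_length", r))
        specs.append(ModelSpec("homing_efficiency_index", r))
        specs.append(ModelSpec("efficiency_index", r))
    return specs


MODEL_SPECS = model_specs()


@dataclass(frozen=True)
class EffectReport:
    term: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    mean_difference: float
    mean_difference_ci: tuple[float, float]
    cohens_d: float
    cohens_d_ci: tuple[float, float]

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["mean_difference_ci"] = list(self.mean_difference_ci)
        d["cohens_d_ci"] = list(self.cohens_d_ci)
        return d


@dataclass(frozen=True)
class DiagnosticsReport:
    shapiro_W: float
    shapiro_p: float
    qq_points: np.ndarray = field(repr=False)  # (n, 2): theoretical, sample


def _prepare(records: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = records[records["radius_m"] == spec.radius].copy()
    if df.empty:
        raise ValueError(f"no records at radius {spec.radius}")
    if df[spec.metric].isna().any():
        raise ValueError(f"missing {spec.metric} values")
    sites = sorted(df["release_site"].unique())
    if len(sites) != 2 or df["group"].nunique() != 2:
        raise ValueError("both treatment groups and both release sites are required")
    y = df[spec.metric].astype(float)
    if spec.transform == "natural_log":
        if (y <= 0).any():
            raise ValueError("natural_log transform requires positive values")
        y = np.log(y)
    return pd.DataFrame({
        "y": y,
        "is_experimental": (df["group"] == EXPERIMENTAL).astype(float),
        "is_site2": (df["release_site"] == sites[1]).astype(float),
    })


def fit_metric_model(records: pd.DataFrame, spec: ModelSpec):
    """OLS fit of ``metric ~ group + release_site`` (additive, Type II SS).

    ``records`` is the per-bird metric table with columns ``group``,
    ``release_site``, ``radius_m`` and the metric columns.
    """
    data = _prepare(records, spec)
    fit = smf.ols("y ~ is_experimental + is_site2", data=data).fit()
    fit.model.data.frame = data  # keep indicators reachable for effect sizes
    return fit


def type2_anova(fit) -> pd.DataFrame:
    return anova_lm(fit, typ=2)


def cohens_d_ci(t: float, df: int, n1: int, n2: int,
                conf: float = 0.95) -> tuple[float, float]:
    """CI for Cohen's d by inverting the noncentral-t pivot of ``t``."""
    alpha = (1.0 - conf) / 2.0
    scale = math.sqrt(1.0 / n1 + 1.0 / n2)

    def _solve(prob):
        # ncp with nct.cdf(t, df, ncp) == prob; the cdf decreases in ncp, so
        # expand the bracket outward from t until the target is straddled
        lo, hi = t - 1.0, t + 1.0
        while nct.cdf(t, df, lo) < prob:
            lo -= 1.0
        while nct.cdf(t, df, hi) > prob:
            hi += 1.0
        return brentq(lambda nc: nct.cdf(t, df, nc) - prob, lo, hi, xtol=1e-10)

    lo = _solve(1.0 - alpha)
    hi = _solve(alpha)
    return lo * scale, hi * scale


def effect_sizes(fit, term: str, conf: float = 0.95) -> EffectReport:
    """Full effect report for ``term`` in {"group", "release_site"}."""
    if term not in _INDICATORS:
        raise KeyError(f"term must be one of {sorted(_INDICATORS)}")
    name = _INDICATORS[term]
    data = fit.model.data.frame
    table = type2_anova(fit)
    ss_term = float(table.loc[name, "sum_sq"])
    ss_resid = float(table.loc["Residual", "sum_sq"])
    df_den = int(table.loc["Residual", "df"])
    endog = np.asarray(fit.model.endog, dtype=float)
    if float(np.var(endog)) <= 1e-24 * max(1.0, float(np.mean(endog)) ** 2):
        # constant response: no variation to attribute
        return EffectReport(term, 0.0, 1, df_den, 1.0, 0.0, 0.0, (0.0, 0.0),
                            0.0, (0.0, 0.0))
    f_val = float(table.loc[name, "F"])
    p = float(table.loc[name, "PR(>F)"])
    eta = ss_term / (ss_term + ss_resid)
    coef = float(fit.params[name])
    ci = fit.conf_int(alpha=1.0 - conf).loc[name]
    tval = float(fit.tvalues[name])
    ind = data[name].to_numpy()
    n1, n2 = int((ind == 1.0).sum()), int((ind == 0.0).sum())
    d = tval * math.sqrt(1.0 / n1 + 1.0 / n2)
    d_ci = cohens_d_ci(tval, df_den, n1, n2, conf)
    return EffectReport(term=term, F=f_val, df_num=1, df_den=df_den, p=p,
                        partial_eta_sq=float(eta), mean_difference=coef,
                        mean_difference_ci=(float(ci[0]), float(ci[1])),
                        cohens_d=float(d), cohens_d_ci=d_ci)


def normal_qq_points(std_resid) -> np.ndarray:
    """Ordered (theoretical, sample) quantile pairs, Blom plotting positions."""
    r = np.sort(np.asarray(std_resid, dtype=float))
    n = r.size
    theo = norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    return np.column_stack([theo, r])


def residual_diagnostics(fit) -> DiagnosticsReport:
    """Shapiro–Wilk test and QQ pairs for the standardized residuals."""
    resid = np.asarray(fit.resid, dtype=float)
    if resid.size < 3:
        raise ValueError("need at least 3 residuals")
    sd = resid.std(ddof=1)
    std = (resid - resid.mean()) / sd if sd > 0 else resid * 0.0
    w, p = shapiro(resid)
    return DiagnosticsReport(shapiro_W=float(w), shapiro_p=float(p),
                             qq_points=normal_qq_points(std))
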