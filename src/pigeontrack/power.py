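"""Analytic power for one tested predictor in the two-predictor linear model.

The fixed-effects regression parameterisation is used: for a target partial
η², Cohen's f² = η² / (1 − η²), the noncentrality is λ = f² · N with N the
total sample size, and power is the survival probability of the noncentral
F(1, N − 3; λ) at the central-F critical value for the chosen α.  The
denominator degrees of freedom N − 3 count the intercept and the two binary
predictors (the tested one plus one covariate).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import ncf

__all__ = ["PowerQuery", "PowerResult", "power_for_eta_sq", "power_table"]


@dataclass(frozen=True)
class PowerQuery:
    partial_eta_sq: float
    n_total: int
    n_predictors_tested: int = 1
    n_other_predictors: int = 1
    alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.partial_eta_sq < 1.0:
            raise ValueError("partial_eta_sq must be in (0, 1)")
        if self.n_total <= self.n_predictors_tested + self.n_other_predictors + 1:
            raise ValueError("n_total too small for the model's degrees of freedom")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class PowerResult:
    power_percent: float
    f_squared: float
    noncentrality: float
    df_num: int
    df_den: int


def power_for_eta_sq(query: PowerQuery | None = None, *, partial_eta_sq=None,
                     n_total=None, alpha: float = 0.05) -> PowerResult:
    """Analytic power (percent) to detect ``partial_eta_sq`` at sample size N."""
    if query is None:
        query = PowerQuery(partial_eta_sq=partial_eta_sq, n_total=n_total, alpha=alpha)
    eta = query.partial_eta_sq
    f2 = eta / (1.0 - eta)
    df_num = query.n_predictors_tested
    df_den = query.n_total - query.n_predictors_tested - query.n_other_predictors - 1
    lam = f2 * query.n_total
    crit = f_dist.ppf(1.0 - query.alpha, df_num, df_den)
    power = float(ncf.sf(crit, df_num, df_den, lam))
    return PowerResult(power_percent=100.0 * power, f_squared=float(f2),
                       noncentrality=float(lam), df_num=df_num, df_den=df_den)


def power_table(n_values, eta_values, alpha: float = 0.05) -> pd.DataFrame:
    """Power grid (percent) over effect sizes × sample sizes.

    Rows are η²p values, columns sample sizes; power is monotone increasing
    in both arguments.
    """
    n_values = sorted(set(int(n) for n in n_values))
    eta_values = sorted(set(float(e) for e in eta_values))
    if not n_values or not eta_values:
        raise ValueError("need at least one n and one eta value")
    rows = []
    for eta in eta_values:
        row = {"partial_eta_sq": eta}
        for n in n_values:
            res = power_for_eta_sq(PowerQuery(eta, n, alpha=alpha))
            row[f"power_n{n}_pct"] = res.power_percent
        rows.append(row)
    return pd.DataFrame(rows)
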