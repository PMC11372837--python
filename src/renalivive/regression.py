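"""Empirical log-log relationship between the albumin-effect ratio R and
the fraction unbound in the incubation, plus the extra-sum-of-squares F-test
comparing transporter data sets.

The relationship log10 R = intercept + slope * log10 f_u,inc lets the
albumin-mediated fold change be predicted prospectively from a routine
protein-binding measurement, without running an albumin-containing uptake
assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = ["LogLogFit", "FTestResult", "loglog_fit", "ess_f_test",
           "predict_R_from_fu"]


@dataclass
class LogLogFit:
    transporter: str
    slope: float
    intercept: float
    r_squared: float
    rmse: float            # residual standard error, log10 units
    n_points: int
    residuals: np.ndarray
    fu_range: tuple        # (min, max) of the fitted fu values


@dataclass
class FTestResult:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    ssr_pooled: float
    ssr_separate: float


def _validate(fu, r):
    fu = np.asarray(fu, dtype=float)
    r = np.asarray(r, dtype=float)
    if len(fu) != len(r):
        raise ValueError("fu and R lengths differ")
    if np.any(fu <= 0) or np.any(r <= 0):
        raise ValueError("fu and R must be positive for log transformation")
    return fu, r


def loglog_fit(fu, r, transporter: str = "") -> LogLogFit:
    """OLS of log10 R on log10 f_u,inc."""
    fu, r = _validate(fu, r)
    if len(fu) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.log10(fu)
    y = np.log10(r)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = np.asarray(model.resid)
    dof = len(fu) - 2
    rmse = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return LogLogFit(
        transporter=transporter,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        rmse=rmse,
        n_points=len(fu),
        residuals=resid,
        fu_range=(float(fu.min()), float(fu.max())),
    )


def ess_f_test(fu_a, r_a, fu_b, r_b) -> FTestResult:
    """Extra-sum-of-squares F-test: one shared line vs separate lines.

    Pooled model: common slope and intercept for both data sets (2
    parameters).  Separate model: own slope and intercept each (4).
    F = ((SSR_pooled - SSR_sep)/2) / (SSR_sep / (n_total - 4)).
    """
    fu_a, r_a = _validate(fu_a, r_a)
    fu_b, r_b = _validate(fu_b, r_b)
    n = len(fu_a) + len(fu_b)
    df_den = n - 4
    if df_den <= 0:
        raise ValueError("not enough points for the separate-fits model")

    def ssr(x, y):
        m = sm.OLS(y, sm.add_constant(x)).fit()
        return float(m.ssr)

    xa, ya = np.log10(fu_a), np.log10(r_a)
    xb, yb = np.log10(fu_b), np.log10(r_b)
    ssr_sep = ssr(xa, ya) + ssr(xb, yb)
    ssr_pooled = ssr(np.concatenate([xa, xb]), np.concatenate([ya, yb]))

    f_stat = max(0.0, (ssr_pooled - ssr_sep) / 2.0) / (ssr_sep / df_den)
    p = float(stats.f.sf(f_stat, 2, df_den))
    return FTestResult(f_stat=float(f_stat), df_num=2, df_den=df_den,
                       p_value=p, ssr_pooled=ssr_pooled, ssr_separate=ssr_sep)


def predict_R_from_fu(fit: LogLogFit, fu: float) -> float:
    """Predicted albumin-effect ratio at fraction unbound ``fu``.

    Warns (rather than refusing) when ``fu`` lies below the fitted range:
    the relationship is applied prospectively, but extrapolation beyond the
    calibration data deserves a flag.
    """
    if not (0 < fu <= 1):
        raise ValueError("fu must be in (0, 1]")
    if fu < fit.fu_range[0]:
        warnings.warn(
            f"fu = {fu:g} is below the fitted range "
            f"[{fit.fu_range[0]:g}, {fit.fu_range[1]:g}]; extrapolating",
            stacklevel=2)
    return float(10.0 ** (fit.intercept + fit.slope * np.log10(fu)))
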